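import numpy as np
import pytest

import nephroguide as ng


@pytest.fixture(scope="session")
def default_phantom():
    """Default-spec phantom: 1.5 mm grid, tumor-kidney contrast 3 sigma."""
    vol, truth, hilum = ng.make_phantom(ng.PhantomSpec(seed=0))
    return vol, truth, hilum


@pytest.fixture(scope="session")
def phantom_1mm():
    """Isotropic 1 mm phantom used for registration-accuracy tests."""
    vol, truth, hilum = ng.make_phantom(
        ng.PhantomSpec(seed=0, spacing=(1.0, 1.0, 1.0), shape=(128, 128, 128))
    )
    return vol, truth, hilum


@pytest.fixture(scope="session")
def tumor_stack_1mm(phantom_1mm):
    _, truth, _ = phantom_1mm
    frame = ng.slice_frame_from(truth)
    return ng.resample_mask_to_frame(
        truth, frame, labels=ng.LABEL_TUMOR, pixel_mm=1.0, pad_px=40
    )


@pytest.fixture
def tumor_seed_block(default_phantom):
    """27-voxel seed block at the tumor centroid with tolerance 1.5 sigma."""
    _, truth, _ = default_phantom
    c = np.round(np.argwhere(truth.labels == ng.LABEL_TUMOR).mean(axis=0)).astype(int)
    pts = [
        tuple(c + [i, j, k]) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    ]
    return ng.SeedSet(points=pts, label=ng.LABEL_TUMOR, tolerance=15.0)


def seed_block_for(truth, label=ng.LABEL_TUMOR, tolerance=15.0):
    c = np.round(np.argwhere(truth.labels == label).mean(axis=0)).astype(int)
    pts = [
        tuple(c + [i, j, k]) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    ]
    return ng.SeedSet(points=pts, label=label, tolerance=tolerance)


def box_mask(nz_mm: int, spacing: float = 1.0) -> ng.SegmentationMask:
    """Tumor box spanning exactly nz_mm millimetres along z at given spacing."""
    nz = int(round(nz_mm / spacing))
    labels = np.zeros((30, 30, nz + 10), dtype=np.int16)
    labels[5:25, 5:25, 5:5 + nz] = ng.LABEL_TUMOR
    affine = np.diag([spacing, spacing, spacing, 1.0])
    return ng.SegmentationMask(labels=labels, affine=affine)


def perturb_slice(mask2d, scale, rot_deg, trans_mm, pixel_mm=1.0):
    """Apply a known similarity transform about the mask centroid.

    Returns (photo mask, forward transform) with the same convention the
    macro-slice simulator uses.
    """
    theta = np.deg2rad(rot_deg)
    c = np.argwhere(mask2d).mean(axis=0) * pixel_mm
    cs, sn = np.cos(theta), np.sin(theta)
    rotm = np.array([[cs, -sn], [sn, cs]])
    fwd = ng.SimilarityTransform2D(
        scale, theta, tuple(c + np.asarray(trans_mm) - scale * rotm @ c)
    )
    photo = ng.warp_mask(mask2d, fwd, mask2d.shape, pixel_mm)
    return photo, fwd
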