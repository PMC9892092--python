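"""Synthetic inputs for the whole pipeline.

Two generators and one packaged fixture:

* :func:`make_phantom` builds a contrast-enhanced kidney+tumor volume as
  nested ellipsoids with Gaussian noise and an optional non-enhancing
  (low-intensity) necrotic core, together with the exact ground-truth label
  mask and a hilum point on the medial kidney surface.  Default intensity
  levels put the tumor 3 noise-sigmas above the kidney, emulating a
  post-contrast T1 acquisition with clear but not trivial contrast.
* :func:`simulate_macro_slices` turns the ground-truth tumor slices into
  mock macroscopic-photograph masks: per-slice similarity perturbations
  (the pose of the photographed slice on the table), optional elastic
  deformation (weak specimen consistency), thickness jitter, and random
  merging of adjacent slabs (cuts thicker than intended, which is what
  drives the resulted-slice count below the DWI target).  Every drawn
  transform is recorded as ground truth.
* :func:`cohort_fixture` returns the packaged per-patient study tables
  (ages/sex/stage, printing cost, slice accounting and overlap statistics)
  used by the cohort-summary stage.

Everything is seed-deterministic: the same seed reproduces the same volume
and the same macro-slice draws bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .radpath_qc import SimilarityTransform2D, warp_mask
from .volume_io import (
    LABEL_KIDNEY,
    LABEL_TUMOR,
    LabeledVolume,
    SegmentationMask,
    SliceFrame,
    SliceStack,
    resample_mask_to_frame,
)


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of the synthetic kidney+tumor volume.

    Defaults are a scaled-down but anatomically proportioned left kidney
    with a large intrarenal tumor: kidney long axis cranial-caudal (z),
    tumor displacing the upper pole, hilum on the medial (-x) surface.
    Intensity levels are arbitrary units with tumor-kidney contrast equal
    to 3 noise sigmas.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    kidney_semiaxes: tuple[float, float, float] = (30.0, 25.0, 45.0)
    kidney_center_mm: tuple[float, float, float] | None = None  # default: grid centre
    tumor_semiaxes: tuple[float, float, float] = (22.0, 18.0, 25.0)
    tumor_offset_mm: tuple[float, float, float] = (8.0, 5.0, 12.0)
    # second tumor lobe: breaks the rotational symmetry of a pure ellipsoid,
    # emulating the lobulated outline of a heterogeneous nephroblastoma
    tumor_lobe_semiaxes: tuple[float, float, float] | None = (13.0, 11.0, 16.0)
    tumor_lobe_offset_mm: tuple[float, float, float] = (8.0, -14.0, 4.0)
    intensity_background: float = 30.0
    intensity_kidney: float = 90.0
    intensity_tumor: float = 120.0
    intensity_necrosis: float = 45.0
    noise_sigma: float = 10.0
    necrotic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.necrotic_fraction < 1.0:
            raise ValueError("necrotic fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    q = sum(((coords[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    return q <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, SegmentationMask, np.ndarray]:
    """Generate (volume, ground-truth mask, hilum world point) from a spec."""
    spacing = np.asarray(spec.spacing, dtype=float)
    affine = np.diag([*spacing, 1.0])
    coords = np.meshgrid(
        *(spacing[a] * np.arange(spec.shape[a]) for a in range(3)), indexing="ij"
    )
    extent = spacing * (np.asarray(spec.shape) - 1)
    kc = (
        np.asarray(spec.kidney_center_mm, dtype=float)
        if spec.kidney_center_mm is not None
        else extent / 2.0
    )
    tc = kc + np.asarray(spec.tumor_offset_mm)

    kidney = _ellipsoid(coords, kc, spec.kidney_semiaxes)
    tumor = _ellipsoid(coords, tc, spec.tumor_semiaxes)
    if spec.tumor_lobe_semiaxes is not None:
        tumor |= _ellipsoid(
            coords, tc + np.asarray(spec.tumor_lobe_offset_mm), spec.tumor_lobe_semiaxes
        )
    if not tumor.any():
        raise ValueError("tumor lies entirely outside the grid")
    if not (tumor & kidney).any():
        raise ValueError("tumor neither overlaps nor abuts the kidney")

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[kidney] = LABEL_KIDNEY
    labels[tumor] = LABEL_TUMOR

    levels = np.full(spec.shape, spec.intensity_background, dtype=float)
    levels[kidney] = spec.intensity_kidney
    levels[tumor] = spec.intensity_tumor
    if spec.necrotic_fraction > 0:
        core_axes = np.asarray(spec.tumor_semiaxes) * spec.necrotic_fraction ** (1 / 3)
        core = _ellipsoid(coords, tc, core_axes) & tumor
        levels[core] = spec.intensity_necrosis

    rng = np.random.default_rng(spec.seed)
    voxels = levels + rng.normal(0.0, spec.noise_sigma, size=spec.shape) \
        if spec.noise_sigma > 0 else levels

    hilum = kc - np.array([spec.kidney_semiaxes[0], 0.0, 0.0])
    return (
        LabeledVolume(voxels=voxels, affine=affine),
        SegmentationMask(labels=labels, affine=affine),
        hilum,
    )


# ---------------------------------------------------------------------------
# Macroscopic slice simulation
# ---------------------------------------------------------------------------

@dataclass
class MacroSimSpec:
    """Per-slice perturbations applied to the ground-truth tumor slices.

    Ranges are uniform draw bounds; ``elastic_amplitude_mm`` is the maximum
    contour displacement of the smoothed random deformation field;
    ``merge_probability`` is the chance that a slab is cut together with its
    cranial neighbour (thicker-than-intended cut), which reduces the
    resulted-slice count.
    """

    scale_range: tuple[float, float] = (0.9, 1.1)
    rotation_range_deg: tuple[float, float] = (-20.0, 20.0)
    translation_max_mm: float = 10.0
    elastic_amplitude_mm: float = 0.0
    thickness_jitter_sigma_mm: float = 0.3
    merge_probability: float = 0.0
    #: in-plane raster size; None derives it from the mask voxel lattice
    pixel_mm: float | None = None
    canvas_pad_px: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.merge_probability < 1.0:
            raise ValueError("merge probability must be in [0, 1)")
        if self.scale_range[0] <= 0:
            raise ValueError("scale must stay positive")


@dataclass
class SimulatedSlice:
    """One mock macroscopic slice with its ground truth."""

    macro_mask: np.ndarray
    forward: SimilarityTransform2D      # MRI slice -> photo pose
    true_inverse: SimilarityTransform2D  # photo -> MRI slice (registration target)
    slab_indices: list[int]              # MRI slabs merged into this cut
    thickness_pair: tuple[float, float]  # caliper readings, two opposite sides
    deformed: bool = False


@dataclass
class MacroSimResult:
    slices: list[SimulatedSlice]
    mri_stack: SliceStack
    spec: MacroSimSpec

    @property
    def n_target(self) -> int:
        return len(self.mri_stack)

    @property
    def n_resulted(self) -> int:
        return len(self.slices)

    def thickness_pairs(self) -> list[tuple[float, float]]:
        return [s.thickness_pair for s in self.slices]

    def macro_masks(self) -> list[np.ndarray]:
        return [s.macro_mask for s in self.slices]


def _elastic_deform(mask: np.ndarray, amplitude_px: float, rng) -> np.ndarray:
    """Smoothed random displacement field with max displacement amplitude_px."""
    if amplitude_px <= 0:
        return mask
    disp = rng.normal(size=(2, *mask.shape))
    disp = np.stack([ndimage.gaussian_filter(d, sigma=8.0) for d in disp])
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= amplitude_px / peak
    ii, jj = np.meshgrid(*(np.arange(s) for s in mask.shape), indexing="ij")
    sampled = ndimage.map_coordinates(
        mask.astype(float), [ii + disp[0], jj + disp[1]], order=1, mode="constant"
    )
    return sampled >= 0.5


def simulate_macro_slices(
    mask: SegmentationMask, frame: SliceFrame, spec: MacroSimSpec
) -> MacroSimResult:
    """Simulate photographed macro-slice tumor masks from the MRI ground truth.

    Slabs are first grouped (merge draws, cranial to caudal), each group's
    tumor mask is united and perturbed by a drawn similarity transform about
    the slab centroid, then optionally elastically deformed.  With zero
    perturbation and zero merge probability the output masks equal the
    resampled MRI slices exactly.
    """
    rng = np.random.default_rng(spec.seed)
    stack = resample_mask_to_frame(
        mask, frame, labels=LABEL_TUMOR, pixel_mm=spec.pixel_mm,
        pad_px=spec.canvas_pad_px,
    )
    pixel_mm = stack.pixel_mm

    groups: list[list[int]] = []
    for k in range(frame.n_slices):
        if groups and rng.random() < spec.merge_probability:
            groups[-1].append(k)
        else:
            groups.append([k])

    slices: list[SimulatedSlice] = []
    for group in groups:
        union = np.zeros_like(stack[0])
        for k in group:
            union |= stack[k]

        s = float(rng.uniform(*spec.scale_range))
        theta = float(np.deg2rad(rng.uniform(*spec.rotation_range_deg)))
        t = rng.uniform(-spec.translation_max_mm, spec.translation_max_mm, size=2)

        if union.any():
            c = np.argwhere(union).mean(axis=0) * pixel_mm
        else:
            c = np.asarray(union.shape, dtype=float) / 2.0 * pixel_mm
        cs, sn = np.cos(theta), np.sin(theta)
        rot = np.array([[cs, -sn], [sn, cs]])
        fwd = SimilarityTransform2D(
            scale=s, rotation=theta, translation=tuple(c + t - s * rot @ c)
        )
        identity_draw = s == 1.0 and theta == 0.0 and not t.any()
        macro = union if identity_draw else warp_mask(
            union, fwd, union.shape, pixel_mm
        )
        deformed = spec.elastic_amplitude_mm > 0
        macro = _elastic_deform(
            macro, spec.elastic_amplitude_mm / pixel_mm, rng
        )

        nominal = len(group) * frame.thickness
        jit = rng.normal(0.0, spec.thickness_jitter_sigma_mm, size=2) \
            if spec.thickness_jitter_sigma_mm > 0 else np.zeros(2)
        pair = tuple(float(max(v, 0.5)) for v in nominal + jit)

        slices.append(
            SimulatedSlice(
                macro_mask=macro,
                forward=fwd,
                true_inverse=fwd.inverse(),
                slab_indices=list(group),
                thickness_pair=pair,  # type: ignore[arg-type]
                deformed=deformed,
            )
        )
    return MacroSimResult(slices=slices, mri_stack=stack, spec=spec)


# ---------------------------------------------------------------------------
# Packaged cohort tables
# ---------------------------------------------------------------------------

def _read_table(name: str) -> pd.DataFrame:
    with resources.files("nephroguide.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def cohort_fixture() -> dict[str, pd.DataFrame]:
    """The study cohort's per-patient tables as structured data.

    Returns ``{"patients", "guides", "slices", "merged"}``: baseline
    characteristics (age, sex, stage), guide printing cost, per-patient
    slice accounting / overlap statistics, and their join on patient id
    with the derived resulted/target percentage, ready for
    :func:`nephroguide.radpath_qc.cohort_summary`.
    """
    patients = _read_table("cohort_patients.csv")
    guides = _read_table("cohort_guides.csv")
    slices = _read_table("cohort_slices.csv")
    merged = patients.merge(guides, on="patient").merge(slices, on="patient")
    merged["slice_ratio_pct"] = (
        100.0 * merged["n_resulted"] / merged["n_target"]
    ).round(1)
    return {"patients": patients, "guides": guides, "slices": slices, "merged": merged}
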