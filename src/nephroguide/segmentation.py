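"""Semiautomatic delineation: seeded 3-D region growing, averaging-filter
smoothing of binary masks, and scripted manual edits.

Region growing selects the 26-connected components, reachable from the seed
voxels, of the set ``{v : |I(v) - ref| <= tol}`` where ``ref`` is the mean
intensity over the seeds.  Smoothing is a box mean of the binary indicator
over a ``(2r+1)^3`` window re-thresholded at 0.5, the standard reading of an
"averaging filter" applied to a binary delineation.  Kidney and tumor are
grown independently; where they overlap the tumor label wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import LABEL_KIDNEY, LABEL_TUMOR, LabeledVolume, SegmentationMask

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class InvalidSeedError(ValueError):
    pass


@dataclass
class SeedSet:
    """Seed voxels for one target label with a symmetric intensity tolerance."""

    points: Sequence[tuple[int, int, int]]
    label: int
    tolerance: float

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise InvalidSeedError("at least one seed required")
        if self.tolerance < 0:
            raise InvalidSeedError("tolerance must be >= 0")
        self.points = [tuple(int(c) for c in p) for p in self.points]

    def validate_against(self, volume: LabeledVolume) -> None:
        shape = volume.shape
        for p in self.points:
            if any(c < 0 or c >= s for c, s in zip(p, shape)):
                raise IndexError(f"seed {p} outside grid {shape}")
            if np.isnan(float(volume.voxels[p])):
                raise InvalidSeedError(f"seed {p} lies on a NaN voxel")


def region_grow(volume: LabeledVolume, seeds: SeedSet) -> SegmentationMask:
    """Grow the seed label through 26-connected in-tolerance voxels.

    The reference intensity is the mean over the seed voxels; a voxel is
    admissible when its intensity lies in ``[ref - tol, ref + tol]``.  The
    output contains every seed and is connected per seed component.
    """
    seeds.validate_against(volume)
    vox = np.asarray(volume.voxels, dtype=float)
    ref = float(np.mean([vox[p] for p in seeds.points]))
    with np.errstate(invalid="ignore"):
        admissible = np.abs(vox - ref) <= seeds.tolerance
    admissible &= ~np.isnan(vox)
    comp, _ = ndimage.label(admissible, structure=_CONN26)
    keep = {comp[p] for p in seeds.points}
    keep.discard(0)  # cannot happen: seeds are admissible by construction
    grown = np.isin(comp, sorted(keep))
    labels = np.where(grown, seeds.label, 0).astype(np.int16)
    return SegmentationMask(labels=labels, affine=volume.affine)


def smooth_mask(mask: SegmentationMask, radius: int) -> SegmentationMask:
    """Box-mean smoothing of each label's indicator, re-thresholded at 0.5.

    Window is ``(2*radius+1)^3``; voxels outside the grid count as
    background.  Radius 0 is the identity.  Where smoothed labels overlap,
    the tumor label wins.
    """
    if radius < 0 or int(radius) != radius:
        raise ValueError("radius must be a non-negative integer")
    if radius == 0:
        return SegmentationMask(labels=mask.labels.copy(), affine=mask.affine)
    w = 2 * int(radius) + 1
    half = w**3 // 2  # window size is odd, so count > half  <=>  mean > 0.5
    out = np.zeros(mask.shape, dtype=np.int16)
    kernel = np.ones((w, w, w), dtype=np.int32)
    for label in (LABEL_KIDNEY, LABEL_TUMOR):  # tumor last: overwrites overlap
        ind = (mask.labels == label).astype(np.int32)
        if not ind.any():
            continue
        counts = ndimage.convolve(ind, kernel, mode="constant", cval=0)
        out[counts > half] = label
    return SegmentationMask(labels=out, affine=mask.affine)


@dataclass
class ManualEdit:
    """One scripted edit: add voxels to a label and/or remove voxels from it."""

    label: int
    add: Sequence[tuple[int, int, int]] = field(default_factory=list)
    remove: Sequence[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.add = [tuple(int(c) for c in p) for p in self.add]
        self.remove = [tuple(int(c) for c in p) for p in self.remove]
        if set(self.add) & set(self.remove):
            raise ValueError("edit both adds and removes the same voxel")


def apply_manual_edits(
    mask: SegmentationMask, edits: Iterable[ManualEdit]
) -> SegmentationMask:
    """Apply edits in order; later edits override earlier ones."""
    labels = mask.labels.copy()
    shape = mask.shape
    for edit in edits:
        for p in list(edit.add) + list(edit.remove):
            if any(c < 0 or c >= s for c, s in zip(p, shape)):
                raise IndexError(f"edit voxel {p} outside grid {shape}")
        for p in edit.add:
            labels[p] = edit.label
        for p in edit.remove:
            if labels[p] == edit.label:
                labels[p] = 0
    return SegmentationMask(labels=labels, affine=mask.affine)


def delineate(
    volume: LabeledVolume,
    seed_sets: Sequence[SeedSet],
    smooth_radius: int = 1,
    edits: Iterable[ManualEdit] = (),
) -> SegmentationMask:
    """Full delineation pipeline: grow each seed set, smooth, merge, edit.

    Labels are merged tumor-wins; the smoothing pass fills the interior
    speckle that a conservative growing tolerance leaves behind in noisy
    volumes.
    """
    merged = np.zeros(volume.shape, dtype=np.int16)
    for seeds in seed_sets:
        grown = region_grow(volume, seeds)
        grown = smooth_mask(grown, smooth_radius)
        sel = grown.labels == seeds.label
        if seeds.label == LABEL_TUMOR:
            merged[sel] = seeds.label
        else:
            merged[sel & (merged == 0)] = seeds.label
    mask = SegmentationMask(labels=merged, affine=volume.affine)
    return apply_manual_edits(mask, edits)
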