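"""Volume and mask I/O, coordinate conventions, and imaging slice geometry.

All world coordinates are millimetres in a right-handed RAS+ frame
(+x right, +y anterior, +z superior); any NIfTI affine is reoriented to the
closest canonical RAS form on read.  Voxel indices are 0-based.  A slice
frame partitions world space into half-open slabs ``[lower, upper)`` along
its stacking normal, so every voxel belongs to exactly one slab.

The default slice geometry matches an axial DWI acquisition: 5 mm slice
thickness, 0 mm inter-slice gap, slices ordered cranial to caudal (the
stacking normal points caudal, i.e. -z in RAS).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

LABEL_BACKGROUND = 0
LABEL_KIDNEY = 1
LABEL_TUMOR = 2

#: default slice geometry (axial DWI)
DEFAULT_THICKNESS_MM = 5.0
DEFAULT_GAP_MM = 0.0


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a 3-D volume."""


@dataclass
class LabeledVolume:
    """A 3-D intensity grid with a voxel-index -> world-mm affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D volume, got {self.voxels.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm."""
        idx = np.atleast_2d(idx).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class SegmentationMask:
    """Integer label grid (0 background, 1 kidney, 2 tumor) sharing a volume's geometry."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise VolumeFormatError("mask must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        extra = set(np.unique(self.labels)) - {LABEL_BACKGROUND, LABEL_KIDNEY, LABEL_TUMOR}
        if extra:
            raise ValueError(f"unexpected labels {sorted(extra)}")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def indicator(self, labels: int | set[int] | None = None) -> np.ndarray:
        """Boolean grid of the selected labels (default: any foreground)."""
        if labels is None:
            return self.labels > 0
        if isinstance(labels, int):
            labels = {labels}
        return np.isin(self.labels, sorted(labels))

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class SliceFrame:
    """Imaging slice geometry: stacking normal, in-plane axes, origin and pitch.

    ``origin`` is the world point on the lower (cranial) face of the first
    slab; slab ``i`` covers the half-open interval
    ``[i * pitch, i * pitch + thickness)`` of the signed distance
    ``(p - origin) . normal``, where ``pitch = thickness + gap``.
    """

    normal: np.ndarray
    in_plane_axes: tuple[np.ndarray, np.ndarray]
    origin: np.ndarray
    thickness: float = DEFAULT_THICKNESS_MM
    gap: float = DEFAULT_GAP_MM
    n_slices: int = 1

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        u, v = (np.asarray(a, dtype=float) for a in self.in_plane_axes)
        self.in_plane_axes = (u, v)
        if self.thickness <= 0:
            raise ValueError("slice thickness must be > 0")
        if self.gap < 0:
            raise ValueError("slice gap must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        for vec in (self.normal, u, v):
            n = np.linalg.norm(vec)
            if not np.isclose(n, 1.0, atol=1e-9):
                raise ValueError("frame axes must be unit vectors")
        if abs(np.dot(self.normal, u)) > 1e-9 or abs(np.dot(self.normal, v)) > 1e-9:
            raise ValueError("in-plane axes must be orthogonal to the normal")

    @property
    def pitch(self) -> float:
        return self.thickness + self.gap

    def slab_index(self, points: np.ndarray) -> np.ndarray:
        """Slab index per world point; -1 for points in a gap or outside the stack."""
        d = (np.atleast_2d(points) - self.origin) @ self.normal
        k = np.floor(d / self.pitch).astype(int)
        within = (d - k * self.pitch) < self.thickness
        ok = within & (k >= 0) & (k < self.n_slices)
        return np.where(ok, k, -1)

    def flipped(self) -> "SliceFrame":
        """The same slab stack traversed in the opposite direction."""
        far = self.origin + self.normal * (
            (self.n_slices - 1) * self.pitch + self.thickness
        )
        return replace(
            self,
            normal=-self.normal,
            in_plane_axes=(self.in_plane_axes[1], self.in_plane_axes[0]),
            origin=far,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> LabeledVolume:
    """Read a 3-D NIfTI volume, reoriented to canonical RAS+."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path!r} as NIfTI: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path!r}: expected a 3-D image, got shape {data.shape}"
        )
    return LabeledVolume(voxels=data, affine=np.asarray(img.affine))


def read_mask(path) -> SegmentationMask:
    """Read a multi-label segmentation mask from NIfTI."""
    vol = read_volume(path)
    return SegmentationMask(labels=np.rint(vol.voxels).astype(np.int16), affine=vol.affine)


def write_volume(vol: LabeledVolume | SegmentationMask, path) -> None:
    data = vol.voxels if isinstance(vol, LabeledVolume) else vol.labels
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


# ---------------------------------------------------------------------------
# Slice frames
# ---------------------------------------------------------------------------

_AXIS_VECTORS = {
    # stacking normals in RAS; axial stacks cranial->caudal hence -z
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
    "axial": np.array([0.0, 0.0, -1.0]),
}


def _in_plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis completing a right-handed triad."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(normal, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, normal)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def slice_frame_from(
    source: SegmentationMask | LabeledVolume,
    thickness_mm: float = DEFAULT_THICKNESS_MM,
    gap_mm: float = DEFAULT_GAP_MM,
    normal: np.ndarray | str = "axial",
    labels: set[int] | int | None = None,
) -> SliceFrame:
    """Derive the slice stack covering a mask's extent along the stacking normal.

    The number of slabs is ``ceil(extent / (thickness + gap))`` where the
    extent is measured over the selected labels (default: the kidney+tumor
    union) including the half-voxel on either side of the outermost voxel
    centres.  The origin is placed at the cranial end so slabs run cranial
    to caudal.

    Parameters
    ----------
    source:
        Mask (extent from its foreground labels) or volume (extent from
        non-zero voxels).
    thickness_mm, gap_mm:
        Slab thickness and inter-slab gap in mm.
    normal:
        Stacking direction: an axis name (``"axial"``/``"x"``/``"y"``/``"z"``)
        or an explicit 3-vector in world mm.
    labels:
        Label subset defining the extent when ``source`` is a mask.
    """
    if thickness_mm <= 0:
        raise ValueError("slice thickness must be > 0")
    if isinstance(normal, str):
        try:
            n = _AXIS_VECTORS[normal.lower()]
        except KeyError:
            raise ValueError(f"unknown slice orientation {normal!r}") from None
    else:
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)

    if isinstance(source, SegmentationMask):
        fg = source.indicator(labels)
    else:
        fg = np.asarray(source.voxels) != 0
    idx = np.argwhere(fg)
    if idx.size == 0:
        raise ValueError("source has no foreground voxels to span")
    pts = source.world_coords(idx)
    d = pts @ n
    # half-voxel step of a voxel footprint projected on the normal
    step = float(np.abs(source.affine[:3, :3].T @ n).max())
    extent = float(d.max() - d.min()) + step
    pitch = thickness_mm + gap_mm
    n_slices = int(np.ceil(extent / pitch - 1e-9))
    centroid = pts.mean(axis=0)
    d0 = d.min() - step / 2.0
    origin = centroid + (d0 - centroid @ n) * n
    u, v = _in_plane_basis(n)
    return SliceFrame(
        normal=n,
        in_plane_axes=(u, v),
        origin=origin,
        thickness=thickness_mm,
        gap=gap_mm,
        n_slices=max(n_slices, 1),
    )


@dataclass
class SliceStack:
    """Rasterised 2-D slab masks sharing one in-plane pixel grid.

    Behaves as an ordered sequence of 2-D boolean arrays (slab 0 = most
    cranial).  ``pixel_mm`` is the in-plane pixel size; pixel ``(0, 0)``
    sits at in-plane offset ``(u0, v0)`` mm from the frame origin.
    """

    masks: list[np.ndarray]
    pixel_mm: float
    frame: SliceFrame
    uv_offset: tuple[float, float] = (0.0, 0.0)

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, i):
        return self.masks[i]

    def __iter__(self):
        return iter(self.masks)

    def areas_mm2(self) -> np.ndarray:
        return np.array([m.sum() * self.pixel_mm**2 for m in self.masks])


def resample_mask_to_frame(
    mask: SegmentationMask,
    frame: SliceFrame,
    labels: set[int] | int | None = LABEL_TUMOR,
    pixel_mm: float | None = None,
    pad_px: int = 4,
) -> SliceStack:
    """Bin mask voxels into the frame's slabs and rasterise each slab in-plane.

    Each voxel is assigned to the slab containing its centre (half-open slab
    intervals, so no voxel lands in two slabs).  Returns exactly
    ``frame.n_slices`` 2-D masks; slabs not intersecting the selected labels
    are empty arrays on the common grid.
    """
    if pixel_mm is None:
        # coarsest voxel lattice step projected on the in-plane axes, so
        # voxel-centre binning leaves no holes
        cols = mask.affine[:3, :3]
        u_, v_ = frame.in_plane_axes
        pixel_mm = float(
            max(np.abs(cols.T @ u_).max(), np.abs(cols.T @ v_).max())
        )
    fg = mask.indicator(labels)
    idx = np.argwhere(fg)
    n, (u, v) = frame.normal, frame.in_plane_axes

    if idx.size == 0:
        import warnings

        warnings.warn("empty mask: returning empty slices", stacklevel=2)
        empty = np.zeros((1, 1), dtype=bool)
        return SliceStack([empty.copy() for _ in range(frame.n_slices)], pixel_mm, frame)

    pts = mask.world_coords(idx)
    rel = pts - frame.origin
    a, b = rel @ u, rel @ v
    u0, v0 = float(a.min()) - pad_px * pixel_mm, float(b.min()) - pad_px * pixel_mm
    ia = np.floor((a - u0) / pixel_mm).astype(int)
    ib = np.floor((b - v0) / pixel_mm).astype(int)
    shape = (int(ia.max()) + 1 + pad_px, int(ib.max()) + 1 + pad_px)

    slab = frame.slab_index(pts)
    masks = [np.zeros(shape, dtype=bool) for _ in range(frame.n_slices)]
    ok = slab >= 0
    for k, x, y in zip(slab[ok], ia[ok], ib[ok]):
        masks[k][x, y] = True
    return SliceStack(masks, pixel_mm, frame, uv_offset=(u0, v0))
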