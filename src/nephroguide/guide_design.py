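"""Patient-specific cutting-guide geometry.

The guide is built in its own coordinate frame: +x points cranial ("cranial
side of the tumor to the right"), +z is the open side where the renal hilum
faces up, and y completes a right-handed triad.  The specimen mesh is placed
by a rigid transform (rotation + translation, no scaling); the base is a box
grown by a margin around the specimen with a clearance-dilated cavity that
is open on top, and a knife slot at every slab boundary.  Barriers (the
walls between consecutive slots) sit at the imaging slice pitch and are
alternately assigned to color groups A/B; the two barriers flanking the
slab of maximal specimen cross-section are realised as separate printable
parts so the pathologist can reposition them while slicing.

Solid geometry is done on a regular voxel grid (occupancy resampled from
the segmentation, Euclidean-distance dilation for the clearance, boolean
slot subtraction) and surfaced with marching cubes, which yields watertight
meshes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volume_io import SegmentationMask, SliceFrame

DEFAULT_SLOT_WIDTH_MM = 2.0
DEFAULT_CLEARANCE_MM = 1.0
DEFAULT_WALL_MM = 3.0
DEFAULT_MARGIN_MM = 10.0
DEFAULT_CSG_PITCH_MM = 1.0
#: barrier fits a slot with this much play on either side
BARRIER_FIT_PLAY_MM = 0.2
#: warn above this bounding-box edge (typical FFF build volume)
PRINTABLE_LIMIT_MM = 300.0


class ConfigurationError(ValueError):
    pass


class MeshExportError(RuntimeError):
    pass


@dataclass
class SpecimenModel:
    """Closed surface of the kidney+tumor union in guide coordinates."""

    surface: trimesh.Trimesh
    hilum_point: np.ndarray
    cranial_axis: np.ndarray
    # source voxel data, kept so downstream CSG can resample occupancy exactly
    source_mask: SegmentationMask | None = None
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.hilum_point = np.asarray(self.hilum_point, dtype=float)
        self.cranial_axis = np.asarray(self.cranial_axis, dtype=float)
        diag = float(np.linalg.norm(self.surface.extents))
        if np.linalg.norm(self.hilum_point - self.surface.centroid) > 2 * diag:
            raise ConfigurationError("hilum point implausibly far from specimen")


@dataclass
class Barrier:
    """One guide barrier: its cranial-face position along the slicing axis."""

    position: float
    movable: bool
    color_group: str  # "A" or "B", alternating


@dataclass
class GuideModel:
    """Printable cutting guide: base mesh, barrier bookkeeping, movable parts."""

    base: trimesh.Trimesh
    barriers: list[Barrier]
    slot_width: float
    compass: np.ndarray  # 4x4 pose of the embossed orientation marker
    frame: SliceFrame
    movable_meshes: list[trimesh.Trimesh] = field(default_factory=list)
    # voxelised cavity (clearance-dilated specimen), for containment QC
    cavity_grid: np.ndarray | None = None
    grid_origin: np.ndarray | None = None
    grid_pitch: float = DEFAULT_CSG_PITCH_MM
    warnings: list[str] = field(default_factory=list)

    def barrier_positions(self) -> np.ndarray:
        return np.array([b.position for b in self.barriers])


# ---------------------------------------------------------------------------
# Surface extraction
# ---------------------------------------------------------------------------

def extract_surface(
    mask: SegmentationMask, labels: set[int] | int | None = None
) -> trimesh.Trimesh:
    """Closed triangle mesh of the selected labels at iso-level 0.5, in world mm.

    The binary indicator is zero-padded by one voxel so marching cubes always
    closes the surface, then vertices are mapped through the mask affine.
    """
    ind = mask.indicator(labels)
    if not ind.any():
        raise ValueError("empty label selection: nothing to extract")
    padded = np.pad(ind.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts -= 1.0  # undo padding offset, back to voxel-index space
    world = verts @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=True)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def orient_specimen(
    mask: SegmentationMask,
    frame: SliceFrame,
    hilum: np.ndarray | None,
    labels: set[int] | None = None,
) -> tuple[SpecimenModel, np.ndarray]:
    """Rigidly place the specimen into guide coordinates.

    The cranial direction (opposite the frame's cranial-to-caudal stacking
    normal) maps to +x; the hilum direction from the specimen centroid maps
    to +z (the open side); translation centres the hilum on the slicing axis
    (hilum x = 0).  Returns the oriented model and the 4x4 rigid transform
    (determinant +1, no scaling).
    """
    if hilum is None:
        raise ConfigurationError(
            "renal hilum position is required to orient the cutting guide"
        )
    hilum = np.asarray(hilum, dtype=float)
    fg = mask.indicator(labels)
    if not fg.any():
        raise ValueError("mask is empty")
    centroid = mask.world_coords(np.argwhere(fg)).mean(axis=0)

    x_axis = -frame.normal  # cranial
    x_axis = x_axis / np.linalg.norm(x_axis)
    hdir = hilum - centroid
    hperp = hdir - np.dot(hdir, x_axis) * x_axis
    if np.linalg.norm(hperp) < 1e-9:
        raise ConfigurationError(
            "hilum lies on the slicing axis; open-side direction undefined"
        )
    z_axis = hperp / np.linalg.norm(hperp)
    y_axis = np.cross(z_axis, x_axis)
    rot = np.vstack([x_axis, y_axis, z_axis])  # rows: world -> guide

    t = np.zeros(3)
    t[0] = -float(rot[0] @ hilum)  # hilum centred along the slicing axis
    transform = np.eye(4)
    transform[:3, :3] = rot
    transform[:3, 3] = t

    surface = extract_surface(mask, labels)
    surface.apply_transform(transform)
    model = SpecimenModel(
        surface=surface,
        hilum_point=rot @ hilum + t,
        cranial_axis=np.array([1.0, 0.0, 0.0]),
        source_mask=mask,
        transform=transform,
    )
    return model, transform


# ---------------------------------------------------------------------------
# Guide construction (voxel CSG)
# ---------------------------------------------------------------------------

def _occupancy_grid(
    model: SpecimenModel, origin: np.ndarray, shape: tuple[int, int, int], pitch: float
) -> np.ndarray:
    """Specimen occupancy on the guide CSG grid, resampled from the source mask."""
    mask = model.source_mask
    if mask is None:
        raise ValueError("model lacks source voxel data for CSG")
    ii, jj, kk = np.meshgrid(
        *(origin[a] + pitch * (np.arange(shape[a]) + 0.5) for a in range(3)),
        indexing="ij",
    )
    pts_guide = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    inv = np.linalg.inv(model.transform)
    pts_world = pts_guide @ inv[:3, :3].T + inv[:3, 3]
    vox = np.linalg.solve(
        mask.affine[:3, :3], (pts_world - mask.affine[:3, 3]).T
    ).T
    ind = mask.indicator(None).astype(np.uint8)
    occ = ndimage.map_coordinates(ind, vox.T, order=0, mode="constant", cval=0)
    return occ.reshape(shape).astype(bool)


def _grid_to_mesh(grid: np.ndarray, origin: np.ndarray, pitch: float) -> trimesh.Trimesh:
    padded = np.pad(grid.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0 + 0.5) * pitch + origin  # +0.5: cell centres
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def build_guide(
    model: SpecimenModel,
    frame: SliceFrame,
    slot_width: float = DEFAULT_SLOT_WIDTH_MM,
    clearance: float = DEFAULT_CLEARANCE_MM,
    wall: float = DEFAULT_WALL_MM,
    margin: float = DEFAULT_MARGIN_MM,
    csg_pitch: float = DEFAULT_CSG_PITCH_MM,
) -> GuideModel:
    """Construct the guide base, barrier array and movable parts.

    ``frame.n_slices + 1`` barrier planes orthogonal to the slicing axis are
    placed at the slice pitch (= thickness), each carrying a knife slot of
    ``slot_width``; the base is the specimen bounding box grown by ``margin``
    minus the clearance-dilated cavity (open on +z) and the slots, which stop
    ``wall`` mm above the floor so the base stays one connected part.
    """
    for name, val in (("slot_width", slot_width), ("clearance", clearance),
                      ("wall", wall), ("margin", margin), ("csg_pitch", csg_pitch)):
        if val <= 0:
            raise ValueError(f"{name} must be > 0")

    bmin, bmax = model.surface.bounds
    box_min, box_max = bmin - margin, bmax + margin
    warnings_: list[str] = []
    if np.any(box_max - box_min > PRINTABLE_LIMIT_MM):
        warnings_.append(
            f"guide exceeds the {PRINTABLE_LIMIT_MM:.0f} mm printable bound: "
            f"{np.round(box_max - box_min, 1).tolist()} mm"
        )

    shape = tuple(int(np.ceil((box_max[a] - box_min[a]) / csg_pitch)) for a in range(3))
    origin = box_min
    occ = _occupancy_grid(model, origin, shape, csg_pitch)

    # clearance dilation via Euclidean distance to the specimen
    dist = ndimage.distance_transform_edt(~occ, sampling=csg_pitch)
    cavity = dist <= clearance

    # open the cavity on +z: clear every cell above the cavity's top surface
    open_above = np.flip(np.maximum.accumulate(np.flip(cavity, axis=2), axis=2), axis=2)
    cavity_open = open_above

    # barrier planes sit on the slab boundaries of the imaging frame: the
    # frame origin (cranial face of slab 0) mapped into guide coordinates,
    # advancing caudally (-x) at the slice pitch
    n_planes = frame.n_slices + 1
    origin_guide = model.transform[:3, :3] @ frame.origin + model.transform[:3, 3]
    x_cranial = float(origin_guide[0])
    plane_x = x_cranial - frame.thickness * np.arange(n_planes)

    centers = origin[0] + csg_pitch * (np.arange(shape[0]) + 0.5)
    zc = origin[2] + csg_pitch * (np.arange(shape[2]) + 0.5)
    slots = np.zeros(shape, dtype=bool)
    floor_keep = zc <= (box_min[2] + wall)  # slots never cut the floor
    for x in plane_x:
        sel = np.abs(centers - x) <= slot_width / 2.0
        slots[sel] = True
    slots &= ~floor_keep[None, None, :]

    base_grid = ~(cavity_open | slots)
    base = _grid_to_mesh(base_grid, origin, csg_pitch)

    # slab of maximal specimen cross-section -> movable barriers flank it;
    # slab areas come from the same resampling volume_io uses, keeping the
    # two modules' slab accounting identical
    from .volume_io import resample_mask_to_frame

    slab_area = resample_mask_to_frame(
        model.source_mask, frame, labels=None
    ).areas_mm2()
    k_max = int(np.argmax(slab_area))
    movable_planes = {k_max, k_max + 1}

    barriers = [
        Barrier(
            position=float(plane_x[k]),
            movable=k in movable_planes,
            color_group="A" if k % 2 == 0 else "B",
        )
        for k in range(n_planes)
    ]

    # movable barriers: rectangular parts that drop into any slot
    bw = max(slot_width - 2 * BARRIER_FIT_PLAY_MM, csg_pitch)
    by = box_max[1] - box_min[1]
    bz = box_max[2] - (box_min[2] + wall)
    movable_meshes = []
    for k in sorted(movable_planes):
        part = trimesh.creation.box(extents=(bw, by, bz))
        part.apply_translation(
            [plane_x[k], (box_min[1] + box_max[1]) / 2.0, box_min[2] + wall + bz / 2.0]
        )
        movable_meshes.append(part)

    # compass pose: embossed marker on the cranial rim of the base, arrow +x
    compass = np.eye(4)
    compass[:3, 3] = [x_cranial + margin / 2.0, (box_min[1] + box_max[1]) / 2.0, box_max[2]]

    return GuideModel(
        base=base,
        barriers=barriers,
        slot_width=slot_width,
        compass=compass,
        frame=frame,
        movable_meshes=movable_meshes,
        cavity_grid=cavity,
        grid_origin=origin,
        grid_pitch=csg_pitch,
        warnings=warnings_,
    )


def protruding_vertices(guide: GuideModel, model: SpecimenModel) -> int:
    """Number of specimen-surface vertices outside the clearance cavity."""
    if guide.cavity_grid is None:
        raise ValueError("guide carries no cavity grid")
    rel = (model.surface.vertices - guide.grid_origin) / guide.grid_pitch - 0.5
    inside = ndimage.map_coordinates(
        guide.cavity_grid.astype(np.uint8), rel.T, order=0, mode="constant", cval=0
    )
    return int((inside == 0).sum())


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _check_printable(mesh: trimesh.Trimesh, name: str) -> None:
    if not mesh.is_watertight:
        raise MeshExportError(f"{name}: mesh is not watertight after repair")
    if mesh.volume <= 0:
        raise MeshExportError(f"{name}: inconsistent (inward) face normals")


def export_stl(guide: GuideModel, path_prefix) -> list[str]:
    """Write one binary STL per printable part; returns the file paths.

    Parts: ``<prefix>_base.stl`` plus ``<prefix>_movable1.stl`` /
    ``_movable2.stl``.  Export is refused with a diagnostic if any mesh is
    not watertight or has inward-pointing normals.
    """
    prefix = str(path_prefix)
    parts = [("base", guide.base)] + [
        (f"movable{i + 1}", m) for i, m in enumerate(guide.movable_meshes)
    ]
    paths = []
    for name, mesh in parts:
        _check_printable(mesh, name)
        out = f"{prefix}_{name}.stl"
        mesh.export(out)
        paths.append(out)
    return paths


def guide_sidecar(guide: GuideModel, transform: np.ndarray | None = None) -> dict:
    """JSON-serialisable record of barrier positions, colors and the rigid pose."""
    return {
        "slot_width_mm": guide.slot_width,
        "slice_thickness_mm": guide.frame.thickness,
        "n_slabs": guide.frame.n_slices,
        "barriers": [
            {"position_mm": b.position, "movable": b.movable, "color_group": b.color_group}
            for b in guide.barriers
        ],
        "compass_pose": guide.compass.tolist(),
        "rigid_transform": None if transform is None else np.asarray(transform).tolist(),
        "warnings": guide.warnings,
    }
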