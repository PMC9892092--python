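# Methods

## Coordinate conventions and slice geometry

World coordinates are millimetres in a right-handed RAS+ frame (+x right,
+y anterior, +z superior). Any NIfTI affine is reoriented to the closest
canonical RAS form on read, so downstream code sees one handedness. Voxel
indices are 0-based.

A *slice frame* models the imaging stack: a unit stacking normal, two
orthonormal in-plane axes, the world point of the first slab's cranial
face, slab thickness and inter-slab gap. Defaults are the axial DWI
geometry the guide is matched to: 5 mm thickness, 0 mm gap, slabs ordered
cranial to caudal (normal −z). Slabs are half-open intervals
`[k·pitch, k·pitch + thickness)` of the signed distance from the origin, so
every voxel belongs to exactly one slab and slice accounting is
deterministic. The slab count is `ceil(extent / pitch)` where the extent is
measured over the kidney+tumor union (the guide and the target-slice count
are specimen-relative, not image-relative), including the half-voxel on
either side of the outermost voxel centres so that a mask occupying exactly
40 mm of world space yields 8 slabs and 41 mm yields 9. Which labels define
the extent is configurable (`labels=` on `slice_frame_from`); the union is
the default.

Resampling a mask into a frame bins voxel centres by slab and rasterises
each slab's in-plane footprint on a common pixel grid (default pixel: the
coarsest voxel-lattice step projected on the in-plane axes, so binning
leaves no holes). The 2-D slab mask is therefore the *union* of the
footprints of the voxel layers inside the slab; summed slab areas times
thickness consequently overestimate the voxel volume by up to one voxel
layer per slab, which is the documented discretisation bound.

## Segmentation

Region growing reproduces the semiautomatic delineation protocol: the
reference intensity is the mean over the seed voxels, a voxel is admissible
when it lies within a symmetric tolerance of the reference, and the output
is the union of 26-connected admissible components containing the seeds.
26-connectivity was chosen over 6-connectivity to avoid artifactual
disconnections of thin structures; the homogeneity criterion (seed-mean ±
tolerance) is the common contract of interactive tools.

The "averaging filter" smoothing of a binary delineation is implemented as
the box mean of the indicator over a `(2r+1)³` window re-thresholded at
0.5 (computed with integer counts, so the threshold is exact; the window is
odd, so ties cannot occur). Radius 0 is the identity; voxels outside the
grid count as background. Kidney and tumor are grown independently and
merged tumor-wins.

On the default phantom the tumor–kidney contrast is 3 noise sigmas
(30 intensity units vs. σ = 10). This makes the tolerance choice a real
trade-off rather than a formality: the fraction of *kidney* voxels that
fall inside the admissible band must stay below the site-percolation
threshold of the 26-connected lattice (≈ 0.097), otherwise the grown region
floods through the boundary. A tolerance of 1.5 σ keeps the kidney
in-band fraction at ≈ 0.067 (no long-range leakage) at the cost of
≈ 13 % interior speckle holes in the tumor, which the smoothing pass is
there to fill. The validated delineation pipeline is therefore
grow-then-smooth (`delineate`), exactly as the clinical protocol applies
the averaging filter after region growing; with a 27-voxel seed block the
pipeline recovers the phantom tumor at mean dice ≈ 0.98 over 10 noise
seeds. A single seed voxel is insufficient at this contrast because the
reference intensity itself is then a draw from N(tumor, σ) and a 1.5 σ
reference error either floods the kidney or truncates the tumor.

## Cutting-guide geometry

Guide coordinates: +x cranial ("cranial side of the tumor to the right"),
+z the open side where the renal hilum faces up, y completing a
right-handed triad. Orientation is a rigid transform (rotation +
translation, determinant +1): the cranial direction (opposite the stacking
normal) maps to +x, the hilum direction from the specimen centroid —
projected perpendicular to the slicing axis — maps to +z, and the
translation centres the hilum on the slicing axis (hilum x = 0). A hilum
point is required; there is no silent default. A hilum lying exactly on the
slicing axis leaves the open-side direction undefined and is rejected.

The base is the specimen bounding box grown by `margin` (default 10 mm)
with a cavity formed by dilating the specimen occupancy by `clearance`
(default 1 mm, Euclidean distance), opened on +z, and a knife slot of
`slot_width` (default 2 mm) at every slab boundary. Slots stop `wall`
(default 3 mm) above the floor so the base remains a single printable part.
Barrier planes — `n_slices + 1` of them — sit on the slab boundaries of the
imaging frame mapped into guide coordinates, at exactly the slice pitch;
the two barriers flanking the slab of maximal specimen cross-section
(computed with the same resampling the slice accounting uses, keeping the
two modules consistent) are realised as separate drop-in rectangular parts
so the pathologist can reposition them while slicing. Barrier color groups
alternate A/B as metadata (single-extruder STL carries no color; the groups
name the part files). The compass is a pose on the cranial rim recorded in
the sidecar. None of these dimensions is prescribed by the clinical
protocol; the defaults suit a standard macro-knife blade and fused-filament
tolerances and are all configurable.

Solid geometry is done on a regular voxel grid (default 1 mm): occupancy is
resampled from the source segmentation through the inverse rigid transform,
the clearance dilation is an exact Euclidean distance transform, and slots
are boolean cell subtractions. Surfaces come from marching cubes on the
zero-padded grid, which yields watertight, consistently oriented meshes by
construction — no mesh-boolean backend is needed, and identical inputs
produce byte-identical STL output. The trade-off is a ~half-cell surface
quantisation; outer base dimensions are preserved to within one grid cell.
Export refuses non-watertight or inverted meshes with a diagnostic.

## Registration and overlap QC

Macro-photo tumor masks are registered to MRI slice masks with a similarity
transform `y = s·R(θ)·x + t` (no reflection: the compass fixes the
photograph orientation). Initialisation is from image moments: translation
from the centroid difference, scale from the square root of the area ratio,
rotation from the principal axes with both π-ambiguous candidates scored by
dice. Refinement maximises dice directly: a coarse ±10° sweep at 1° steps
around the moment angle, then a shrinking coordinate pattern search
(6 halvings from steps of 0.02 in scale, 1° in rotation, 1 mm in
translation), parameterised by (scale, rotation, image of the moving
centroid) so the parameters stay decoupled. Dice of two binary masks is
`2|A∩B|/(|A|+|B|)`; the empty–empty case is defined as 1.0 (vacuous
agreement) and flagged. Near-circular masks (principal-moment ratio
< 1.05) are flagged as rotation-degenerate; their angle is fixed only by
the dice tie-break.

Parameter-recovery comparisons are made in a centroid-anchored
parameterisation (scale, rotation, and the image of the moving mask's
centroid) because the raw translation vector about the pixel origin
amplifies any angular error by the centroid's lever arm and is not a
meaningful accuracy measure.

Per patient, dice is scored on the four macro slices of largest tumor area
— a deterministic stand-in for the study's manually chosen "representative
slices" — always including the largest one, whose dice feeds the inclusion
rule. When macro and MRI slice counts diverge, macro slices are matched to
MRI slices index-proportionally by default, or anchored to matched landmark
levels (`matching="landmark"`); the report records the registration per
slice. Whether dice uses tumor-only or tumor+kidney outlines is
configurable; tumor-only is the default.

Slice accounting: per-slice thickness is the mean of the two opposite-side
caliper readings taken along the longest diameter; per-patient statistics
are medians (even counts: mean of the middle two). The resulted/target
ratio is reported to one decimal, money to two (decimal half-even on the
printed precision, so a median landing exactly on a half-cent rounds the
way the tables print), dice to three. Landmark concordance counts a
landmark as matched when its pathology slice level is within ±1 slice
(configurable) of the radiology level; landmarks absent from pathology
count toward the total only.

The inclusion rule is a conjunction — slice ratio ≥ 75 %, largest-tumor
slice dice ≥ 0.800, MRI-to-surgery interval ≤ 14 days, no interim
chemotherapy — with every failed criterion emitted as a reason code. All
bounds are inclusive (the rule excludes strictly below / strictly above),
and the decision is monotone: improving any single criterion never flips
include to exclude.

## Phantom generator

The phantom emulates a post-contrast T1 kidney+tumor volume: a kidney
ellipsoid (default semi-axes 30×25×45 mm, long axis cranial–caudal), a
two-lobed tumor (a 22×18×25 mm ellipsoid plus a 13×11×16 mm lobe) displacing
the upper pole, intensity levels background 30 / kidney 90 / tumor 120 in
arbitrary units with Gaussian noise σ = 10, an optional non-enhancing
necrotic core (intensity 45) carved at a requested volume fraction, and a
hilum point on the medial kidney surface. The second lobe exists because a
pure ellipsoid is 180°-rotationally symmetric in-plane, which makes
rotation recovery ill-posed; real nephroblastoma outlines are lobulated.
The grid (96³ at 1.5 mm; 128³ at 1 mm for registration tests) is a
scaled-down but anatomically proportioned specimen chosen to keep the full
suite fast while leaving >10 slabs per specimen. Everything is
seed-deterministic.

Macro-slice simulation models the failure modes of physical slicing: each
slab's tumor mask is perturbed by a similarity transform drawn per slice
(the pose of the photographed slice on the table; defaults scale 0.9–1.1,
rotation ±20°, translation ≤ 10 mm), optionally deformed by a smoothed
random displacement field whose amplitude parameter is the maximum contour
displacement in mm (weak specimen consistency), given caliper readings with
Gaussian jitter, and — with a configurable probability — merged with its
cranial neighbour to mimic thicker-than-intended cuts, which is what drives
the resulted count below the target. All draws and ground-truth transforms
are recorded. What the phantom does **not** model: MRI physics (bias
fields, DWI signal), perinephric fat and specimen collapse, photographic
texture, and inter-observer delineation variability — so passing tests
demonstrate the correctness of the geometry, registration and accounting
machinery, not clinical-grade robustness on real photographs.

The packaged cohort tables encode the eight-patient study's per-patient
values (age/sex/stage, printing cost, slice counts, thickness statistics,
dice ranges, landmark counts). Cells that are ambiguous in the source
(run-together design/print times and some volumes) are omitted rather than
guessed. The quoted 59.4–90.3 % slice-ratio range is computed over the
seven patients whose resulted count diverged from the target; one patient
sliced exactly to target (100 %) and is outside that range by definition.
The study's overall median dice (over 32 individual slices) is *not*
recomputable from per-patient averages and ranges and is deliberately not
reported.

## Problem sizes and tolerances

Registration recovery is assessed on 50 slices from the 1 mm phantom with
transforms drawn from scale 0.8–1.25, rotation ±45°, translation ≤ 20 mm;
recovery means post-registration dice ≥ 0.95 and parameter errors within
(0.02, 2°, 1 mm). Segmentation recovery averages dice over 10 noise seeds
of the default phantom. Guide geometry is checked on 38/40/41 mm extents
(8/8/9 slabs) with barrier pitch exact to 1e-9 and zero specimen vertices
outside the clearance cavity (evaluated on the CSG grid, which is the
authoritative geometry). Mesh volumes are accepted within 5 % of analytic
values for voxelised spheres at 1 mm spacing.

## Known limitations

- The guide's open-side wall is a plain opened cavity; no hilum-contoured
  cutout or tenon/mortise slot mechanics beyond rectangular drop-ins.
- Voxel-CSG surfaces carry ~half-cell quantisation; for printing, the
  default 1 mm grid is below typical FFF nozzle resolution but the pitch is
  configurable.
- Registration assumes consistently oriented photographs (no reflection)
  and one connected tumor region per slice; two independent lesions violate
  the single-similarity model and are flagged by their low dice, not
  resolved.
- The landmark-anchored slice matching interpolates linearly between
  anchors; strongly non-uniform slab merging between anchors is not
  modelled.
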