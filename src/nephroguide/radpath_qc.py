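"""Quantitative radiology-histopathology correlation.

Macroscopic-slice tumor masks (photograph delineations) are registered to
the corresponding MRI slice masks with a similarity transform (rotation +
isotropic scale + translation; reflections excluded, since the compass on
the guide fixes the photograph orientation), overlap is scored with the
dice similarity coefficient (DSC, ``2|A&B| / (|A|+|B|)``; 0 = no overlap,
1 = perfect), slice thickness and slice-count accounting are summarised per
patient, anatomical-landmark levels are matched between modalities, and an
inclusion rule decides whether the specimen supports valid correlation:

* resulted slices >= 75% of the DWI target count,
* DSC of the slice with the largest tumor cross-section >= 0.800,
* <= 14 days between the preoperative MRI and the nephrectomy,
* no chemotherapy between MRI and surgery.

Registration is initialised from image moments (centroid difference,
sqrt-of-area-ratio scale, principal-axis rotation with both pi-ambiguous
candidates tried) and refined by maximising the DSC: a 1-degree coarse
rotation sweep followed by a coordinate pattern search over all four
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

DICE_GOOD_OVERLAP = 0.800
SLICE_RATIO_THRESHOLD_PCT = 75.0
MAX_DAYS_MRI_TO_SURGERY = 14
LANDMARK_TOLERANCE_SLICES = 1
N_REPRESENTATIVE_SLICES = 4


class GridError(ValueError):
    pass


class RegistrationError(ValueError):
    pass


class IncompleteReportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dice similarity coefficient
# ---------------------------------------------------------------------------

def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks on a common grid.

    ``2|A & B| / (|A| + |B|)``; two empty masks agree vacuously (1.0).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise GridError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


# ---------------------------------------------------------------------------
# Similarity registration
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTransform2D:
    """Rotation + isotropic scale + translation acting as ``y = s R x + t``.

    Coordinates are (row, col) pixel positions scaled by the pixel size, i.e.
    mm when the pixel size is supplied.  No reflection component.
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.translation = (float(self.translation[0]), float(self.translation[1]))

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.eye(3)
        m[:2, :2] = self.scale * np.array([[c, -s], [s, c]])
        m[:2, 2] = self.translation
        return m

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    def compose(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """``self`` after ``other``: (self o other)(x) = self(other(x))."""
        return _from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "SimilarityTransform2D":
        return _from_matrix(np.linalg.inv(self.matrix))


def _from_matrix(m: np.ndarray) -> SimilarityTransform2D:
    scale = float(np.hypot(m[0, 0], m[1, 0]))
    rot = float(np.arctan2(m[1, 0], m[0, 0]))
    return SimilarityTransform2D(scale=scale, rotation=rot, translation=(m[0, 2], m[1, 2]))


def warp_mask(
    mask: np.ndarray,
    tf: SimilarityTransform2D,
    out_shape: tuple[int, int] | None = None,
    pixel_mm: float = 1.0,
) -> np.ndarray:
    """Apply ``tf`` (mm units, row/col axes) to a binary mask.

    Bilinear interpolation of the indicator, re-thresholded at 0.5.  Pixel
    ``(i, j)`` sits at mm coordinate ``(i, j) * pixel_mm``.
    """
    out_shape = out_shape or mask.shape
    inv = np.linalg.inv(tf.matrix)
    # output pixel -> input pixel: x_in = (inv_rot @ x_out*pix + inv_t) / pix
    warped = ndimage.affine_transform(
        mask.astype(float),
        inv[:2, :2],
        offset=inv[:2, 2] / pixel_mm,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return warped >= 0.5


def _moments(mask: np.ndarray, pixel_mm: float):
    """Centroid (mm), area (mm^2) and principal-axis angle of a binary mask."""
    pts = np.argwhere(mask).astype(float) * pixel_mm
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    angle = float(np.arctan2(axis[1], axis[0]))
    anisotropy = float(evals.max() / max(evals.min(), 1e-12))
    return c, len(pts) * pixel_mm**2, angle, anisotropy

_NEAR_CIRCULAR_ANISOTROPY = 1.05


def _candidate(photo_c, mri_c, scale, theta) -> SimilarityTransform2D:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    t = mri_c - scale * rot @ photo_c
    return SimilarityTransform2D(scale=scale, rotation=theta, translation=tuple(t))


def estimate_similarity(
    photo: np.ndarray,
    mri: np.ndarray,
    pixel_mm: float = 1.0,
    refine: bool = True,
) -> tuple[SimilarityTransform2D, float, bool]:
    """Register a macro-photo mask onto an MRI slice mask.

    Moment initialisation (centroid translation, sqrt-of-area-ratio scale,
    principal-axis rotation with both pi-ambiguous candidates scored by DSC)
    followed by DSC maximisation: a coarse 1-degree rotation sweep around
    the initial angle, then a shrinking coordinate pattern search over
    (scale, rotation, translation).

    Returns ``(transform, dice_after, degenerate_flag)``; the flag marks
    near-circular masks whose rotation is fixed only by the DSC tie-break.
    """
    photo = np.asarray(photo).astype(bool)
    mri = np.asarray(mri).astype(bool)
    if not photo.any() or not mri.any():
        raise RegistrationError("cannot register an empty mask")

    pc, pa, pang, paniso = _moments(photo, pixel_mm)
    mc, ma, mang, _ = _moments(mri, pixel_mm)
    scale0 = float(np.sqrt(ma / pa))
    degenerate = paniso < _NEAR_CIRCULAR_ANISOTROPY

    def score(tf: SimilarityTransform2D) -> float:
        return dice(warp_mask(photo, tf, mri.shape, pixel_mm), mri)

    best_tf, best_d = None, -1.0
    for theta in (mang - pang, mang - pang + np.pi):
        tf = _candidate(pc, mc, scale0, theta)
        d = score(tf)
        if d > best_d:
            best_tf, best_d = tf, d

    if refine:
        # coarse rotation sweep at 1-degree steps around the moment angle
        for dtheta in np.deg2rad(np.arange(-10, 10.5, 1.0)):
            tf = _candidate(pc, mc, scale0, best_tf.rotation + dtheta)
            d = score(tf)
            if d > best_d:
                best_tf, best_d = tf, d

        # pattern search with shrinking steps, parameterised by
        # (scale, rotation, image of the photo centroid) so scale and
        # rotation updates do not drag the translation along
        center0 = best_tf.apply(pc)[0]
        params = np.array([best_tf.scale, best_tf.rotation, center0[0], center0[1]])
        steps = np.array([0.02, np.deg2rad(1.0), 1.0, 1.0])

        def build(p) -> SimilarityTransform2D:
            return _candidate(pc, np.array([p[2], p[3]]), p[0], p[1])

        for _ in range(6):
            improved = True
            while improved:
                improved = False
                for i in range(4):
                    for sgn in (1.0, -1.0):
                        trial = params.copy()
                        trial[i] += sgn * steps[i]
                        if trial[0] <= 0:
                            continue
                        tf = build(trial)
                        d = score(tf)
                        if d > best_d:
                            best_tf, best_d, params = tf, d, trial
                            improved = True
            steps /= 2.0

    return best_tf, best_d, degenerate


@dataclass
class CorrelationRecord:
    """Registration result for one macroscopic slice."""

    slice_index: int
    transform: SimilarityTransform2D
    dice: float
    matched_mri_slice: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError("dice must lie in [0, 1]")


def match_slices(
    n_macro: int, n_mri: int, method: str = "proportional",
    landmark_pairs: list[tuple[int, int]] | None = None,
) -> list[int]:
    """Map macro-slice index -> MRI slice index when the counts diverge.

    ``proportional`` spreads macro indices linearly over the MRI stack;
    ``landmark`` anchors the linear map to matched (macro, mri) landmark
    levels, interpolating between anchors.
    """
    if method == "proportional" or not landmark_pairs:
        if n_macro == 1:
            return [0]
        return [int(round(i * (n_mri - 1) / (n_macro - 1))) for i in range(n_macro)]
    if method != "landmark":
        raise ValueError(f"unknown matching method {method!r}")
    xs = [p[0] for p in landmark_pairs]
    ys = [p[1] for p in landmark_pairs]
    out = np.interp(np.arange(n_macro), xs, ys)
    return [int(round(min(max(v, 0), n_mri - 1))) for v in out]


# ---------------------------------------------------------------------------
# Slice accounting
# ---------------------------------------------------------------------------

def slice_thickness_stats(
    measurements: list[tuple[float, float]],
) -> tuple[float, float]:
    """Median per-slice thickness and median opposite-side difference (mm).

    Each slice is measured on two opposite sides along its longest diameter;
    per-slice thickness is the mean of the two sides.  Even-count medians
    are the mean of the middle two values.
    """
    if len(measurements) == 0:
        raise ValueError("at least one thickness pair required")
    arr = np.asarray(measurements, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("thickness measurements must be positive")
    thick = arr.mean(axis=1)
    diff = np.abs(arr[:, 0] - arr[:, 1])
    return float(np.median(thick)), float(np.median(diff))


def slice_count_ratio(n_resulted: int, n_target: int) -> float:
    """Resulted/target slice count as a percentage, to one decimal."""
    if n_target < 1:
        raise ValueError("target slice count must be >= 1")
    if n_resulted < 0:
        raise ValueError("resulted slice count must be >= 0")
    return round(100.0 * n_resulted / n_target, 1)


def landmark_concordance(
    radiology_levels: dict[str, int],
    pathology_levels: dict[str, int | None],
    tolerance: int = LANDMARK_TOLERANCE_SLICES,
) -> tuple[int, int]:
    """Count landmarks whose pathology slice level matches radiology.

    A landmark matches when its pathology level lies within ``tolerance``
    slices of the radiology level; landmarks absent on the pathology side
    (value ``None`` or missing key) count toward the total only.
    """
    unknown = set(pathology_levels) - set(radiology_levels)
    if unknown:
        raise ValueError(f"unknown landmark ids on pathology side: {sorted(unknown)}")
    total = len(radiology_levels)
    matched = 0
    for name, rlevel in radiology_levels.items():
        plevel = pathology_levels.get(name)
        if plevel is not None and abs(int(plevel) - int(rlevel)) <= tolerance:
            matched += 1
    return matched, total


# ---------------------------------------------------------------------------
# Per-patient report and inclusion rule
# ---------------------------------------------------------------------------

@dataclass
class PatientQCReport:
    """Per-patient slice accounting and correlation metrics."""

    patient_id: str
    median_thickness: float
    median_opposite_diff: float
    n_target: int
    n_resulted: int
    landmarks_matched: int
    landmarks_total: int
    dice_values: list[float]
    largest_slice_dice: float | None = None
    records: list[CorrelationRecord] = field(default_factory=list)
    include: bool | None = None
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_resulted < 0 or self.n_target < 1:
            raise ValueError("invalid slice counts")
        if self.landmarks_matched > self.landmarks_total:
            raise ValueError("matched landmarks exceed total")

    @property
    def slice_ratio_pct(self) -> float:
        return slice_count_ratio(self.n_resulted, self.n_target)

    @property
    def average_dice(self) -> float | None:
        return float(np.mean(self.dice_values)) if self.dice_values else None


def inclusion_decision(
    report: PatientQCReport,
    days_mri_to_surgery: int,
    chemo_between: bool,
    ratio_threshold_pct: float = SLICE_RATIO_THRESHOLD_PCT,
    dice_threshold: float = DICE_GOOD_OVERLAP,
    max_days: int = MAX_DAYS_MRI_TO_SURGERY,
) -> tuple[bool, list[str]]:
    """Decide whether the sliced specimen supports valid correlation.

    Include iff the resulted/target slice ratio is >= 75%, the DSC of the
    slice with the largest representative part of the tumor is >= 0.800,
    the MRI-to-surgery interval is <= 14 days and no chemotherapy was given
    in between.  Every failed criterion is emitted as a reason code.
    """
    if report.largest_slice_dice is None:
        raise IncompleteReportError(
            "largest-tumor-slice dice is missing from the report"
        )
    reasons = []
    if report.slice_ratio_pct < ratio_threshold_pct:
        reasons.append("slice-count")
    if report.largest_slice_dice < dice_threshold:
        reasons.append("overlap")
    if days_mri_to_surgery > max_days:
        reasons.append("interval")
    if chemo_between:
        reasons.append("chemotherapy")
    return (len(reasons) == 0), reasons


# ---------------------------------------------------------------------------
# Patient-level correlation driver
# ---------------------------------------------------------------------------

def correlate_patient(
    patient_id: str,
    mri_slices: list[np.ndarray],
    macro_slices: list[np.ndarray],
    thickness_pairs: list[tuple[float, float]],
    radiology_landmarks: dict[str, int] | None = None,
    pathology_landmarks: dict[str, int | None] | None = None,
    pixel_mm: float = 1.0,
    n_representative: int = N_REPRESENTATIVE_SLICES,
    matching: str = "proportional",
) -> PatientQCReport:
    """Register macro slices to MRI slices and assemble the QC report.

    DSC is scored on the ``n_representative`` macro slices of largest tumor
    area (the deterministic stand-in for the manually chosen representative
    slices), always including the largest one, whose DSC feeds the
    inclusion rule.
    """
    non_empty_mri = [i for i, m in enumerate(mri_slices) if np.asarray(m).any()]
    n_target = len(mri_slices)
    n_resulted = len(macro_slices)
    mapping = match_slices(n_resulted, n_target, method=matching)

    areas = np.array([int(np.asarray(m).sum()) for m in macro_slices])
    order = np.argsort(areas)[::-1]
    chosen = [int(i) for i in order[:n_representative] if areas[i] > 0]

    records: list[CorrelationRecord] = []
    for idx in sorted(chosen):
        mri_idx = mapping[idx]
        if not np.asarray(mri_slices[mri_idx]).any():
            # fall back to the nearest tumor-bearing MRI slice
            mri_idx = min(non_empty_mri, key=lambda j: abs(j - mri_idx))
        tf, d, degen = estimate_similarity(
            np.asarray(macro_slices[idx]), np.asarray(mri_slices[mri_idx]), pixel_mm
        )
        flags = ["degenerate-rotation"] if degen else []
        if d < DICE_GOOD_OVERLAP:
            flags.append("poor-overlap")
        records.append(CorrelationRecord(idx, tf, d, mri_idx, flags))

    med_t, med_d = slice_thickness_stats(thickness_pairs)
    matched, total = (
        landmark_concordance(radiology_landmarks, pathology_landmarks or {})
        if radiology_landmarks
        else (0, 0)
    )
    largest_idx = int(order[0]) if areas.size and areas[order[0]] > 0 else None
    largest_dice = None
    for r in records:
        if r.slice_index == largest_idx:
            largest_dice = r.dice
    return PatientQCReport(
        patient_id=patient_id,
        median_thickness=med_t,
        median_opposite_diff=med_d,
        n_target=n_target,
        n_resulted=n_resulted,
        landmarks_matched=matched,
        landmarks_total=total,
        dice_values=[r.dice for r in records],
        largest_slice_dice=largest_dice,
        records=records,
    )


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def reports_to_table(
    reports: list[PatientQCReport], metadata: dict[str, dict] | None = None
) -> pd.DataFrame:
    """Tidy per-patient table from QC reports plus optional metadata columns.

    ``metadata`` maps patient id to extra fields (e.g. ``age_months``,
    ``cost_eur``) merged into the table.
    """
    rows = []
    for r in reports:
        row = {
            "patient": r.patient_id,
            "median_thickness_mm": r.median_thickness,
            "median_opposite_diff_mm": r.median_opposite_diff,
            "n_target": r.n_target,
            "n_resulted": r.n_resulted,
            "slice_ratio_pct": r.slice_ratio_pct,
            "avg_dsc": r.average_dice,
            "landmarks_matched": r.landmarks_matched,
            "landmarks_total": r.landmarks_total,
        }
        if metadata and r.patient_id in metadata:
            row.update(metadata[r.patient_id])
        rows.append(row)
    return pd.DataFrame(rows)


def _round_half_even(value: float, ndigits: int) -> float:
    """Decimal round-half-even on the printed value, immune to float repr.

    A median of two 2-decimal costs can land exactly on a half (e.g.
    18.905), where binary floats push ``round`` the wrong way.
    """
    from decimal import ROUND_HALF_EVEN, Decimal

    q = Decimal(1).scaleb(-ndigits)
    # snap accumulated float error well below the table precision first
    return float(Decimal(repr(round(value, 6))).quantize(q, rounding=ROUND_HALF_EVEN))


_SUMMARY_COLUMNS = (
    "age_months",
    "cost_eur",
    "median_thickness_mm",
    "median_opposite_diff_mm",
    "slice_ratio_pct",
    "avg_dsc",
)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median and range of the cohort's per-patient quantities.

    Accepts a tidy per-patient table (see :func:`reports_to_table` or the
    packaged cohort fixture); money is rounded to 2 decimals, percentages
    to 1.  Landmark counts are summed, not averaged.
    """
    if len(table) == 0:
        raise ValueError("cohort is empty")
    rows = []
    for col in _SUMMARY_COLUMNS:
        if col not in table.columns:
            continue
        vals = table[col].dropna().astype(float)
        if vals.empty:
            continue
        nd = {"cost_eur": 2, "avg_dsc": 3}.get(col, 1)
        rows.append(
            {
                "quantity": col,
                "median": _round_half_even(float(np.median(vals)), nd),
                "min": _round_half_even(float(vals.min()), nd),
                "max": _round_half_even(float(vals.max()), nd),
                "n": int(vals.size),
            }
        )
    if {"landmarks_matched", "landmarks_total"} <= set(table.columns):
        rows.append(
            {
                "quantity": "landmarks_matched_total",
                "median": float(table["landmarks_matched"].sum()),
                "min": float(table["landmarks_matched"].sum()),
                "max": float(table["landmarks_total"].sum()),
                "n": int(len(table)),
            }
        )
    return pd.DataFrame(rows)
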