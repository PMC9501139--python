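"""Rule-based spondylolisthesis detectors on spine geometry.

Three detectors operate on fitted vertebral corners:

* **P-grade** — the displacement ratio behind the Meyerding grading.  The
  lower-right corner of the upper vertebra is projected orthogonally onto
  the line through the lower vertebra's top plate; the distance D from the
  projection to the plate's right end, divided by the plate length and
  scaled by 100, is the P-grade.  A junction flags when P-grade > K1.
* **PSD (piecewise slope detection)** — along each side of the spine the
  corner chain (11 points, 10 segments) is walked; every segment's angle
  against the vertical is computed with the cosine formula, and a junction
  flags when any consecutive-angle difference inside its segment window
  exceeds K2 degrees, on either side.
* **DS (dynamic shift)** — for a flexion/extension pair, the P-grade
  displacement is measured in each view, normalized by that view's
  lower-plate length, and a junction flags when the absolute difference
  exceeds K3.

All comparisons are strict (">").  Distances are unsigned, so forward
(anterolisthesis) and backward (retrolisthesis) slips both flag; the
displacement direction is additionally reported for interpretability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import JUNCTIONS, LEVELS, SpineGeometry, VertebraQuad

_SEVERITY = {1: "low grade", 2: "low grade", 3: "high grade", 4: "high grade",
             5: "spondyloptosis"}

#: PSD consecutive-angle-difference windows per junction (1-based diff
#: indices into |theta_j - theta_{j+1}|, j = 1..9).  Junction m in 1..4 owns
#: segments {2m-1, 2m, 2m+1}, hence diffs {2m-1, 2m}; L5-S1 owns segments
#: {9, 10}, hence diff {9}.
PSD_DIFF_WINDOWS: dict[str, tuple[int, ...]] = {
    "L1L2": (1, 2),
    "L2L3": (3, 4),
    "L3L4": (5, 6),
    "L4L5": (7, 8),
    "L5S1": (9,),
}


class DegeneratePlateError(ValueError):
    """Lower plate has zero length."""


@dataclass(frozen=True)
class Thresholds:
    """Detection thresholds: K1 (percent) for P-grade, K2 (degrees) for
    PSD, K3 (shift fraction) for dynamic shift.

    The PSD threshold was calibrated at 37 degrees standalone and relaxed
    to 50 degrees when combined with the P-grade detector; use
    :meth:`combined` for the latter."""

    k1: float = 10.0
    k2: float = 37.0
    k3: float = 0.14

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3) <= 0:
            raise ValueError("thresholds must be strictly positive")

    @classmethod
    def combined(cls) -> "Thresholds":
        return cls(k1=10.0, k2=50.0, k3=0.14)


@dataclass(frozen=True)
class PGradeResult:
    junction: str
    projected_point: tuple[float, float]
    displacement: float  # pixels, the slip distance A
    plate_length: float  # pixels, the lower-plate width B
    pgrade: float  # percent, 100*A/B
    flag: bool
    direction: int  # +1 projection beyond the right plate end, -1 within, 0 on it

    def to_dict(self) -> dict:
        return {
            "junction": self.junction,
            "projected_point": list(self.projected_point),
            "displacement": self.displacement,
            "plate_length": self.plate_length,
            "pgrade": self.pgrade,
            "flag": self.flag,
            "direction": self.direction,
        }


@dataclass
class PSDProfile:
    """Per-side piecewise-slope profile: 10 segment angles against the
    vertical, 9 consecutive differences, and per-junction flags.  Entries
    are None where chain points were missing."""

    side: str  # "alpha" (left) or "beta" (right)
    angles: list[float | None]
    diffs: list[float | None]
    flags: dict[str, bool | None]
    max_diff: dict[str, float | None] = field(default_factory=dict)


@dataclass(frozen=True)
class DSResult:
    junction: str
    shift_flexion: float  # D  / plate length, flexion view
    shift_extension: float  # D' / plate length, extension view
    difference: float
    flag: bool

    def to_dict(self) -> dict:
        return {
            "junction": self.junction,
            "shift_flexion": self.shift_flexion,
            "shift_extension": self.shift_extension,
            "difference": self.difference,
            "flag": self.flag,
        }


def project_point_to_line(
    p: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Orthogonal projection of p onto the infinite line through a and b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise DegeneratePlateError("plate end points coincide")
    t = float((p - a) @ ab) / denom
    return a + t * ab


def compute_pgrade(
    upper_quad: VertebraQuad,
    lower_plate: tuple[tuple[float, float], tuple[float, float]],
    k1: float = 10.0,
    junction: str = "",
) -> PGradeResult:
    """P-grade of one junction from the upper quad and the lower top plate.

    The projection may land beyond the plate segment; that is permitted and
    measured the same way (the line is extended).
    """
    a = np.asarray(lower_plate[0], dtype=float)
    b = np.asarray(lower_plate[1], dtype=float)
    p3 = np.asarray(upper_quad.p3, dtype=float)
    ab = b - a
    plate_len = float(np.linalg.norm(ab))
    if plate_len == 0.0:
        raise DegeneratePlateError("plate end points coincide")
    u = ab / plate_len
    # signed position of the projection along the plate, measured from the
    # right end b; |s| is the slip distance D (projection is collinear with
    # b, so this equals the projection-to-b norm without cancellation error)
    s = float((p3 - b) @ u)
    proj = b + s * u
    d = abs(s)
    pgrade = 100.0 * d / plate_len
    direction = 0 if d == 0.0 else (1 if s > 0 else -1)
    return PGradeResult(
        junction=junction or f"{upper_quad.level}?",
        projected_point=(float(proj[0]), float(proj[1])),
        displacement=d,
        plate_length=plate_len,
        pgrade=pgrade,
        flag=pgrade > k1,
        direction=direction,
    )


def segment_angle(u: np.ndarray) -> float:
    """Angle in degrees between segment vector u and the vertical (0, 1),
    via the cosine formula; result in [0, 180]."""
    nu = float(np.linalg.norm(u))
    if nu == 0.0:
        raise ValueError("zero-length segment")
    cos = float(u[1]) / nu  # u . (0,1) / (|u| * 1)
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _side_chain(geometry: SpineGeometry, side: str) -> list[np.ndarray | None]:
    """11-point corner chain for one side: alternating upper/lower corners
    of L1..L5 then the sacral plate end.  Missing levels yield None."""
    pts: list[np.ndarray | None] = []
    for level in LEVELS:
        quad = geometry.quads.get(level)
        if quad is None:
            pts.extend([None, None])
        elif side == "alpha":
            pts.extend([np.asarray(quad.p1, float), np.asarray(quad.p4, float)])
        else:
            pts.extend([np.asarray(quad.p2, float), np.asarray(quad.p3, float)])
    if geometry.sacrum is None:
        pts.append(None)
    else:
        sp = geometry.sacrum.p1 if side == "alpha" else geometry.sacrum.p2
        pts.append(np.asarray(sp, float))
    return pts


def _psd_side(geometry: SpineGeometry, side: str, k2: float) -> PSDProfile:
    chain = _side_chain(geometry, side)
    angles: list[float | None] = []
    for j in range(10):
        p, q = chain[j], chain[j + 1]
        angles.append(None if p is None or q is None else segment_angle(q - p))
    diffs: list[float | None] = []
    for j in range(9):
        a, b = angles[j], angles[j + 1]
        diffs.append(None if a is None or b is None else abs(a - b))
    flags: dict[str, bool | None] = {}
    max_diff: dict[str, float | None] = {}
    for junction, window in PSD_DIFF_WINDOWS.items():
        vals = [diffs[j - 1] for j in window if diffs[j - 1] is not None]
        if not vals:
            flags[junction] = None
            max_diff[junction] = None
        else:
            max_diff[junction] = max(vals)
            flags[junction] = max(vals) > k2
    return PSDProfile(side=side, angles=angles, diffs=diffs, flags=flags,
                      max_diff=max_diff)


def compute_psd(
    geometry: SpineGeometry, k2: float = 37.0
) -> tuple[PSDProfile, PSDProfile]:
    """Left (alpha) and right (beta) piecewise-slope profiles.

    A junction's combined flag (see :func:`psd_junction_flags`) is the OR
    of the two sides; junctions whose chain points are missing on both
    sides are skipped with a warning.
    """
    alpha = _psd_side(geometry, "alpha", k2)
    beta = _psd_side(geometry, "beta", k2)
    skipped = [j for j in JUNCTIONS if alpha.flags[j] is None and beta.flags[j] is None]
    if skipped:
        warnings.warn("PSD skipped junctions with missing chain points: "
                      + ", ".join(skipped))
    return alpha, beta


def psd_junction_flags(alpha: PSDProfile, beta: PSDProfile) -> dict[str, bool | None]:
    out: dict[str, bool | None] = {}
    for j in JUNCTIONS:
        fa, fb = alpha.flags[j], beta.flags[j]
        out[j] = None if fa is None and fb is None else bool(fa) or bool(fb)
    return out


def compute_ds(
    geom_flexion: SpineGeometry,
    geom_extension: SpineGeometry,
    k3: float = 0.14,
) -> list[DSResult]:
    """Dynamic shift per junction across a flexion/extension pair.

    Each view's slip displacement is normalized by that view's lower-plate
    length (the same denominator as the P-grade), making the shift a
    dimensionless fraction comparable across radiographs of different
    scale.  Junctions absent in either view are skipped with a warning.
    """
    results: list[DSResult] = []
    skipped: list[str] = []
    for junction in JUNCTIONS:
        mf = geom_flexion.junction_plates(junction)
        me = geom_extension.junction_plates(junction)
        if mf is None or me is None:
            skipped.append(junction)
            continue
        rf = compute_pgrade(mf[0], mf[1], junction=junction)
        re = compute_pgrade(me[0], me[1], junction=junction)
        sf = rf.displacement / rf.plate_length
        se = re.displacement / re.plate_length
        diff = abs(sf - se)
        results.append(
            DSResult(
                junction=junction,
                shift_flexion=sf,
                shift_extension=se,
                difference=diff,
                flag=diff > k3,
            )
        )
    if skipped:
        warnings.warn("DS skipped junctions missing in a view: " + ", ".join(skipped))
    return results


def classify_grade(pgrade: float) -> tuple[int, str]:
    """Meyerding grade (1..5) and severity label for a P-grade percent.

    Grades quarter the 0-100% range (grade 1 up to 25%, 2 to 50%, 3 to
    75%, 4 to 100%) with right-closed edges; above 100% is grade 5,
    spondyloptosis (complete dislocation).  Grades 1-2 are low grade,
    3-4 high grade, with the mild/severe cut at 50%.
    """
    if pgrade < 0:
        raise ValueError("P-grade cannot be negative")
    if pgrade <= 25:
        grade = 1
    elif pgrade <= 50:
        grade = 2
    elif pgrade <= 75:
        grade = 3
    elif pgrade <= 100:
        grade = 4
    else:
        grade = 5
    return grade, _SEVERITY[grade]


@dataclass
class DetectionReport:
    """Combined per-case decision across detectors and junctions."""

    pgrade: dict[str, list[PGradeResult]]  # junction -> per-view results
    psd_flags: dict[str, bool | None]  # OR over sides and views
    ds: dict[str, DSResult] | None
    junction_flags: dict[str, bool]
    case_positive: bool
    grades: dict[str, tuple[int, str]]  # flagged junction -> (grade, severity)
    thresholds: Thresholds

    def to_dict(self) -> dict:
        return {
            "thresholds": {"K1": self.thresholds.k1, "K2": self.thresholds.k2,
                           "K3": self.thresholds.k3},
            "pgrade": {j: [r.to_dict() for r in rs] for j, rs in self.pgrade.items()},
            "psd_flags": self.psd_flags,
            "ds": None if self.ds is None
            else {j: r.to_dict() for j, r in self.ds.items()},
            "junction_flags": self.junction_flags,
            "case_positive": self.case_positive,
            "grades": {j: {"grade": g, "severity": s}
                       for j, (g, s) in self.grades.items()},
        }


def detect_case(
    views: SpineGeometry | tuple[SpineGeometry, SpineGeometry],
    thresholds: Thresholds | None = None,
) -> DetectionReport:
    """Run the detector cascade on one case.

    With a single view the P-grade and PSD detectors run and a junction
    flags on either.  With a flexion/extension pair all three run — P-grade
    and PSD on each view, dynamic shift on the pair — and the junction flag
    is the OR over all of them.  The case is positive when any junction
    flags; flagged junctions carry the Meyerding grade of their maximal
    view-wise P-grade.
    """
    thr = thresholds if thresholds is not None else Thresholds()
    geoms = list(views) if isinstance(views, tuple) else [views]
    if not geoms:
        raise ValueError("at least one geometry is required")

    pgrades: dict[str, list[PGradeResult]] = {j: [] for j in JUNCTIONS}
    psd_or: dict[str, bool | None] = {j: None for j in JUNCTIONS}
    for geom in geoms:
        for junction in JUNCTIONS:
            members = geom.junction_plates(junction)
            if members is not None:
                pgrades[junction].append(
                    compute_pgrade(members[0], members[1], k1=thr.k1,
                                   junction=junction)
                )
        alpha, beta = compute_psd(geom, k2=thr.k2)
        for junction, flag in psd_junction_flags(alpha, beta).items():
            if flag is not None:
                psd_or[junction] = bool(psd_or[junction]) or flag

    ds_map: dict[str, DSResult] | None = None
    if len(geoms) >= 2:
        ds_map = {r.junction: r for r in compute_ds(geoms[0], geoms[1], k3=thr.k3)}

    junction_flags: dict[str, bool] = {}
    grades: dict[str, tuple[int, str]] = {}
    for junction in JUNCTIONS:
        flag = any(r.flag for r in pgrades[junction]) or bool(psd_or[junction])
        if ds_map is not None and junction in ds_map:
            flag = flag or ds_map[junction].flag
        junction_flags[junction] = flag
        if flag and pgrades[junction]:
            grades[junction] = classify_grade(
                max(r.pgrade for r in pgrades[junction])
            )
    return DetectionReport(
        pgrade={j: rs for j, rs in pgrades.items()},
        psd_flags=psd_or,
        ds=ds_map,
        junction_flags=junction_flags,
        case_positive=any(junction_flags.values()),
        grades=grades,
        thresholds=thr,
    )
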