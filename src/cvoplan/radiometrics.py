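"""Radiographic measurement of hips before and after curved varus osteotomy.

Input is a landmark table digitized from anteroposterior (AP) hip
radiographs, one row per landmark with columns ``hip_id, stage, side, name,
x_mm, y_mm``.  All downstream quantities are computed in a canonical frame
anchored on the pelvic tear-drop landmarks: the ipsilateral teardrop is the
origin, the tear-drop line is the x-axis, ``+x`` points lateral for the hip
under study and ``+y`` proximal.  Left hips are mirrored into this frame so
the same varus-rotation formulas serve both sides.

Measured quantities per hip:

* neck-shaft angle (NSA) pre and post, and the varus angulation
  ``theta = NSA_pre - NSA_post``;
* VD, the vertical distance from the greater-trochanter tip to the tear-drop
  line, and LD, the lateral distance of the lateral trochanteric border from
  the teardrop origin — their pre-to-post differences are the actual leg
  shortening and femoral lateralization;
* the femoral-head and osteotomy-arc centers, fitted as circles through
  digitized rim/arc points, giving the lateral shift ``A`` and distal shift
  ``B`` of the arc center relative to the head center;
* the lateral head index (LHI), the percentage of the femoral-head width
  that is intact (non-necrotic) laterally.

Head and arc centers are fitted on the post-operative radiograph (the arc is
only visible after the cut).  Because the proximal fragment has already been
rotated there, the head-to-arc offset measured post-operatively is the
rotated vector H'; it is rotated back by the measured varus angle to recover
the pre-operative offsets (A, B) that enter the prediction formulas.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Circle,
    DegenerateGeometryError,
    OffsetPair,
    Point,
    Prediction,
    fit_circle,
    head_offsets,
    head_post,
    predict_lateralization,
    predict_shortening,
    rotate_point,
)

__all__ = [
    "LandmarkSet",
    "LHIResult",
    "MeasurementRecord",
    "LandmarkError",
    "load_landmarks",
    "write_landmarks",
    "canonicalize",
    "neck_shaft_angle",
    "varus_angulation",
    "measure_vd_ld",
    "actual_changes",
    "compute_lhi",
    "lhi_after_varus",
    "measure_hip",
    "records_to_dataframe",
    "write_records",
]

STAGES = ("pre", "post")
SIDES = ("left", "right")

#: Landmarks required at every stage.
CORE_LANDMARKS = (
    "teardrop_ipsi",
    "teardrop_contra",
    "gt_tip",
    "gt_lateral",
    "shaft_axis_1",
    "shaft_axis_2",
    "neck_axis_1",
    "neck_axis_2",
    "head_rim_1",
    "head_rim_2",
    "head_rim_3",
    "head_medial",
    "head_lateral",
)

_ARC_RE = re.compile(r"^arc_(\d+)$")

CSV_COLUMNS = ["hip_id", "stage", "side", "name", "x_mm", "y_mm"]


class LandmarkError(ValueError):
    """Raised for malformed or incomplete landmark data."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points for one hip at one stage (pre or post)."""

    hip_id: str
    stage: str
    side: str
    landmarks: Mapping[str, Point]
    frame: str = "raw"  # "raw" (as digitized) or "canonical" (tear-drop frame)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise LandmarkError(f"{self.hip_id}: unknown stage {self.stage!r}")
        if self.side not in SIDES:
            raise LandmarkError(f"{self.hip_id}: unknown side {self.side!r}")
        self._validate_names()

    def _validate_names(self) -> None:
        missing = [n for n in CORE_LANDMARKS if n not in self.landmarks]
        if missing:
            raise LandmarkError(
                f"{self.hip_id}/{self.stage}: missing landmark(s) {', '.join(missing)}"
            )

    def validate_complete(self) -> None:
        """Stage-specific completeness: a digitized pre set must carry the
        necrosis margin and a post set at least three osteotomy-arc points.
        (In-memory sets may omit them: an absent margin means a fully intact
        head in :func:`compute_lhi`.)"""
        if self.stage == "pre" and "necrosis_lateral_margin" not in self.landmarks:
            raise LandmarkError(f"{self.hip_id}/pre: missing landmark(s) necrosis_lateral_margin")
        if self.stage == "post" and len(self.arc_points()) < 3:
            raise LandmarkError(
                f"{self.hip_id}/post: need at least 3 arc_<i> landmarks on the osteotomy arc"
            )

    def __getitem__(self, name: str) -> Point:
        return self.landmarks[name]

    def arc_points(self) -> list[Point]:
        """Digitized points on the osteotomy arc, in arc_<i> index order."""
        keyed = sorted(
            (int(m.group(1)), p)
            for name, p in self.landmarks.items()
            if (m := _ARC_RE.match(name))
        )
        return [p for _, p in keyed]

    def head_rim_points(self) -> list[Point]:
        return [self.landmarks[f"head_rim_{i}"] for i in (1, 2, 3)]


@dataclass(frozen=True)
class LHIResult:
    """Lateral head index: percentage of the femoral-head width intact laterally.

    ``head_width`` is the full horizontal extent of the head and
    ``intact_width`` the part lateral to the necrotic region's lateral
    margin; ``lhi = 100 * intact_width / head_width``.
    """

    intact_width: float
    head_width: float

    @property
    def lhi(self) -> float:
        return 100.0 * self.intact_width / self.head_width


@dataclass
class MeasurementRecord:
    """All derived quantities for one hip (pre/post radiograph pair)."""

    hip_id: str
    side: str
    nsa_pre: float
    nsa_post: float
    theta: float
    vd_pre: float
    vd_post: float
    ld_pre: float
    ld_post: float
    actual_shortening: float
    actual_lateralization: float
    offsets: OffsetPair
    head_center: Point
    arc_center: Point
    arc_radius: float
    lhi_pre: float
    lhi_post: float
    predicted: Prediction
    residual_shortening: float
    residual_lateralization: float
    arc_center_discrepancy: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "hip_id": self.hip_id,
            "side": self.side,
            "nsa_pre": self.nsa_pre,
            "nsa_post": self.nsa_post,
            "theta": self.theta,
            "vd_pre": self.vd_pre,
            "vd_post": self.vd_post,
            "ld_pre": self.ld_pre,
            "ld_post": self.ld_post,
            "actual_shortening": self.actual_shortening,
            "actual_lateralization": self.actual_lateralization,
            "A": self.offsets.A,
            "B": self.offsets.B,
            "head_center_x": self.head_center.x,
            "head_center_y": self.head_center.y,
            "arc_center_x": self.arc_center.x,
            "arc_center_y": self.arc_center.y,
            "arc_radius": self.arc_radius,
            "lhi_pre": self.lhi_pre,
            "lhi_post": self.lhi_post,
            "predicted_shortening": self.predicted.shortening,
            "predicted_lateralization": self.predicted.lateralization,
            "residual_shortening": self.residual_shortening,
            "residual_lateralization": self.residual_lateralization,
            "arc_center_discrepancy": self.arc_center_discrepancy,
            "warnings": "; ".join(self.warnings),
        }
        return d


# ---------------------------------------------------------------------------
# Landmark file I/O


def load_landmarks(path: str | Path) -> list[LandmarkSet]:
    """Read a landmark CSV and return one validated LandmarkSet per (hip, stage)."""
    df = pd.read_csv(path, dtype={"hip_id": str}, float_precision="round_trip")
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LandmarkError(f"{path}: missing column(s) {', '.join(missing_cols)}")
    for col in ("x_mm", "y_mm"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(df.index[bad | df[col].isna()][0]) + 2  # 1-based + header
            raise LandmarkError(f"{path}: non-numeric {col} at file row {row}")
        df[col] = df[col].astype(float)

    sets: list[LandmarkSet] = []
    for (hip_id, stage), grp in df.groupby(["hip_id", "stage"], sort=True):
        dup = grp["name"][grp["name"].duplicated()]
        if not dup.empty:
            raise LandmarkError(f"{hip_id}/{stage}: duplicate landmark {dup.iloc[0]!r}")
        sides = grp["side"].unique()
        if len(sides) != 1:
            raise LandmarkError(f"{hip_id}/{stage}: inconsistent side labels {list(sides)}")
        landmarks = {
            str(name): Point(x, y)
            for name, x, y in zip(grp["name"], grp["x_mm"], grp["y_mm"])
        }
        ls = LandmarkSet(
            hip_id=str(hip_id), stage=str(stage), side=str(sides[0]), landmarks=landmarks
        )
        ls.validate_complete()
        sets.append(ls)
    return sets


def write_landmarks(sets: Sequence[LandmarkSet], path: str | Path) -> None:
    """Write landmark sets back to the CSV schema (exact round trip)."""
    rows = [
        (ls.hip_id, ls.stage, ls.side, name, p.x, p.y)
        for ls in sets
        for name, p in ls.landmarks.items()
    ]
    # %.17g guarantees an exact binary round trip for every coordinate
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Canonical frame


def canonicalize(ls: LandmarkSet) -> LandmarkSet:
    """Map a raw landmark set into the canonical tear-drop frame.

    Rigid transform (plus a mirror when needed): the ipsilateral teardrop
    becomes the origin, the tear-drop line the x-axis with ``+x`` lateral
    (the ipsilateral teardrop lies lateral to the contralateral one), and
    ``+y`` proximal.  The proximal direction is disambiguated with the
    greater-trochanter tip, which always lies above the tear-drop line; this
    makes the result invariant to any rigid motion or mirroring of the raw
    digitization, and maps left hips onto the right-hip convention.
    """
    if ls.frame == "canonical":
        return ls
    t_i = ls["teardrop_ipsi"].as_array()
    t_c = ls["teardrop_contra"].as_array()
    u = t_i - t_c
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise DegenerateGeometryError(
            f"{ls.hip_id}/{ls.stage}: teardrop landmarks coincide; frame undefined"
        )
    u = u / norm
    rot = np.array([[u[0], u[1]], [-u[1], u[0]]])  # proper rotation, u -> +x
    witness = rot @ (ls["gt_tip"].as_array() - t_i)
    if abs(witness[1]) < 1e-12:
        raise DegenerateGeometryError(
            f"{ls.hip_id}/{ls.stage}: greater-trochanter tip on the tear-drop line; "
            "proximal direction ambiguous"
        )
    if witness[1] < 0:  # mirrored digitization (e.g. a left hip): flip across the line
        rot = np.array([[u[0], u[1]], [u[1], -u[0]]])
    landmarks = {
        name: Point.from_array(rot @ (p.as_array() - t_i)) for name, p in ls.landmarks.items()
    }
    return replace(ls, landmarks=landmarks, frame="canonical")


def _require_canonical(ls: LandmarkSet, op: str) -> None:
    if ls.frame != "canonical":
        raise ValueError(f"{op} requires a canonical-frame LandmarkSet; call canonicalize() first")


# ---------------------------------------------------------------------------
# Angles and distances


def neck_shaft_angle(ls: LandmarkSet) -> float:
    """Neck-shaft angle (degrees) between the neck axis and the shaft axis.

    The shaft axis points distally (``shaft_axis_1`` proximal to
    ``shaft_axis_2``) and the neck axis toward the head (``neck_axis_1`` at
    the base, ``neck_axis_2`` nearer the head); the NSA is the angle between
    those two directions, in (0, 180].
    """
    shaft = ls["shaft_axis_2"].as_array() - ls["shaft_axis_1"].as_array()
    neck = ls["neck_axis_2"].as_array() - ls["neck_axis_1"].as_array()
    ns, nn = np.linalg.norm(shaft), np.linalg.norm(neck)
    if ns < 1e-9 or nn < 1e-9:
        raise DegenerateGeometryError(f"{ls.hip_id}/{ls.stage}: zero-length axis")
    cosang = float(np.clip(shaft @ neck / (ns * nn), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def varus_angulation(nsa_pre: float, nsa_post: float) -> float:
    """Varus angulation (degrees): pre-operative NSA minus post-operative NSA."""
    for v, label in ((nsa_pre, "nsa_pre"), (nsa_post, "nsa_post")):
        if not 0.0 < v < 180.0:
            raise ValueError(f"{label} must lie in (0, 180) degrees, got {v}")
    return nsa_pre - nsa_post


def measure_vd_ld(ls: LandmarkSet) -> tuple[float, float]:
    """VD and LD (mm) of the greater trochanter in the canonical frame.

    VD is the height of the trochanter tip above the tear-drop line; LD the
    lateral distance of the lateral trochanteric border from the teardrop
    origin along that line.
    """
    _require_canonical(ls, "measure_vd_ld")
    return ls["gt_tip"].y, ls["gt_lateral"].x


def actual_changes(pre: LandmarkSet, post: LandmarkSet) -> tuple[float, float]:
    """Actual leg shortening and femoral lateralization (mm), post minus pre.

    Shortening is the rise of the trochanter tip relative to the tear-drop
    line (VD_post - VD_pre); lateralization is LD_post - LD_pre.
    """
    if pre.hip_id != post.hip_id:
        raise ValueError(f"hip_id mismatch: {pre.hip_id!r} vs {post.hip_id!r}")
    vd_pre, ld_pre = measure_vd_ld(pre)
    vd_post, ld_post = measure_vd_ld(post)
    return vd_post - vd_pre, ld_post - ld_pre


# ---------------------------------------------------------------------------
# Lateral head index


def _lhi_from_extents(x_medial: float, x_lateral: float, x_margin: float | None) -> LHIResult:
    head_width = x_lateral - x_medial
    if head_width <= 0:
        raise DegenerateGeometryError("non-positive head width; check head extent landmarks")
    if x_margin is None:
        intact = head_width
    else:
        intact = min(max(x_lateral - x_margin, 0.0), head_width)
    return LHIResult(intact_width=intact, head_width=head_width)


def compute_lhi(ls: LandmarkSet) -> LHIResult:
    """Lateral head index from head extents and the necrosis lateral margin.

    Widths are horizontal extents parallel to the tear-drop line.  A margin
    at or lateral to the lateral head border gives 0%; a margin medial to the
    medial border — or no margin at all — gives a fully intact head (100%).
    """
    _require_canonical(ls, "compute_lhi")
    margin = ls.landmarks.get("necrosis_lateral_margin")
    return _lhi_from_extents(
        ls["head_medial"].x, ls["head_lateral"].x, None if margin is None else margin.x
    )


def lhi_after_varus(ls: LandmarkSet, arc: Circle, theta_deg: float) -> LHIResult:
    """LHI after rotating the proximal fragment by ``theta_deg`` about the arc center.

    The head extent landmarks and the necrosis margin ride with the proximal
    fragment; after the rotation the intact lateral region sits more
    superiorly, so the index measured on horizontal extents increases with
    the varus angle for a superolaterally located margin.
    """
    _require_canonical(ls, "lhi_after_varus")
    med = rotate_point(ls["head_medial"], arc.center, theta_deg)
    lat = rotate_point(ls["head_lateral"], arc.center, theta_deg)
    margin = ls.landmarks.get("necrosis_lateral_margin")
    if margin is not None:
        margin = rotate_point(margin, arc.center, theta_deg)
    return _lhi_from_extents(med.x, lat.x, None if margin is None else margin.x)


# ---------------------------------------------------------------------------
# Per-hip orchestration


def measure_hip(pre: LandmarkSet, post: LandmarkSet) -> MeasurementRecord:
    """Compute every radiographic quantity for one pre/post radiograph pair.

    Head and arc circles are fitted on the post-operative set; the measured
    head-to-arc offset is rotated back by the measured varus angulation to
    recover the pre-operative (A, B), which feed the closed-form predictions.
    When arc points were also digitized pre-operatively, the distance between
    the pre-fitted arc center and the one implied by the post-operative fit
    is reported as a consistency metric.
    """
    if pre.hip_id != post.hip_id:
        raise ValueError(f"hip_id mismatch: {pre.hip_id!r} vs {post.hip_id!r}")
    if pre.stage != "pre" or post.stage != "post":
        raise ValueError("measure_hip expects (pre, post) stages in that order")
    warnings: list[str] = []
    pre_c, post_c = canonicalize(pre), canonicalize(post)

    nsa_pre = neck_shaft_angle(pre_c)
    nsa_post = neck_shaft_angle(post_c)
    theta = varus_angulation(nsa_pre, nsa_post)
    if theta < 0:
        warnings.append(f"negative varus angulation ({theta:.2f}°): valgus rotation measured")

    vd_pre, ld_pre = measure_vd_ld(pre_c)
    vd_post, ld_post = measure_vd_ld(post_c)
    actual_short, actual_lat = vd_post - vd_pre, ld_post - ld_pre

    head_circle = fit_circle(post_c.head_rim_points())
    arc_circle = fit_circle(post_c.arc_points())
    # Post-operative head-to-arc vector is the rotated H'; undo the varus
    # rotation to recover the pre-operative offsets.
    h_rel_post = Point(
        head_circle.center.x - arc_circle.center.x, head_circle.center.y - arc_circle.center.y
    )
    h_rel_pre = rotate_point(h_rel_post, Point(0.0, 0.0), -theta)
    offsets = OffsetPair(A=-h_rel_pre.x, B=h_rel_pre.y)

    head_circle_pre = fit_circle(pre_c.head_rim_points())
    arc_center_pre = Point(head_circle_pre.center.x + offsets.A, head_circle_pre.center.y - offsets.B)
    discrepancy: float | None = None
    if len(pre_c.arc_points()) >= 3:
        arc_circle_pre = fit_circle(pre_c.arc_points())
        arc_center_pre = arc_circle_pre.center
        discrepancy = math.hypot(
            arc_circle_pre.center.x - (arc_circle.center.x - actual_lat),
            arc_circle_pre.center.y - (arc_circle.center.y - actual_short),
        )

    lhi_pre = compute_lhi(pre_c)
    lhi_post = lhi_after_varus(pre_c, Circle(arc_center_pre, arc_circle.radius), theta)

    predicted = Prediction(
        shortening=predict_shortening(offsets, theta),
        lateralization=predict_lateralization(offsets, theta),
        head_post=head_post(offsets, theta),
    )
    return MeasurementRecord(
        hip_id=pre.hip_id,
        side=pre.side,
        nsa_pre=nsa_pre,
        nsa_post=nsa_post,
        theta=theta,
        vd_pre=vd_pre,
        vd_post=vd_post,
        ld_pre=ld_pre,
        ld_post=ld_post,
        actual_shortening=actual_short,
        actual_lateralization=actual_lat,
        offsets=offsets,
        head_center=head_circle.center,
        arc_center=arc_circle.center,
        arc_radius=arc_circle.radius,
        lhi_pre=lhi_pre.lhi,
        lhi_post=lhi_post.lhi,
        predicted=predicted,
        residual_shortening=actual_short - predicted.shortening,
        residual_lateralization=actual_lat - predicted.lateralization,
        arc_center_discrepancy=discrepancy,
        warnings=warnings,
    )


def measure_cohort(sets: Sequence[LandmarkSet]) -> tuple[list[MeasurementRecord], list[str]]:
    """Pair pre/post sets by hip_id and measure each hip.

    Returns the successful records plus per-hip error messages; one broken
    hip does not abort the rest of the batch.
    """
    by_hip: dict[str, dict[str, LandmarkSet]] = {}
    for ls in sets:
        by_hip.setdefault(ls.hip_id, {})[ls.stage] = ls
    records, errors = [], []
    for hip_id in sorted(by_hip):
        stages = by_hip[hip_id]
        try:
            if "pre" not in stages or "post" not in stages:
                raise LandmarkError(f"{hip_id}: needs both pre and post stages")
            records.append(measure_hip(stages["pre"], stages["post"]))
        except (ValueError, KeyError) as exc:
            errors.append(f"{hip_id}: {exc}")
    return records, errors


def records_to_dataframe(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])


def write_records(
    records: Sequence[MeasurementRecord], path: str | Path, fmt: str = "csv"
) -> None:
    path = Path(path)
    if fmt == "csv":
        records_to_dataframe(records).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps([r.to_dict() for r in records], indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")
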