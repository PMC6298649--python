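"""Synthetic radiograph-landmark cohorts obeying the varus-rotation kinematics.

No public landmark dataset exists for curved intertrochanteric varus
osteotomy, so validation runs on simulated cohorts.  Each hip gets ground
-truth planning parameters — lateral shift ``A``, distal shift ``B`` and
varus angle ``theta`` — drawn from truncated normals whose means and bounds
follow the reported clinical cohort (A: mean 3.3 mm on [-8, 21]; B: mean
9.3 mm on [1, 21]; theta: mean 21.7 deg on [15, 38]).  A full pre-operative
landmark scene is built in the canonical tear-drop frame, and the
post-operative scene applies the osteotomy kinematics exactly:

* the proximal fragment (head rim, neck axis, head extents, necrosis
  margin) rotates by ``theta`` about the osteotomy-arc center;
* the whole femur then translates so the head center returns to its
  pre-operative position — the head stays seated in the acetabulum, and the
  greater trochanter's displacement against the fixed tear-drop line becomes
  the measurable leg shortening / lateralization;
* the pelvic teardrop landmarks never move.

By construction the actual changes measured from a noiseless rendering equal
the closed-form predictions; digitization error is emulated afterwards as
independent Gaussian noise on every landmark coordinate.  Left hips are
rendered mirrored, exercising the canonicalization path.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .geometry import OffsetPair, Point, predict_lateralization, predict_shortening, rotate_point
from .radiometrics import LandmarkSet

__all__ = [
    "TruncatedNormal",
    "CohortParams",
    "GroundTruthHip",
    "sample_cohort",
    "render_landmarks",
    "simulate_cohort",
    "rater_replicates",
    "truth_to_dataframe",
]

# Fixed scene anatomy (mm, canonical frame: teardrop origin, +x lateral,
# +y proximal).  Chosen once to resemble an adult AP pelvis radiograph;
# measurement results do not depend on these absolute positions.
TEARDROP_CONTRA = Point(-120.0, 0.0)  # across the midline
HEAD_CENTER = Point(42.0, 12.0)
NECK_AXIS_OFFSETS = (45.0, 10.0)  # distances from head center along the neck axis
HEAD_RIM_ANGLES_DEG = (35.0, 100.0, 150.0)
ARC_POINT_ANGLES_DEG = (195.0, 230.0, 270.0, 310.0, 345.0)
SHAFT_LATERAL_OFFSET = 5.0  # shaft axis x relative to the arc center
SHAFT_Y = (-35.0, -95.0)
GT_TIP_OFFSET = (3.0, 14.0)  # relative to (shaft_x, 0)
GT_LATERAL_OFFSET = (10.0, 2.0)

PROXIMAL_FRAGMENT = (
    "neck_axis_1",
    "neck_axis_2",
    "head_rim_1",
    "head_rim_2",
    "head_rim_3",
    "head_medial",
    "head_lateral",
    "necrosis_lateral_margin",
)
PELVIC = ("teardrop_ipsi", "teardrop_contra")


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated-normal sampling spec (mean/sd before truncation, hard bounds)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"bounds must be ordered, got [{self.lo}, {self.hi}]")
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    def sample(self, n: int, rng: np.random.Generator, family: str = "truncnorm") -> np.ndarray:
        if family == "truncnorm":
            a, b = (self.lo - self.mean) / self.sd, (self.hi - self.mean) / self.sd
            return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)
        if family == "uniform":
            return rng.uniform(self.lo, self.hi, size=n)
        raise ValueError(f"unknown distribution family {family!r}")


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level simulation parameters.

    Defaults reproduce the reference clinical cohort: 42 hips, arc-center
    offsets and varus angles matching its reported means and ranges, a 45 mm
    osteotomy guide (radius 22.5 mm), and 0.5 mm digitization noise per
    landmark coordinate.
    """

    n: int = 42
    seed: int = 0
    dist_A: TruncatedNormal = TruncatedNormal(3.3, 5.0, -8.0, 21.0)
    dist_B: TruncatedNormal = TruncatedNormal(9.3, 4.0, 1.0, 21.0)
    dist_theta: TruncatedNormal = TruncatedNormal(21.7, 5.0, 15.0, 38.0)
    family: str = "truncnorm"
    noise_sd: float = 0.5
    arc_radius: float = 22.5
    head_radius: float = 25.0
    nsa_pre: float = 135.0
    necrosis_extent: tuple[float, float] = (0.6, 0.95)
    include_pre_arc: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.arc_radius <= 0 or self.head_radius <= 0:
            raise ValueError("radii must be positive")
        lo, hi = self.necrosis_extent
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("necrosis_extent bounds must be ordered within [0, 1]")

    @staticmethod
    def from_dict(d: dict) -> "CohortParams":
        d = dict(d)
        for key in ("dist_A", "dist_B", "dist_theta"):
            if key in d and isinstance(d[key], dict):
                d[key] = TruncatedNormal(**d[key])
        if "necrosis_extent" in d:
            d["necrosis_extent"] = tuple(d["necrosis_extent"])
        return CohortParams(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["necrosis_extent"] = list(self.necrosis_extent)
        return d


@dataclass(frozen=True)
class GroundTruthHip:
    """One simulated hip: sampled parameters plus their exact consequences.

    ``head_cx/head_cy`` and ``gt_dx/gt_dy`` carry per-patient anatomical
    variation (head-center position, trochanter offsets); without it every
    hip would measure the same VD/LD and subject-level agreement statistics
    would be degenerate.  The offsets cancel in pre-to-post differences, so
    they do not perturb the kinematic round trip.
    """

    hip_id: str
    side: str
    A: float
    B: float
    theta: float
    necrosis_extent: float
    arc_radius: float
    head_radius: float
    nsa_pre: float
    head_cx: float = HEAD_CENTER.x
    head_cy: float = HEAD_CENTER.y
    gt_dx: float = 0.0
    gt_dy: float = 0.0

    @property
    def offsets(self) -> OffsetPair:
        return OffsetPair(self.A, self.B)

    @property
    def true_shortening(self) -> float:
        return predict_shortening(self.offsets, self.theta)

    @property
    def true_lateralization(self) -> float:
        return predict_lateralization(self.offsets, self.theta)

    def true_scene(self, include_pre_arc: bool = True) -> tuple[dict, dict]:
        """Noiseless landmark coordinates (canonical frame) for both stages."""
        return _build_scene(self, include_pre_arc)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_cohort(params: CohortParams) -> list[GroundTruthHip]:
    """Draw a deterministic cohort of ground-truth hips (sides alternate R/L)."""
    rng = _rng(params.seed)
    A = params.dist_A.sample(params.n, rng, params.family)
    B = params.dist_B.sample(params.n, rng, params.family)
    theta = params.dist_theta.sample(params.n, rng, params.family)
    lo, hi = params.necrosis_extent
    extent = rng.uniform(lo, hi, size=params.n)
    # Per-patient anatomy: head-center position and trochanter offsets vary a
    # few millimetres around the template scene (clipped Gaussians).
    head_cx = HEAD_CENTER.x + np.clip(rng.normal(0.0, 4.0, params.n), -8.0, 8.0)
    head_cy = HEAD_CENTER.y + np.clip(rng.normal(0.0, 4.0, params.n), -6.0, 6.0)
    gt_dx = np.clip(rng.normal(0.0, 3.0, params.n), -6.0, 6.0)
    gt_dy = np.clip(rng.normal(0.0, 3.0, params.n), -6.0, 6.0)
    width = max(3, len(str(params.n)))
    return [
        GroundTruthHip(
            hip_id=f"H{i + 1:0{width}d}",
            side="right" if i % 2 == 0 else "left",
            A=float(A[i]),
            B=float(B[i]),
            theta=float(theta[i]),
            necrosis_extent=float(extent[i]),
            arc_radius=params.arc_radius,
            head_radius=params.head_radius,
            nsa_pre=params.nsa_pre,
            head_cx=float(head_cx[i]),
            head_cy=float(head_cy[i]),
            gt_dx=float(gt_dx[i]),
            gt_dy=float(gt_dy[i]),
        )
        for i in range(params.n)
    ]


def _build_scene(hip: GroundTruthHip, include_pre_arc: bool) -> tuple[dict, dict]:
    """Noiseless pre/post landmark dictionaries in the canonical frame."""
    h = Point(hip.head_cx, hip.head_cy)
    arc_c = Point(h.x + hip.A, h.y - hip.B)
    r_h, r_a = hip.head_radius, hip.arc_radius

    # Neck axis direction toward the head; with +x lateral and +y proximal a
    # neck-shaft angle of `nsa` against the distal shaft direction (0, -1)
    # puts the axis at 270 - nsa degrees in standard orientation.
    alpha = math.radians(270.0 - hip.nsa_pre)
    d = np.array([math.cos(alpha), math.sin(alpha)])
    shaft_x = arc_c.x + SHAFT_LATERAL_OFFSET

    margin_x_rel = r_h * (2.0 * hip.necrosis_extent - 1.0)
    margin_y_rel = math.sqrt(max(r_h**2 - margin_x_rel**2, 0.0))

    pre: dict[str, Point] = {
        "teardrop_ipsi": Point(0.0, 0.0),
        "teardrop_contra": TEARDROP_CONTRA,
        "gt_tip": Point(shaft_x + GT_TIP_OFFSET[0] + hip.gt_dx, GT_TIP_OFFSET[1] + hip.gt_dy),
        "gt_lateral": Point(
            shaft_x + GT_LATERAL_OFFSET[0] + hip.gt_dx, GT_LATERAL_OFFSET[1] + hip.gt_dy
        ),
        "shaft_axis_1": Point(shaft_x, SHAFT_Y[0]),
        "shaft_axis_2": Point(shaft_x, SHAFT_Y[1]),
        "neck_axis_1": Point(h.x - NECK_AXIS_OFFSETS[0] * d[0], h.y - NECK_AXIS_OFFSETS[0] * d[1]),
        "neck_axis_2": Point(h.x - NECK_AXIS_OFFSETS[1] * d[0], h.y - NECK_AXIS_OFFSETS[1] * d[1]),
        "head_medial": Point(h.x - r_h, h.y),
        "head_lateral": Point(h.x + r_h, h.y),
        "necrosis_lateral_margin": Point(h.x + margin_x_rel, h.y + margin_y_rel),
    }
    for i, ang in enumerate(HEAD_RIM_ANGLES_DEG, start=1):
        a = math.radians(ang)
        pre[f"head_rim_{i}"] = Point(h.x + r_h * math.cos(a), h.y + r_h * math.sin(a))
    arc_points = {}
    for i, ang in enumerate(ARC_POINT_ANGLES_DEG, start=1):
        a = math.radians(ang)
        arc_points[f"arc_{i}"] = Point(arc_c.x + r_a * math.cos(a), arc_c.y + r_a * math.sin(a))
    if include_pre_arc:
        pre.update(arc_points)

    # Osteotomy: rotate the proximal fragment about the arc center, then
    # translate the whole femur so the head center returns into the
    # acetabulum.  The translation is exactly (lateralization, shortening).
    head_rot = rotate_point(h, arc_c, hip.theta)
    t = np.array([h.x - head_rot.x, h.y - head_rot.y])
    post: dict[str, Point] = {}
    for name, p in {**pre, **arc_points}.items():
        if name == "necrosis_lateral_margin":  # visible on MRI pre-operatively only
            continue
        if name in PELVIC:
            post[name] = p
            continue
        if name in PROXIMAL_FRAGMENT:
            p = rotate_point(p, arc_c, hip.theta)
        post[name] = Point(p.x + t[0], p.y + t[1])
    return pre, post


def _emit(hip: GroundTruthHip, stage: str, landmarks: dict, noise_sd: float,
          rng: np.random.Generator) -> LandmarkSet:
    out = {}
    for name, p in landmarks.items():
        x, y = p.x, p.y
        if hip.side == "left":  # left hips are digitized mirrored
            x = -x
        if noise_sd > 0:
            x += rng.normal(0.0, noise_sd)
            y += rng.normal(0.0, noise_sd)
        out[name] = Point(x, y)
    return LandmarkSet(hip_id=hip.hip_id, stage=stage, side=hip.side, landmarks=out)


def render_landmarks(
    hip: GroundTruthHip,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    include_pre_arc: bool = True,
) -> tuple[LandmarkSet, LandmarkSet]:
    """Render raw pre/post landmark sets for one hip, with digitization noise."""
    rng = _rng(seed)
    pre, post = _build_scene(hip, include_pre_arc)
    return _emit(hip, "pre", pre, noise_sd, rng), _emit(hip, "post", post, noise_sd, rng)


def simulate_cohort(params: CohortParams) -> tuple[list[LandmarkSet], pd.DataFrame]:
    """Sample a cohort and render all landmark sets; returns sets + truth table."""
    hips = sample_cohort(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    sets: list[LandmarkSet] = []
    for hip in hips:
        pre, post = render_landmarks(hip, params.noise_sd, rng, params.include_pre_arc)
        sets.extend([pre, post])
    return sets, truth_to_dataframe(hips)


def truth_to_dataframe(hips: Sequence[GroundTruthHip]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hip_id": [h.hip_id for h in hips],
            "side": [h.side for h in hips],
            "A": [h.A for h in hips],
            "B": [h.B for h in hips],
            "theta": [h.theta for h in hips],
            "necrosis_extent": [h.necrosis_extent for h in hips],
            "true_shortening": [h.true_shortening for h in hips],
            "true_lateralization": [h.true_lateralization for h in hips],
        }
    )


def rater_replicates(
    ls: LandmarkSet, sd: float, k: int, seed: int | np.random.Generator | None = None
) -> list[LandmarkSet]:
    """k independent noisy re-digitizations of the same landmark truth."""
    if k < 2:
        raise ValueError("need at least 2 replicates")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = _rng(seed)
    reps = []
    for _ in range(k):
        lm = {
            name: Point(p.x + (rng.normal(0, sd) if sd > 0 else 0.0),
                        p.y + (rng.normal(0, sd) if sd > 0 else 0.0))
            for name, p in ls.landmarks.items()
        }
        reps.append(LandmarkSet(ls.hip_id, ls.stage, ls.side, lm, frame=ls.frame))
    return reps
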