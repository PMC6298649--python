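"""Pre-operative planning on top of the varus-rotation model.

Forward prediction of leg shortening and femoral lateralization, the largest
lateral shift of the arc center compatible with a shortening budget, local
sensitivities of the shortening to the planning parameters, and the smallest
varus angle that brings the lateral head index (LHI) up to the surgical
indication threshold.

Planning only considers varus rotations (theta >= 0); the geometric core
also evaluates valgus angles, but a negative plan is rejected here.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass

from .geometry import Circle, OffsetPair, Prediction, head_post, predict_lateralization, predict_shortening
from .radiometrics import LandmarkSet, lhi_after_varus

__all__ = [
    "PlanningConstraints",
    "InfeasiblePlanError",
    "plan_forward",
    "max_lateral_shift",
    "sensitivity",
    "required_varus_for_lhi",
]

#: Hard cap on the planned varus angle (degrees); comfortably above the
#: largest angle used clinically, guarding against nonphysical solutions.
THETA_CAP = 45.0


class InfeasiblePlanError(ValueError):
    """Raised when no varus angle within the allowed range meets the target."""


@dataclass(frozen=True)
class PlanningConstraints:
    """Clinical planning limits.

    ``max_shortening`` — shortening budget in mm (default 5, the threshold
    separating clinically relevant shortening); ``theta_range`` — the varus
    angles normally used (default 15–38°; plans outside it trigger a
    warning, not an error); ``target_lhi`` — the post-operative intact-width
    percentage required for a good outcome (default 25%).
    """

    max_shortening: float = 5.0
    theta_range: tuple[float, float] = (15.0, 38.0)
    target_lhi: float = 25.0

    def __post_init__(self) -> None:
        if not self.max_shortening > 0:
            raise ValueError("max_shortening must be positive")
        lo, hi = self.theta_range
        if not (0.0 < lo < hi < 90.0):
            raise ValueError("theta_range must be ordered and within (0, 90) degrees")
        if not 0.0 < self.target_lhi <= 100.0:
            raise ValueError("target_lhi must lie in (0, 100]")


def plan_forward(off: OffsetPair, theta_deg: float) -> Prediction:
    """Predicted shortening, lateralization and post-rotation head position."""
    if theta_deg < 0:
        raise ValueError(f"planning requires a varus (non-negative) angle, got {theta_deg}")
    return Prediction(
        shortening=predict_shortening(off, theta_deg),
        lateralization=predict_lateralization(off, theta_deg),
        head_post=head_post(off, theta_deg),
    )


def max_lateral_shift(B: float, theta_deg: float, s_max: float = 5.0) -> float:
    """Largest lateral shift A keeping predicted shortening within ``s_max``.

    Solves ``A sin(theta) + B (1 - cos(theta)) = s_max`` for A.  A negative
    result means the arc center must be placed medial to the head center to
    respect the budget at this angle.
    """
    if not 0.0 < theta_deg < 90.0:
        raise ValueError(f"theta must lie in (0, 90) degrees, got {theta_deg}")
    t = math.radians(theta_deg)
    return (s_max - B * (1.0 - math.cos(t))) / math.sin(t)


def sensitivity(off: OffsetPair, theta_deg: float) -> tuple[float, float, float]:
    """Partial derivatives of the predicted shortening.

    Returns ``(dS/dA, dS/dB, dS/dtheta)`` in mm/mm, mm/mm and mm/degree:
    ``(sin(theta), 1 - cos(theta), (A cos(theta) + B sin(theta)) * pi/180)``.
    """
    t = math.radians(theta_deg)
    return (
        math.sin(t),
        1.0 - math.cos(t),
        (off.A * math.cos(t) + off.B * math.sin(t)) * math.pi / 180.0,
    )


def required_varus_for_lhi(
    ls: LandmarkSet,
    arc: Circle,
    constraints: PlanningConstraints = PlanningConstraints(),
    grid_step: float = 0.5,
    tol: float = 1e-3,
) -> float:
    """Smallest varus angle (degrees) reaching the LHI indication threshold.

    Evaluates the post-rotation LHI on a coarse grid over [0°, 45°] to locate
    a bracket, then bisects to ``tol`` degrees.  If the LHI profile is not
    monotone across the grid the first grid angle meeting the target is
    returned with a warning.  Raises :class:`InfeasiblePlanError` when even
    the capped angle cannot reach the target.
    """
    target = constraints.target_lhi

    def lhi_at(theta: float) -> float:
        return lhi_after_varus(ls, arc, theta).lhi

    if lhi_at(0.0) >= target:
        return 0.0

    n_steps = int(round(THETA_CAP / grid_step))
    grid = [i * grid_step for i in range(n_steps + 1)]
    values = [lhi_at(g) for g in grid]
    feasible = [g for g, v in zip(grid, values) if v >= target]
    if not feasible and values[-1] < target:
        raise InfeasiblePlanError(
            f"target LHI {target}% unreachable with varus up to {THETA_CAP}° "
            f"(best {max(values):.1f}%)"
        )
    monotone = all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
    if not monotone:
        theta_req = min(feasible)
        _warnings.warn(
            "LHI is not monotone in the varus angle over the search grid; "
            f"returning the smallest feasible grid angle {theta_req:.2f}°",
            stacklevel=2,
        )
    else:
        # Bisect within the first bracketing grid interval.
        hi = min(feasible)
        lo = max(0.0, hi - grid_step)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if lhi_at(mid) >= target:
                hi = mid
            else:
                lo = mid
        theta_req = hi
    lo_r, hi_r = constraints.theta_range
    if not lo_r <= theta_req <= hi_r:
        _warnings.warn(
            f"required varus angle {theta_req:.2f}° lies outside the usual "
            f"clinical range [{lo_r}, {hi_r}]°",
            stacklevel=2,
        )
    return theta_req


def planning_report(
    off: OffsetPair,
    theta_deg: float,
    constraints: PlanningConstraints = PlanningConstraints(),
) -> dict:
    """JSON-serializable planning summary for one candidate (A, B, theta)."""
    pred = plan_forward(off, theta_deg)
    ds_da, ds_db, ds_dtheta = sensitivity(off, theta_deg)
    warnings: list[str] = []
    if pred.shortening > constraints.max_shortening:
        warnings.append(
            f"predicted shortening {pred.shortening:.2f} mm exceeds the "
            f"{constraints.max_shortening:.1f} mm budget"
        )
    lo, hi = constraints.theta_range
    if not lo <= theta_deg <= hi:
        warnings.append(f"varus angle {theta_deg}° outside the usual range [{lo}, {hi}]°")
    return {
        "inputs": {"A_mm": off.A, "B_mm": off.B, "theta_deg": theta_deg},
        "prediction": {
            "shortening_mm": pred.shortening,
            "lateralization_mm": pred.lateralization,
            "head_post_mm": [pred.head_post.x, pred.head_post.y],
        },
        "max_lateral_shift_mm": max_lateral_shift(off.B, theta_deg, constraints.max_shortening),
        "sensitivity": {
            "dS_dA_mm_per_mm": ds_da,
            "dS_dB_mm_per_mm": ds_db,
            "dS_dtheta_mm_per_deg": ds_dtheta,
        },
        "constraints": {
            "max_shortening_mm": constraints.max_shortening,
            "theta_range_deg": list(constraints.theta_range),
            "target_lhi_pct": constraints.target_lhi,
        },
        "warnings": warnings,
    }
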