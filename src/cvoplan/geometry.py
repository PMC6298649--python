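"""Closed-form rotation model for curved intertrochanteric varus osteotomy (CVO).

CVO removes a circular arc of bone between the greater and lesser trochanters
and rotates the proximal fragment (femoral head and neck) about the center of
that arc.  Working in the arc-center frame — arc center ``O`` at the origin,
``+x`` lateral, ``+y`` proximal — the femoral-head center sits pre-operatively
at ``H = (-A, B)``, where ``A`` is the lateral shift and ``B`` the distal
shift of the arc center relative to the head center.  A varus rotation by
``theta`` carries ``H`` to::

    H' = (-A cos(theta) - B sin(theta), -A sin(theta) + B cos(theta))

Because the head stays seated in the acetabulum while the distal fragment
carries the leg, the drop of the head in the arc-center frame is exactly the
leg shortening, and its medial displacement is the femoral lateralization:

    shortening      = A sin(theta) + B (1 - cos(theta))
    lateralization  = -A (1 - cos(theta)) + B sin(theta)

All interfaces take angles in degrees and lengths in millimetres.  The same
formulas serve left and right hips because landmark data are first mirrored
into the canonical ``+x``-lateral frame (see :mod:`cvoplan.radiometrics`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Point",
    "OffsetPair",
    "Circle",
    "Prediction",
    "DegenerateGeometryError",
    "rotate_point",
    "head_offsets",
    "predict_shortening",
    "predict_lateralization",
    "head_post",
    "fit_circle",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is ill-posed (e.g. collinear points)."""


@dataclass(frozen=True)
class Point:
    """A 2D location in millimetres; +x lateral, +y proximal for the hip under study."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    @staticmethod
    def from_array(a: Iterable[float]) -> "Point":
        x, y = a
        return Point(float(x), float(y))


@dataclass(frozen=True)
class OffsetPair:
    """Displacement of the osteotomy-arc center relative to the femoral-head center.

    ``A`` (mm, positive = arc center lateral to the head center) and ``B``
    (mm, positive = arc center distal to the head center).  Equivalently the
    head center sits at ``(-A, B)`` in the arc-center frame.
    """

    A: float
    B: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and math.isfinite(self.B)):
            raise ValueError("Offsets must be finite")

    def head_pre(self) -> Point:
        """Pre-operative head-center position in the arc-center frame."""
        return Point(-self.A, self.B)


@dataclass(frozen=True)
class Circle:
    center: Point
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise ValueError(f"Circle radius must be positive and finite, got {self.radius}")


@dataclass(frozen=True)
class Prediction:
    """Model outputs for one planned varus rotation.

    ``shortening`` (mm, positive = leg shortened), ``lateralization`` (mm,
    positive = femoral shaft displaced laterally) and ``head_post`` — the
    post-rotation head-center position H' in the arc-center frame.
    """

    shortening: float
    lateralization: float
    head_post: Point


def _check_theta(theta_deg: float) -> float:
    if not math.isfinite(theta_deg):
        raise ValueError("theta must be finite")
    if not -90.0 <= theta_deg <= 90.0:
        raise ValueError(f"varus angle must lie in [-90, 90] degrees, got {theta_deg}")
    return math.radians(theta_deg)


def rotate_point(p: Point, center: Point, theta_deg: float) -> Point:
    """Rotate ``p`` about ``center`` by ``theta_deg`` degrees.

    The rotation convention is ``x' = x cos - y sin``, ``y' = x sin + y cos``
    (counter-clockwise in the canonical frame); with +x lateral and +y
    proximal this is the varus sense for positive angles.
    """
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    dx, dy = p.x - center.x, p.y - center.y
    return Point(center.x + c * dx - s * dy, center.y + s * dx + c * dy)


def head_offsets(head: Point, arc_center: Point) -> OffsetPair:
    """Lateral (A) and distal (B) shift of the arc center relative to the head center.

    Both points must be expressed in the same canonical frame.  The sign
    convention puts the head at ``(-A, B)`` in the arc-center frame: a
    positive ``A`` means the arc center lies lateral to the head center and a
    positive ``B`` means it lies distal to it.
    """
    return OffsetPair(A=arc_center.x - head.x, B=head.y - arc_center.y)


def predict_shortening(off: OffsetPair, theta_deg: float) -> float:
    """Predicted leg shortening (mm) for a varus rotation of ``theta_deg``.

    ``A sin(theta) + B (1 - cos(theta))`` — the drop in the head-center height
    in the arc-center frame, equal to the shortening of the leg once the head
    is re-seated in the acetabulum.
    """
    t = _check_theta(theta_deg)
    return off.A * math.sin(t) + off.B * (1.0 - math.cos(t))


def predict_lateralization(off: OffsetPair, theta_deg: float) -> float:
    """Predicted femoral lateralization (mm): ``-A (1 - cos(theta)) + B sin(theta)``."""
    t = _check_theta(theta_deg)
    return -off.A * (1.0 - math.cos(t)) + off.B * math.sin(t)


def head_post(off: OffsetPair, theta_deg: float) -> Point:
    """Post-rotation head-center position H' in the arc-center frame."""
    t = _check_theta(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return Point(-off.A * c - off.B * s, -off.A * s + off.B * c)


def fit_circle(points: Sequence[Point], collinearity_tol: float = 1e-9) -> Circle:
    """Fit a circle to digitized points.

    Exactly three points give the circumcircle; more give the algebraic
    (Kåsa) least-squares circle, solving ``x² + y² = c0 + c1 x + c2 y`` in
    the least-squares sense.  Both reduce to the same linear system; the
    three-point case is solved exactly.

    Raises :class:`DegenerateGeometryError` for fewer than three points or
    for points collinear to within ``collinearity_tol`` (relative to the
    point spread).
    """
    pts = np.array([[p.x, p.y] for p in points], dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"circle fit needs at least 3 points, got {n}")

    # Center coordinates for conditioning; restore afterwards.
    mean = pts.mean(axis=0)
    q = pts - mean
    scale = float(np.abs(q).max())
    if scale == 0.0:
        raise DegenerateGeometryError("all points coincide")
    q /= scale

    design = np.column_stack([np.ones(n), q])
    rhs = (q**2).sum(axis=1)
    # Collinearity check: the 2D scatter must have rank 2.
    sv = np.linalg.svd(q, compute_uv=False)
    if sv[-1] <= collinearity_tol * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are collinear; circle is undefined")
    if n == 3:
        coef = np.linalg.solve(design, rhs)
    else:
        coef, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    cx, cy = coef[1] / 2.0, coef[2] / 2.0
    r2 = coef[0] + cx**2 + cy**2
    if r2 <= 0:
        raise DegenerateGeometryError("degenerate circle fit (non-positive radius)")
    center = mean + scale * np.array([cx, cy])
    return Circle(Point(float(center[0]), float(center[1])), float(scale * math.sqrt(r2)))


def circle_fit_residuals(points: Sequence[Point], circle: Circle) -> np.ndarray:
    """Signed radial residuals (mm) of ``points`` from a fitted circle."""
    pts = np.array([[p.x, p.y] for p in points], dtype=float)
    d = np.hypot(pts[:, 0] - circle.center.x, pts[:, 1] - circle.center.y)
    return d - circle.radius
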