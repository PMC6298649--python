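"""Independent oracles shared across tests.

These deliberately avoid the library's own code paths: the rotation oracle
builds an explicit rotation matrix with numpy, the correlation oracle is a
direct summation of the product-moment formula, and the ICC oracle computes
ANOVA sums of squares from first principles.
"""

from __future__ import annotations

import math

import numpy as np


def rotation_oracle(xy, center, theta_deg):
    """Rotate point(s) about ``center`` with an explicit matrix product."""
    t = math.radians(theta_deg)
    R = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    xy = np.asarray(xy, dtype=float)
    c = np.asarray(center, dtype=float)
    return (R @ (xy - c).T).T + c


def shortening_oracle(A, B, theta_deg):
    """Leg shortening as the drop of the head point under the explicit rotation."""
    pre = np.array([-A, B])
    post = rotation_oracle(pre, (0.0, 0.0), theta_deg)
    return pre[1] - post[1]


def lateralization_oracle(A, B, theta_deg):
    pre = np.array([-A, B])
    post = rotation_oracle(pre, (0.0, 0.0), theta_deg)
    return -(post[0] - pre[0])


def pearson_oracle(x, y):
    """Product-moment correlation by direct summation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = (x * y).sum()
    sxx, syy = (x * x).sum(), (y * y).sum()
    return (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))


def rigid_transform(xy, angle_deg, tx, ty, mirror=False):
    """Apply mirror-then-rotate-then-translate to an (n, 2) array."""
    xy = np.asarray(xy, dtype=float).copy()
    if mirror:
        xy[:, 0] = -xy[:, 0]
    out = rotation_oracle(xy, (0.0, 0.0), angle_deg)
    return out + np.array([tx, ty])
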