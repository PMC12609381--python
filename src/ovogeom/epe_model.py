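"""Explicit Preston equation (EPE) as a planar egg-profile curve.

The EPE describes the half-profile of an egg-shaped solid as an ellipse
modulated by a cubic polynomial in the normalised axial coordinate
``u = x / b``::

    y(x) = +/- a * sqrt(1 - u**2) * (1 + c1*u + c2*u**2 + c3*u**3)

The plus/minus branches are the upper and lower halves of the closed
profile.  ``a`` and ``b`` are approximately half the maximum width and
half the length of the fruit (cm); ``c1, c2, c3`` are dimensionless
asymmetry/shape coefficients (all zero recovers an ellipse).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "EPEParams",
    "InvalidParamsError",
    "epe_y",
    "epe_dydx",
    "sample_curve",
    "length_width",
]

#: number of grid nodes used for the polynomial-positivity validity check
_VALIDITY_GRID = 2001


class InvalidParamsError(ValueError):
    """Raised when EPE parameters do not describe a valid closed profile."""


@dataclass(frozen=True)
class EPEParams:
    """The five shape parameters of one fitted fruit profile.

    Attributes
    ----------
    a, b:
        Approximate half maximum width and exact half length, cm. Both > 0.
    c1, c2, c3:
        Dimensionless shape coefficients of the cubic modulation polynomial
        ``P(u) = 1 + c1*u + c2*u**2 + c3*u**3``, which must stay strictly
        positive on ``u in [-1, 1]`` for the profile to be a simple closed
        curve around the x-axis.
    """

    a: float
    b: float
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0

    def poly(self, u: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the modulation polynomial P(u)."""
        u = np.asarray(u, dtype=float)
        return 1.0 + u * (self.c1 + u * (self.c2 + u * self.c3))

    def poly_deriv(self, u: np.ndarray | float) -> np.ndarray | float:
        """Evaluate P'(u)."""
        u = np.asarray(u, dtype=float)
        return self.c1 + u * (2.0 * self.c2 + 3.0 * self.c3 * u)

    def is_valid(self) -> bool:
        """True when a, b > 0, all coefficients finite and P > 0 on [-1, 1].

        Positivity is checked on a fixed 2001-point grid; that resolution is
        ample for the coefficient magnitudes real fruit profiles exhibit
        (|c| well below 1).
        """
        vals = (self.a, self.b, self.c1, self.c2, self.c3)
        if not all(np.isfinite(vals)):
            return False
        if self.a <= 0 or self.b <= 0:
            return False
        u = np.linspace(-1.0, 1.0, _VALIDITY_GRID)
        return bool(np.all(self.poly(u) > 0.0))

    def validate(self) -> "EPEParams":
        if not self.is_valid():
            raise InvalidParamsError(f"invalid EPE parameters: {self}")
        return self

    def scaled(self, k: float) -> "EPEParams":
        """Isometric rescale: multiply both linear dimensions by ``k``."""
        return EPEParams(self.a * k, self.b * k, self.c1, self.c2, self.c3)


@dataclass(frozen=True)
class ProfileCoordinates:
    """An ordered closed boundary of one fruit's 2D profile, in cm.

    ``points`` is an (n, 2) float array of (x, y) pairs.  A *standardized*
    profile is centred at the midpoint of its longest chord, has that chord
    on the x-axis (so x spans [-L/2, +L/2]), starts at (-L/2, 0), runs
    counterclockwise and is resampled to approximately arc-length
    equidistant points.
    """

    points: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 10:
            raise ValueError("a profile needs at least 10 points")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


def _as_u(x, params: EPEParams, *, strict: bool = True) -> np.ndarray:
    u = np.asarray(x, dtype=float) / params.b
    if strict and np.any(np.abs(u) > 1.0 + 1e-12):
        raise ValueError(f"|x| exceeds b={params.b}: outside the EPE domain")
    return np.clip(u, -1.0, 1.0)


def epe_y(x, params: EPEParams, branch: str = "upper"):
    """Evaluate the EPE profile ordinate at axial position(s) ``x``.

    Parameters
    ----------
    x:
        Scalar or array of axial coordinates, cm, with ``|x| <= b``.
    branch:
        ``"upper"`` (+) or ``"lower"`` (-) half of the profile.

    Returns y in cm; exactly 0 at the tips ``x = +/- b``.
    """
    params.validate()
    if branch not in ("upper", "lower"):
        raise ValueError(f"branch must be 'upper' or 'lower', got {branch!r}")
    u = _as_u(x, params)
    y = params.a * np.sqrt(np.maximum(0.0, 1.0 - u * u)) * params.poly(u)
    if branch == "lower":
        y = -y
    return y if isinstance(y, np.ndarray) and np.ndim(x) else float(y)


def epe_dydx(x, params: EPEParams, branch: str = "upper"):
    """Analytic slope dy/dx of the EPE profile.

    With ``u = x/b``:  dy/dx = (a/b) * [ -u/sqrt(1-u^2) * P(u)
    + sqrt(1-u^2) * P'(u) ].  The slope diverges at the tips, so
    ``|x| = b`` raises instead of silently returning a number.
    """
    params.validate()
    if branch not in ("upper", "lower"):
        raise ValueError(f"branch must be 'upper' or 'lower', got {branch!r}")
    u = _as_u(x, params)
    if np.any(np.abs(u) >= 1.0 - 1e-15):
        raise ZeroDivisionError("dy/dx has a pole at the profile tips |x| = b")
    root = np.sqrt(1.0 - u * u)
    slope = (params.a / params.b) * (
        -u / root * params.poly(u) + root * params.poly_deriv(u)
    )
    if branch == "lower":
        slope = -slope
    return slope if np.ndim(x) else float(slope)


def _dense_closed_polygon(params: EPEParams, n_dense: int = 4000) -> np.ndarray:
    """Trace the closed curve through both branches, tips included once.

    Uses the angular substitution x = -b*cos(t) so nodes crowd near the
    tips where the curve turns fastest.
    """
    t = np.linspace(0.0, np.pi, n_dense // 2 + 1)
    x = -params.b * np.cos(t)
    upper = np.column_stack([x, epe_y(x, params, "upper")])
    lower = np.column_stack([x[::-1][1:-1], epe_y(x[::-1][1:-1], params, "lower")])
    return np.vstack([upper, lower])


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` arc-length-equidistant vertices.

    Linear interpolation along the polygon edges; the first input vertex is
    kept as the first output vertex.  Input must not repeat the start point.
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polygon with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    xs = np.interp(targets, s, closed[:, 0])
    ys = np.interp(targets, s, closed[:, 1])
    return np.column_stack([xs, ys])


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon (positive = CCW)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def sample_curve(params: EPEParams, n: int = 1000) -> ProfileCoordinates:
    """Sample the closed EPE curve as a standardized profile.

    Returns ``n`` approximately arc-length-equidistant points starting at
    the left tip (-b, 0) and running counterclockwise.
    """
    params.validate()
    if n < 10 or n % 2:
        raise ValueError("n must be an even integer >= 10")
    dense = _dense_closed_polygon(params, n_dense=max(4000, 4 * n))
    pts = resample_closed(dense, n)
    if polygon_area(pts) < 0:
        pts = np.vstack([pts[:1], pts[1:][::-1]])
    return ProfileCoordinates(pts, standardized=True)


def length_width(params: EPEParams) -> Tuple[float, float]:
    """Length and maximum width of the profile, cm.

    L = 2b by construction.  W is twice the maximum of the upper branch,
    located by a dense-grid scan refined with bounded 1-D maximization
    (the cubic modulation can move the widest section off x = 0 and create
    several local maxima).
    """
    params.validate()
    u = np.linspace(-1.0, 1.0, 2001)
    y = params.a * np.sqrt(1.0 - u * u) * params.poly(u)
    i = int(np.argmax(y))
    lo, hi = u[max(i - 1, 0)], u[min(i + 1, len(u) - 1)]

    def neg_y(uu: float) -> float:
        return -params.a * np.sqrt(max(0.0, 1.0 - uu * uu)) * float(params.poly(uu))

    res = minimize_scalar(neg_y, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    w = 2.0 * max(-res.fun, float(y[i]))
    return 2.0 * params.b, float(w)
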