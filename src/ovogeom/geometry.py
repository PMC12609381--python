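"""Volume and surface area of the solid of revolution swept by an EPE profile.

Rotating the upper half-profile y(x) about the long (x) axis gives

    V = pi * Int_{-b}^{b} y(x)^2 dx
    S = 2*pi * Int_{-b}^{b} y(x) * sqrt(1 + y'(x)^2) dx

For the EPE the volume integral has a closed form; an adaptive-quadrature
oracle of the first line is kept alongside as an independent check.  The
surface integral is evaluated after the substitution x = b*sin(t), which
removes the inverse-square-root slope singularity at the tips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .epe_model import EPEParams, epe_y, length_width

__all__ = [
    "GeometryResult",
    "volume_closed_form",
    "volume_numeric_oracle",
    "surface_area",
    "shape_metrics",
]

# fixed quadrature tolerances: the geometry layer is the oracle the
# statistics sit on, so these are deliberately not configurable
_QUAD_REL = 1e-10
_QUAD_ABS_SCALE = 1e-12


@dataclass(frozen=True)
class GeometryResult:
    """Size and shape descriptors of one fruit derived from fitted parameters.

    v_pred: solid-of-revolution volume, cm^3.  s: surface area, cm^2.
    l, w: length and maximum width, cm.  w_over_l: sphericity index
    (1 = round, < 1 = elongated).
    """

    v_pred: float
    s: float
    l: float
    w: float
    w_over_l: float


def volume_closed_form(params: EPEParams) -> float:
    """Closed-form solid-of-revolution volume of an EPE profile, cm^3.

    V = (4*pi/315) * a^2 * b * (105 + 21*c1^2 + 42*c2 + 9*c2^2
                                 + 18*c1*c3 + 5*c3^2)
    """
    params.validate()
    a, b, c1, c2, c3 = params.a, params.b, params.c1, params.c2, params.c3
    poly = 105.0 + 21.0 * c1**2 + 42.0 * c2 + 9.0 * c2**2 + 18.0 * c1 * c3 + 5.0 * c3**2
    return (4.0 * np.pi / 315.0) * a**2 * b * poly


def volume_numeric_oracle(params: EPEParams) -> float:
    """Volume by adaptive quadrature of pi * Int y^2 dx; checks the closed form."""
    params.validate()

    def integrand(x: float) -> float:
        y = epe_y(x, params, "upper")
        return y * y

    scale = params.a**2 * params.b
    val, err = quad(integrand, -params.b, params.b,
                    epsabs=1e-10 * scale, epsrel=_QUAD_REL, limit=200)
    if err > 1e-6 * scale:
        raise ArithmeticError(
            f"volume quadrature did not converge (estimate {val}, error {err})"
        )
    return float(np.pi * val)


def surface_area(params: EPEParams) -> float:
    """Surface area of the solid of revolution, cm^2.

    Substituting x = b*sin(t) turns the improper surface integral into a
    smooth one: with u = sin(t), P the modulation polynomial and
    g(t) = a*(-u*P(u) + cos^2(t)*P'(u)) (which is b*cos(t)*dy/dx),

        S = 2*pi*a * Int_{-pi/2}^{pi/2} P(u)*cos(t)
                       * sqrt(b^2*cos^2(t) + g(t)^2) / b * ... dt

    evaluated below in the algebraically equivalent form
    y * sqrt((dx/dt)^2 + (dy/dt)^2).
    """
    params.validate()
    a, b = params.a, params.b

    def integrand(t: float) -> float:
        u = np.sin(t)
        cos_t = np.cos(t)
        p = float(params.poly(u))
        dp = float(params.poly_deriv(u))
        y = a * cos_t * p
        dxdt = b * cos_t
        dydt = a * (-u * p + cos_t * cos_t * dp)
        return y * np.hypot(dxdt, dydt)

    scale = a * b
    val, err = quad(integrand, -np.pi / 2.0, np.pi / 2.0,
                    epsabs=_QUAD_ABS_SCALE * scale, epsrel=_QUAD_REL, limit=200)
    if err > 1e-6 * scale:
        raise ArithmeticError(
            f"surface quadrature did not converge (estimate {val}, error {err})"
        )
    return float(2.0 * np.pi * val)


def shape_metrics(params: EPEParams) -> GeometryResult:
    """Bundle volume (closed form), surface area, length, width and W/L."""
    length, width = length_width(params)
    return GeometryResult(
        v_pred=volume_closed_form(params),
        s=surface_area(params),
        l=length,
        w=width,
        w_over_l=width / length,
    )
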