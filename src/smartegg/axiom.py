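"""Main-Axiom analysis and boundary-shape theory.

The *Main Axiom* of an egg contour formula requires that the interior
extremum of the contour function fall exactly at the measured
maximum-breadth section: y(w) = B/2 and y'(w) = 0.  A model violating it
draws an outline whose widest point is displaced from, and wider or
narrower than, the breadth that was measured on the egg — the overall
dimensions of the drawn egg no longer match the real one.

This module computes Axiom residuals for any resolved contour, the
Axiom-constrained parameter derivations (the slope parameter, and the
pointed quarter-diameter r that makes the five-parameter variant
compliant), the boundary ratio curves of the parabola-to-Hugelschaffer
pointed-end continuum, and the normalized theoretical profile atlases
built from those ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geometry import (
    SQRT3,
    AdmissibilityWarning,
    AuxMeasures,
    AxialDims,
    ConfigurationError,
    DomainError,
    ModelSpec,
    Variant,
    canonical_contour,
    contour_slope,
    tan_theta_resolve,
)

__all__ = [
    "AxiomReport",
    "axiom_residual",
    "axiom_tan_theta",
    "axiom_required_r",
    "axiom_r_curve",
    "ratio_bounds",
    "ratio_table",
    "atlas",
    "contour_argmax",
    "DEFAULT_T_GRID",
    "TOL_VALUE_REL",
    "TOL_SLOPE",
]

# Compliance tolerances: the value residual is compared relative to B, the
# slope residual is dimensionless.  Engineering choices (no published ones).
TOL_VALUE_REL = 1e-12
TOL_SLOPE = 1e-9

#: the five-step w/L grid used for the theoretical profile atlases
DEFAULT_T_GRID = (0.0, 0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class AxiomReport:
    """Main-Axiom residuals of a resolved contour.

    value_residual = y(w) - B/2 (length units); slope_residual = y'(w)
    (dimensionless).  ``compliant`` is True when both are below tolerance
    (|value| <= tol_v * B, |slope| <= tol_s).
    """

    value_residual: float
    slope_residual: float
    compliant: bool


def axiom_residual(
    spec: ModelSpec,
    tol_value_rel: float = TOL_VALUE_REL,
    tol_slope: float = TOL_SLOPE,
) -> AxiomReport:
    """Evaluate the Main-Axiom residuals of a resolved contour.

    The slope residual uses the analytic derivative of the canonical form
    at x = w, which reduces to

        tan(theta) sqrt(L^2-4w^2) / L  -  2 B w / (L^2-4w^2)

    The Axiom-constrained variant SM_MA is compliant by construction for
    every admissible parameter set.
    """
    dims = spec.dims
    value_res = float(canonical_contour(spec, dims.w) - dims.B / 2.0)
    slope_res = float(contour_slope(spec, dims.w))
    ok = abs(value_res) <= tol_value_rel * dims.B and abs(slope_res) <= tol_slope
    return AxiomReport(value_res, slope_res, ok)


def axiom_tan_theta(dims: AxialDims) -> float:
    """Slope parameter forced by the Main Axiom.

    tan(theta) = 2 B L w / (L^2 - 4 w^2)^(3/2); identical to the SM_MA
    resolver and strictly increasing in w for fixed L, B.
    """
    return tan_theta_resolve(Variant.SM_MA, dims)


def axiom_required_r(dims: AxialDims, R: float) -> float:
    """Pointed quarter-diameter r that makes the r/R-variant Axiom-compliant.

    r = R - sqrt(3) L^2 B w / (2 (L^2 - 4 w^2)^(3/2)).  The result can be
    non-positive for extreme parameter combinations; it is returned as-is
    (a non-physical r, to be flagged by the caller) rather than raised,
    so parameter scans can report where compliance becomes impossible.
    """
    if R <= 0:
        raise ValueError(f"R must be > 0, got {R}")
    L, B, w = dims.L, dims.B, dims.w
    s = dims.half_span
    return float(R - SQRT3 * L**2 * B * w / (2.0 * s**3))


def axiom_r_curve(t):
    """Axiom-compatible r/B ratio as a function of t = w/L.

    Combines the compliance condition on r with the Hugelschaffer blunt-end
    ratio R/B:

        r/B = (sqrt(3)/2) [ 1 / (2 sqrt(1 - 2t + 4t^2))
                            - 1 / ((1 - 4t^2) sqrt(t^-2 - 4)) ]

    t = 0 is evaluated as the analytic limit sqrt(3)/4.  Values above the
    empirical band t <= 0.2 warn; t >= 0.5 is outside the model domain.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr >= 0.5):
        raise DomainError("w/L must lie in [0, 0.5)")
    if np.any(t_arr > 0.2):
        warnings.warn(
            "w/L above the empirical band [0, 0.2]",
            AdmissibilityWarning,
            stacklevel=2,
        )
    # second term vanishes in the t -> 0 limit; evaluate it on t > 0 only
    second = np.zeros_like(t_arr)
    pos = t_arr > 0
    tp = t_arr[pos] if t_arr.shape else (t_arr if pos else None)
    if t_arr.shape:
        second[pos] = 1.0 / ((1.0 - 4.0 * tp**2) * np.sqrt(tp**-2.0 - 4.0))
    elif pos:
        second = 1.0 / ((1.0 - 4.0 * t_arr**2) * np.sqrt(t_arr**-2.0 - 4.0))
    out = SQRT3 / 2.0 * (1.0 / (2.0 * np.sqrt(1.0 - 2.0 * t_arr + 4.0 * t_arr**2)) - second)
    return out if out.shape else float(out)


# --- boundary-shape ratio curves (pointed-end continuum) -------------------

def b0_ratio_parabola(t):
    """Minimum admissible B0/B (parabolic pointed end): 1/sqrt(1 + 2t)."""
    t = np.asarray(t, dtype=float)
    return 1.0 / np.sqrt(1.0 + 2.0 * t)


def b0_ratio_huegel(t):
    """Maximum admissible B0/B (Hugelschaffer ovoid): 1/sqrt(1 + 4t^2)."""
    t = np.asarray(t, dtype=float)
    return 1.0 / np.sqrt(1.0 + 4.0 * t**2)


def b0_ratio_average(t):
    """Arithmetic mean of the parabolic and Hugelschaffer B0/B bounds."""
    return 0.5 * (b0_ratio_parabola(t) + b0_ratio_huegel(t))


def r_ratio_parabola(t):
    """Pointed quarter-diameter ratio r/B for the parabolic bound."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (2.0 * np.sqrt(2.0 * (1.0 + 2.0 * t)))


def r_ratio_huegel(t):
    """r/B for the Hugelschaffer bound: (1/4) sqrt(3 / (1 + 2t + 4t^2))."""
    t = np.asarray(t, dtype=float)
    return 0.25 * np.sqrt(3.0 / (1.0 + 2.0 * t + 4.0 * t**2))


def r_ratio_average(t):
    """Arithmetic mean of the parabolic and Hugelschaffer r/B bounds."""
    return 0.5 * (r_ratio_parabola(t) + r_ratio_huegel(t))


def R_ratio(t):
    """Blunt quarter-diameter ratio R/B: (1/4) sqrt(3 / (1 - 2t + 4t^2)).

    The blunt half follows the Hugelschaffer ovoid for every pointed-end
    shape, so this ratio is shared by the whole continuum.
    """
    t = np.asarray(t, dtype=float)
    return 0.25 * np.sqrt(3.0 / (1.0 - 2.0 * t + 4.0 * t**2))


def ratio_bounds(t: float) -> dict[str, float]:
    """All boundary ratios at a single t = w/L (one RatioTable row)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr >= 0.5):
        raise DomainError("w/L must lie in [0, 0.5)")
    return {
        "t": float(t),
        "b0_over_B_min": float(b0_ratio_parabola(t)),
        "b0_over_B_avg": float(b0_ratio_average(t)),
        "b0_over_B_max": float(b0_ratio_huegel(t)),
        "r_over_B_parabola": float(r_ratio_parabola(t)),
        "r_over_B_avg": float(r_ratio_average(t)),
        "r_over_B_huegel": float(r_ratio_huegel(t)),
        "R_over_B": float(R_ratio(t)),
        "r_over_B_axiom": float(axiom_r_curve(t)),
    }


def ratio_table(t_grid=DEFAULT_T_GRID) -> pd.DataFrame:
    """Boundary-ratio table over a w/L grid (CSV-exportable)."""
    return pd.DataFrame([ratio_bounds(t) for t in np.asarray(t_grid, dtype=float)])


# --- theoretical profile atlases ------------------------------------------

_B0_RULES = {
    "parabola": b0_ratio_parabola,
    "average": b0_ratio_average,
    "huegelschaeffer": b0_ratio_huegel,
}
_R_RULES = {
    "parabola": r_ratio_parabola,
    "average": r_ratio_average,
    "huegelschaeffer": r_ratio_huegel,
}


def _normalized_spec(variant: str, ratio_rule: str, t: float) -> ModelSpec:
    """Unit-normalized (L=1, B=1, w=t) spec for an atlas member."""
    dims = AxialDims(L=1.0, B=1.0, w=float(t))
    if variant == "SM_B0":
        rule = _B0_RULES.get(ratio_rule)
        if rule is None:
            raise ConfigurationError(f"unknown ratio rule {ratio_rule!r}")
        if t == 0:
            return ModelSpec.build(Variant.SM, dims, AuxMeasures(tan_theta=0.0))
        return ModelSpec.build(Variant.SM_B0, dims, AuxMeasures(B0=float(rule(t))))
    if variant == "SM_r":
        rule = _R_RULES.get(ratio_rule)
        if rule is None:
            raise ConfigurationError(f"unknown ratio rule {ratio_rule!r}")
        return ModelSpec.build(
            Variant.SM_R, dims, AuxMeasures(r=float(rule(t)), R=float(R_ratio(t)))
        )
    raise ConfigurationError(f"unknown atlas variant {variant!r}")


def atlas(
    variant: str = "SM_B0",
    ratio_rule: str = "huegelschaeffer",
    t_grid=DEFAULT_T_GRID,
    n_x: int = 401,
) -> pd.DataFrame:
    """Normalized theoretical egg profiles over a w/L grid.

    For each t the chosen variant is resolved with its auxiliary
    measurement supplied by a boundary-shape ratio rule (parabola, average
    or Hugelschaffer), everything in dimensionless units (x/L, y/B with
    L = B = 1, w = t).  The result is a tidy frame with columns
    ``t, x, y``.

    These atlases are the constructions that exhibit how the four- and
    five-parameter variants break the Main Axiom: for t > 0 the profile
    maximum exceeds 1/2 (the drawn breadth beats the measured B) and its
    location drifts away from x = t.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid < 0) or np.any(t_grid > 0.2 + 1e-12):
        raise DomainError("atlas t grid must lie in [0, 0.2]")
    x = np.linspace(-0.5, 0.5, int(n_x))
    frames = []
    for t in t_grid:
        spec = _normalized_spec(variant, ratio_rule, float(t))
        frames.append(pd.DataFrame({"t": t, "x": x, "y": canonical_contour(spec, x)}))
    return pd.concat(frames, ignore_index=True)


def atlas_spec(variant: str, ratio_rule: str, t: float) -> ModelSpec:
    """Resolved unit-normalized spec behind one atlas profile."""
    return _normalized_spec(variant, ratio_rule, float(t))


def contour_argmax(spec: ModelSpec, n_scan: int = 10_000) -> tuple[float, float]:
    """Location and value of the contour maximum over [-L/2, L/2].

    Dense scan followed by bounded golden/Brent refinement; the contour is
    smooth with a single interior extremum of interest, so this is robust
    and accurate to ~sqrt(eps) in x.
    """
    L = spec.dims.L
    xs = np.linspace(-L / 2, L / 2, int(n_scan))
    ys = canonical_contour(spec, xs)
    i = int(np.argmax(ys))
    lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
    res = minimize_scalar(
        lambda x: -canonical_contour(spec, x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * L},
    )
    return float(res.x), float(-res.fun)
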