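"""Contour fit evaluation: the mean-percentage-error metric and the
all-variants comparison workflow.

The fit of a model contour to a digitized profile is scored by the
approximate mean percentage error

    epsilon = (100 / k) * sum_i |v1_i - v2_i| / |v1_i|

where v1 is the measured half-breadth, v2 the model half-breadth at the
same axial position, and k the number of points entering the sum.  Points
where the measured breadth is (numerically) zero — the tips — are
excluded from the sum and reported separately, since the relative error
is undefined there.

Model ranking by epsilon alone is not the whole story: a variant can copy
the contour accurately while violating the Main Axiom (drawing its widest
section away from the measured one).  Each fit report therefore carries
the Axiom residuals next to epsilon so accuracy and geometric compliance
are judged together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axiom import AxiomReport, axiom_residual
from .geometry import (
    N_PARAMS,
    AuxMeasures,
    ModelSpec,
    Variant,
    canonical_contour,
)
from .measure import DigitizedProfile, MeasuredParams, measure_profile

__all__ = [
    "FitReport",
    "UndefinedMetricError",
    "epsilon",
    "epsilon_detail",
    "compare_variants",
    "DEFAULT_VARIANTS",
]

#: variants compared by default: everything resolvable from the measured
#: parameter set (L, B, w, B0, r, R), most parsimonious last.
DEFAULT_VARIANTS = (
    Variant.SM_R,
    Variant.SM_B0,
    Variant.SM_U,
    Variant.SM_B02,
    Variant.SM_R2,
    Variant.SM_MA,
)

#: relative floor below which a measured half-breadth counts as a tip zero
ZERO_REL = 1e-9


class UndefinedMetricError(ValueError):
    """Every profile point was excluded; epsilon is undefined."""


@dataclass(frozen=True)
class FitReport:
    """Fit of one variant to one profile: accuracy plus Axiom compliance."""

    variant: Variant
    epsilon: float
    k_used: int
    excluded: int
    n_params: int
    tan_theta: float
    params_used: MeasuredParams
    axiom: AxiomReport


def epsilon_detail(
    profile: DigitizedProfile, spec: ModelSpec
) -> tuple[float, int, int]:
    """(epsilon %, points used, points excluded) for one model contour.

    The model is evaluated at the profile's own axial positions (clipped
    to the model's length span when the two L differ at the last digit).
    """
    xc, v1, _L = profile.centered()
    Lm = spec.dims.L
    x_eval = np.clip(xc, -Lm / 2.0, Lm / 2.0)
    v2 = np.asarray(canonical_contour(spec, x_eval))
    B_ref = 2.0 * float(v1.max())
    include = np.abs(v1) > ZERO_REL * B_ref
    k = int(include.sum())
    if k == 0:
        raise UndefinedMetricError("all profile points excluded (zero breadths)")
    eps = 100.0 / k * float(np.sum(np.abs((v1[include] - v2[include]) / v1[include])))
    return eps, k, int(len(v1) - k)


def epsilon(profile: DigitizedProfile, spec: ModelSpec) -> float:
    """Mean percentage error (%) of a model contour against a profile."""
    return epsilon_detail(profile, spec)[0]


def _spec_for(variant: Variant, params: MeasuredParams) -> ModelSpec:
    aux = params.aux
    need = {
        Variant.SM_R: AuxMeasures(r=aux.r, R=aux.R),
        Variant.SM_B0: AuxMeasures(B0=aux.B0),
        Variant.SM_U: AuxMeasures(r=aux.r),
        Variant.SM_B02: AuxMeasures(),
        Variant.SM_R2: AuxMeasures(),
        Variant.SM_MA: AuxMeasures(),
    }.get(variant, aux)
    return ModelSpec.build(variant, params.dims, need)


def compare_variants(
    profile: DigitizedProfile,
    variants=DEFAULT_VARIANTS,
    params: MeasuredParams | None = None,
    refinement: str = "structural",
) -> list[FitReport]:
    """Fit every requested variant to a profile and rank by epsilon.

    The profile is measured once (unless ``params`` is supplied) and each
    variant is resolved from that shared parameter set, so the comparison
    isolates how well each slope-parameter rule reproduces the outline.
    Reports are sorted by epsilon ascending.
    """
    if params is None:
        params = measure_profile(profile, refinement=refinement)
    reports = []
    for v in variants:
        v = Variant(v)
        spec = _spec_for(v, params)
        eps, k, excl = epsilon_detail(profile, spec)
        reports.append(
            FitReport(
                variant=v,
                epsilon=eps,
                k_used=k,
                excluded=excl,
                n_params=N_PARAMS[v],
                tan_theta=spec.tan_theta,
                params_used=params,
                axiom=axiom_residual(spec),
            )
        )
    reports.sort(key=lambda rep: rep.epsilon)
    return reports
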