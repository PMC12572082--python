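"""Model/Results surface for fitting the Smart family to a digitized profile.

`SmartEggModel` wraps the measurement + evaluation workflow in the style
of statistical modelling packages: build the model from data (a
:class:`~smartegg.measure.DigitizedProfile` or a plain two-column
DataFrame), call :meth:`~SmartEggModel.fit`, and read the ranked
per-variant fits, Axiom residuals and recovered parameters off the
returned :class:`SmartEggResults`, whose :meth:`~SmartEggResults.summary`
prints the comparison table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import DEFAULT_VARIANTS, FitReport, compare_variants
from .geometry import ModelSpec, Orientation, Variant, canonical_contour
from .measure import DigitizedProfile, MeasuredParams, measure_profile, refit_tan_theta

__all__ = ["SmartEggModel", "SmartEggResults"]


class SmartEggModel:
    """Smart-family contour model for one digitized egg profile.

    Parameters
    ----------
    profile : DigitizedProfile
        The observed half-outline.
    variants : sequence of Variant, optional
        Family members to fit; defaults to every variant resolvable from
        the measured parameter set.
    """

    def __init__(self, profile: DigitizedProfile, variants=DEFAULT_VARIANTS):
        self.profile = profile
        self.variants = tuple(Variant(v) for v in variants)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        x: str = "x",
        y: str = "y",
        units: str = "px",
        scale: float | None = None,
        orientation: Orientation = Orientation.POINTED_NEGATIVE_X,
        variants=DEFAULT_VARIANTS,
    ) -> "SmartEggModel":
        """Build from a two-column table of (x, half-breadth) samples."""
        prof = DigitizedProfile(
            x=df[x].to_numpy(float),
            y=df[y].to_numpy(float),
            units=units,
            scale=scale,
            orientation=orientation,
        )
        return cls(prof, variants=variants)

    def fit(self, refinement: str = "structural") -> "SmartEggResults":
        """Measure the profile and fit every requested variant.

        ``refinement`` is the sub-pixel policy for locating the
        maximum-breadth section (see :func:`smartegg.measure.measure_profile`).
        """
        params = measure_profile(self.profile, refinement=refinement)
        reports = compare_variants(self.profile, self.variants, params=params)
        tan_theta_ls = refit_tan_theta(self.profile, params.dims)
        return SmartEggResults(self, params, reports, tan_theta_ls)


class SmartEggResults:
    """Fit results: recovered parameters and the ranked variant comparison."""

    def __init__(
        self,
        model: SmartEggModel,
        params: MeasuredParams,
        reports: list[FitReport],
        tan_theta_ls: float,
    ):
        self.model = model
        self.params = params
        #: per-variant fit reports, sorted by epsilon ascending
        self.reports = reports
        #: free least-squares slope parameter (diagnostic: the best tan theta
        #: any fixed-point rule could hope to approach given these dims)
        self.tan_theta_ls = tan_theta_ls

    @property
    def best(self) -> FitReport:
        return self.reports[0]

    @property
    def epsilon(self) -> pd.Series:
        return pd.Series(
            {r.variant.value: r.epsilon for r in self.reports}, name="epsilon"
        )

    def spec(self, variant: Variant | str | None = None) -> ModelSpec:
        """Resolved spec of a fitted variant (default: the best one)."""
        if variant is None:
            return _report_spec(self.best)
        v = Variant(variant)
        for rep in self.reports:
            if rep.variant is v:
                return _report_spec(rep)
        raise KeyError(f"variant {v} was not fitted")

    def predict(self, x=None, variant: Variant | str | None = None):
        """Model half-breadth at given axial positions (profile's own by default)."""
        spec = self.spec(variant)
        if x is None:
            x, _, _ = self.model.profile.centered()
        return canonical_contour(spec, np.asarray(x, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """The comparison table as a DataFrame."""
        rows = [
            {
                "variant": r.variant.value,
                "n_params": r.n_params,
                "epsilon_pct": r.epsilon,
                "tan_theta": r.tan_theta,
                "axiom_value_residual": r.axiom.value_residual,
                "axiom_slope_residual": r.axiom.slope_residual,
                "axiom_compliant": r.axiom.compliant,
                "k_used": r.k_used,
                "excluded": r.excluded,
            }
            for r in self.reports
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary (parameters + ranked variant table)."""
        d, a = self.params.dims, self.params.aux
        u = self.params.units
        head = [
            "Smart egg-shape model comparison",
            "=" * 70,
            f"profile: {self.model.profile.n_points} points [{u}]"
            + (
                f", scale {self.model.profile.scale:.6g} mm/px"
                if self.model.profile.scale
                else ""
            ),
            f"measured: L = {d.L:.4g} {u}, B = {d.B:.4g} {u}, "
            f"w = {d.w:.4g} {u} (w/L = {d.w / d.L:.4f})",
            f"          B0 = {a.B0:.4g} {u}, r = {a.r:.4g} {u}, R = {a.R:.4g} {u}",
            f"free LS slope: tan(theta) = {self.tan_theta_ls:.6g}",
            "-" * 70,
        ]
        table = self.to_frame()
        with pd.option_context("display.width", 120, "display.float_format", "{:.6g}".format):
            body = table.to_string(index=False)
        return "\n".join(head + [body])

    def plot(self, ax=None, variants=None):  # pragma: no cover - visual aid
        """Overlay the profile and fitted contours (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        xc, y, _ = self.model.profile.centered()
        ax.plot(xc, y, "k.", ms=2, label="profile")
        for rep in self.reports if variants is None else [
            r for r in self.reports if r.variant.value in set(variants)
        ]:
            ax.plot(xc, canonical_contour(_report_spec(rep), xc), lw=1,
                    label=f"{rep.variant.value} (eps={rep.epsilon:.2f}%)")
        ax.set_xlabel("x")
        ax.set_ylabel("half-breadth")
        ax.legend(fontsize=8)
        ax.set_aspect("equal", adjustable="datalim")
        return ax


def _report_spec(rep: FitReport) -> ModelSpec:
    from .evaluate import _spec_for

    return _spec_for(rep.variant, rep.params_used)
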