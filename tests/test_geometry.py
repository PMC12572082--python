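"""Canonical contour form, slope-parameter resolvers and boundary models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartegg.geometry import (
    AuxMeasures,
    AxialDims,
    ConfigurationError,
    DomainError,
    ModelSpec,
    Variant,
    b0_from_dims,
    canonical_contour,
    contour_slope,
    ellipse_contour,
    huegelschaeffer_contour,
    parabola_contour,
    tan_theta_resolve,
)

from _oracles import (
    printed_sm,
    printed_sm_b0,
    printed_sm_b02,
    printed_sm_ma,
    printed_sm_r,
    printed_sm_r2,
    printed_sm_u,
)
from conftest import random_dims

# high-precision reference values (mpmath, 50 digits)
Y_REF_SM = 21.142582021827996  # L=60 B=45 w=3 tan=0.15 at x=15
TAN_MA_REF = 0.07613922842872819  # L=60 B=45 w=3, Axiom slope
Y_REF_MA = 20.374998367541906  # same dims, Axiom contour at x=15


def sm_spec(L, B, w, tan_theta):
    return ModelSpec.build(
        Variant.SM, AxialDims(L, B, w), AuxMeasures(tan_theta=tan_theta)
    )


class TestCanonicalContour:
    def test_tip_zeros_exact(self):
        spec = sm_spec(60.0, 45.0, 3.0, 0.15)
        assert canonical_contour(spec, 30.0) == 0.0
        assert canonical_contour(spec, -30.0) == 0.0

    def test_pure_ellipse_midpoint(self):
        spec = sm_spec(2.0, 1.0, 0.0, 0.0)
        assert canonical_contour(spec, 0.0) == pytest.approx(0.5, abs=1e-15)

    def test_reference_value(self):
        spec = sm_spec(60.0, 45.0, 3.0, 0.15)
        assert canonical_contour(spec, 15.0) == pytest.approx(Y_REF_SM, rel=1e-14)

    def test_domain_error(self):
        spec = sm_spec(60.0, 45.0, 3.0, 0.15)
        with pytest.raises(DomainError):
            canonical_contour(spec, 30.5)

    def test_vectorized(self):
        spec = sm_spec(60.0, 45.0, 3.0, 0.15)
        x = np.linspace(-30, 30, 11)
        y = canonical_contour(spec, x)
        assert y.shape == (11,)
        assert np.all(np.isfinite(y))

    @settings(derandomize=True, max_examples=200)
    @given(
        L=st.floats(10, 200),
        bl=st.floats(0.3, 0.9),
        wl=st.floats(0, 0.199),
        tt=st.floats(-0.5, 0.5),
    )
    def test_fixed_point_invariant(self, L, bl, wl, tt):
        """Every variant passes through (w, B/2) exactly."""
        spec = sm_spec(L, bl * L, wl * L, tt)
        assert canonical_contour(spec, spec.dims.w) == pytest.approx(
            spec.dims.B / 2, rel=1e-12
        )


class TestResolvers:
    def test_sm_r_equal_radii_is_symmetric(self):
        dims = AxialDims(60, 45, 3)
        assert tan_theta_resolve(Variant.SM_R, dims, AuxMeasures(r=10, R=10)) == 0.0

    def test_main_axiom_w_zero(self):
        assert tan_theta_resolve(Variant.SM_MA, AxialDims(60, 45, 0)) == 0.0

    def test_main_axiom_reference(self):
        dims = AxialDims(60, 45, 3)
        tt = tan_theta_resolve(Variant.SM_MA, dims)
        assert tt == pytest.approx(TAN_MA_REF, rel=1e-14)
        assert tt == pytest.approx(
            2 * 45 * 60 * 3 / (60**2 - 4 * 3**2) ** 1.5, rel=1e-14
        )
        spec = ModelSpec.build(Variant.SM_MA, dims)
        assert canonical_contour(spec, 15.0) == pytest.approx(Y_REF_MA, rel=1e-14)

    def test_missing_aux_raises(self):
        dims = AxialDims(60, 45, 3)
        for v in (Variant.SM, Variant.SM_R, Variant.SM_B0, Variant.SM_U):
            with pytest.raises(ConfigurationError):
                tan_theta_resolve(v, dims, AuxMeasures())

    def test_b0_limit_at_w_zero(self):
        dims = AxialDims(60, 45, 0)
        assert tan_theta_resolve(Variant.SM_B0, dims, AuxMeasures(B0=45.0)) == 0.0
        with pytest.raises(ConfigurationError):
            tan_theta_resolve(Variant.SM_B0, dims, AuxMeasures(B0=40.0))

    @pytest.mark.parametrize("variant", [Variant.SM_B02, Variant.SM_R2, Variant.SM_MA])
    def test_three_param_variants_collapse_to_ellipse_at_w0(self, variant):
        dims = AxialDims(60.0, 45.0, 0.0)
        spec = ModelSpec.build(variant, dims)
        x = np.linspace(-30, 30, 101)
        np.testing.assert_allclose(
            canonical_contour(spec, x), ellipse_contour(dims, x), rtol=0, atol=1e-12
        )

    def test_consistency_chain_sm_r2(self):
        """Eq-6 slope from the boundary-theory quarter radii equals SM_r2."""
        from smartegg.axiom import R_ratio, r_ratio_huegel

        for t in np.linspace(0.001, 0.2, 25):
            L, B = 57.0, 40.0
            dims = AxialDims(L, B, t * L)
            aux = AuxMeasures(r=float(r_ratio_huegel(t)) * B, R=float(R_ratio(t)) * B)
            via_radii = tan_theta_resolve(Variant.SM_R, dims, aux)
            direct = tan_theta_resolve(Variant.SM_R2, dims)
            assert via_radii == pytest.approx(direct, rel=1e-12)


class TestPrintedFormEquivalence:
    """The canonical form + resolver reproduces each printed equation."""

    def _draws(self, n=1000, seed=7):
        rng = np.random.default_rng(seed)
        for _ in range(n):
            dims = random_dims(rng, wl_range=(1e-4, 0.2))
            x = rng.uniform(-dims.L / 2, dims.L / 2)
            yield rng, dims, x

    def test_all_variants_match_printed_forms(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            dims = random_dims(rng, wl_range=(1e-4, 0.2))
            L, B, w = dims.L, dims.B, dims.w
            x = rng.uniform(-L / 2, L / 2)
            r = rng.uniform(0.2, 0.5) * B
            R = rng.uniform(0.2, 0.5) * B
            B0 = rng.uniform(0.8, 1.1) * B
            cases = {
                Variant.SM_R: (AuxMeasures(r=r, R=R), printed_sm_r(L, B, w, r, R, x)),
                Variant.SM_B0: (AuxMeasures(B0=B0), printed_sm_b0(L, B, w, B0, x)),
                Variant.SM_B02: (AuxMeasures(), printed_sm_b02(L, B, w, x)),
                Variant.SM_R2: (AuxMeasures(), printed_sm_r2(L, B, w, x)),
                Variant.SM_MA: (AuxMeasures(), printed_sm_ma(L, B, w, x)),
                Variant.SM_U: (AuxMeasures(r=r), printed_sm_u(L, B, w, r, x)),
            }
            for variant, (aux, expected) in cases.items():
                got = canonical_contour(ModelSpec.build(variant, dims, aux), x)
                assert got == pytest.approx(expected, rel=1e-12, abs=1e-12 * B), variant


class TestB0Conversion:
    def test_w_zero_gives_B(self):
        assert b0_from_dims(AxialDims(60, 45, 0), 0.3) == pytest.approx(45.0)

    def test_zero_slope_exceeds_B(self):
        dims = AxialDims(60, 45, 5)
        assert b0_from_dims(dims, 0.0) > 45.0

    def test_round_trip_inverse_pair(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            dims = random_dims(rng, wl_range=(0.01, 0.2))
            B0 = rng.uniform(0.85, 1.05) * dims.B
            tt = tan_theta_resolve(Variant.SM_B0, dims, AuxMeasures(B0=B0))
            assert b0_from_dims(dims, tt) == pytest.approx(B0, rel=1e-12)

    def test_non_physical_flagged(self):
        dims = AxialDims(60, 45, 10)
        with pytest.raises(ValueError, match="non-physical"):
            b0_from_dims(dims, 1e3)


class TestBoundaryContours:
    """Parabola and Hugelschaffer bounds (native, pointed-positive-x)."""

    dims = AxialDims(60.0, 45.0, 6.0)

    def test_parabola_anchor_points(self):
        d = self.dims
        assert parabola_contour(d, d.L / 2) == pytest.approx(0.0, abs=1e-12)
        assert parabola_contour(d, -d.w) == pytest.approx(d.B / 2, rel=1e-14)
        # mid-length value reproduces the B0/B bound
        expect = d.B / 2 / np.sqrt(1 + 2 * d.w / d.L)
        assert parabola_contour(d, 0.0) == pytest.approx(expect, rel=1e-14)

    def test_huegelschaeffer_anchor_points(self):
        d = self.dims
        assert huegelschaeffer_contour(d, d.L / 2) == 0.0
        assert huegelschaeffer_contour(d, -d.L / 2) == 0.0
        expect = d.B / 2 / np.sqrt(1 + 4 * (d.w / d.L) ** 2)
        assert huegelschaeffer_contour(d, 0.0) == pytest.approx(expect, rel=1e-14)

    def test_huegelschaeffer_extremum_at_minus_w(self):
        """d(y^2)/dx of the ovoid factorizes with its interior root at x=-w."""
        sympy = pytest.importorskip("sympy")
        x = sympy.symbols("x", real=True)
        L, B, w = sympy.symbols("L B w", positive=True)
        y2 = (B / 2) ** 2 * (L**2 - 4 * x**2) / (L**2 + 8 * w * x + 4 * w**2)
        num = sympy.numer(sympy.together(sympy.diff(y2, x)))
        roots = sympy.solve(sympy.expand(num), x)
        assert -w in roots
        d = self.dims
        assert huegelschaeffer_contour(d, -d.w) == pytest.approx(d.B / 2, rel=1e-14)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            parabola_contour(self.dims, 31.0)
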