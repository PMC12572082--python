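import numpy as np
import pytest

from smartegg.geometry import (
    AuxMeasures,
    AxialDims,
    ModelSpec,
    Variant,
    canonical_contour,
)
from smartegg.axiom import axiom_tan_theta
from smartegg.synth import SynthConfig, synth_profile


def random_dims(rng, L_range=(30.0, 80.0), bl_range=(0.5, 0.85), wl_range=(0.0, 0.2)):
    """Admissible (L, B, w) draw inside the empirical w/L band."""
    L = rng.uniform(*L_range)
    B = rng.uniform(*bl_range) * L
    w = rng.uniform(*wl_range) * L
    return AxialDims(L=L, B=B, w=w)


def family_egg(rng, L=398.0, axiom=False):
    """A self-consistent SM_r egg: (dims, r, R, tan_theta, spec).

    r and R are the contour's own quarter radii, so the five parameters
    describe one exact contour.  ``axiom=True`` pins the slope to the
    Main-Axiom value (maximum breadth exactly at x = w); otherwise the
    slope is a realistic multiple of it.
    """
    wl = rng.uniform(0.03, 0.14)
    bl = rng.uniform(0.62, 0.76)
    dims = AxialDims(L=L, B=bl * L, w=wl * L)
    tt = axiom_tan_theta(dims)
    if not axiom:
        tt *= rng.uniform(0.7, 1.3)
    base = ModelSpec.build(Variant.SM, dims, AuxMeasures(tan_theta=tt))
    r = float(canonical_contour(base, -L / 4))
    R = float(canonical_contour(base, L / 4))
    spec = ModelSpec.build(Variant.SM_R, dims, AuxMeasures(r=r, R=R))
    return dims, r, R, tt, spec


def family_profile(seed, n_points=398, quantize=True, axiom=False, noise_sd=0.0):
    """Digitized profile of a family egg plus its generating truth."""
    rng = np.random.default_rng(seed)
    dims, r, R, tt, spec = family_egg(rng, axiom=axiom)
    prof = synth_profile(
        SynthConfig(
            source=spec,
            n_points=n_points,
            quantize=quantize,
            noise_sd=noise_sd,
            seed=seed,
        )
    )
    return prof, dims, r, R, tt, spec


@pytest.fixture(scope="session")
def ellipse_profile():
    """Dense noiseless ellipse half-profile: L = 2, B = 1, 401 points."""
    dims = AxialDims(L=2.0, B=1.0, w=0.0)
    spec = ModelSpec.build(Variant.SM, dims, AuxMeasures(tan_theta=0.0))
    return synth_profile(
        SynthConfig(source=spec, n_points=401, quantize=False, units="mm")
    )
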