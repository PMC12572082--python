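"""Synthetic digitized egg profiles.

Generates pixel-sampled egg outlines with the sampling structure of
photograph-derived contour data: uniform axial sampling, integer-pixel
quantization of the half-breadth, and optional additive noise.  Sources
are either a resolved Smart-family contour or a *blend* egg built from
the pointed-end shape continuum: real pointed ends live between a
parabola (lower bound) and the Hugelschaffer ovoid (upper bound), while
the blunt half always follows the Hugelschaffer ovoid.  Blend eggs are
deliberately outside the Smart family, so they exercise measurement and
model comparison on contours no variant can reproduce exactly.

Three standard fixtures emulate the sampling regimes of characteristic
egg shapes: an ovoid (chicken-like; 398 sample points at L = 398 px), a
conical egg and a pyriform egg (both 215 points at L = 215 px = 57 mm).
Their shape parameters are package choices of realistic values, not
measurements of any particular egg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AxialDims,
    ConfigurationError,
    DomainError,
    ModelSpec,
    Orientation,
    canonical_contour,
    huegelschaeffer_contour,
    parabola_contour,
)
from .measure import DigitizedProfile

__all__ = [
    "BlendSpec",
    "SynthConfig",
    "blend_contour",
    "synth_profile",
    "standard_fixtures",
    "FIXTURE_PARAMS",
]


@dataclass(frozen=True)
class BlendSpec:
    """Pointed-end continuum egg: parabola-to-Hugelschaffer mix.

    ``lam`` mixes the pointed-side half-breadth linearly between the
    parabola (0) and the Hugelschaffer ovoid (1); the blunt half is always
    the Hugelschaffer ovoid.  Native orientation follows the boundary
    contours: pointed end at x = +L/2, maximum breadth at x = -w.
    """

    dims: AxialDims
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ConfigurationError(f"blend lambda must be in [0, 1], got {self.lam}")


def blend_contour(spec: BlendSpec, x):
    """Half-breadth of a blend egg (native, pointed-positive-x orientation).

    Both boundary contours pass through (-w, B/2), so the piecewise blend
    is continuous at the junction for every lambda.
    """
    x = np.asarray(x, dtype=float)
    L, w = spec.dims.L, spec.dims.w
    if np.any(np.abs(x) > L / 2 * (1 + 1e-12)):
        raise DomainError("x outside [-L/2, L/2]")
    hueg = huegelschaeffer_contour(spec.dims, x)
    par = parabola_contour(spec.dims, x)
    pointed = x >= -w
    y = np.where(pointed, (1.0 - spec.lam) * par + spec.lam * hueg, hueg)
    return y if y.shape else float(y)


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for one synthetic digitized profile.

    ``quantize`` rounds half-breadths to the integer pixel grid (the
    stand-in for digitization error); ``noise_sd`` adds zero-mean Gaussian
    noise (truncated so y stays non-negative) before quantization and
    defaults to 0 because pixel data carry no other noise source.
    ``seed`` fixes the output exactly.
    """

    source: ModelSpec | BlendSpec
    n_points: int = 398
    quantize: bool = True
    noise_sd: float = 0.0
    seed: int = 0
    orientation: Orientation = Orientation.POINTED_NEGATIVE_X
    units: str = "px"
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.n_points < 7:
            raise ConfigurationError("n_points must be >= 7")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def synth_profile(cfg: SynthConfig) -> DigitizedProfile:
    """Sample a digitized profile from a contour source.

    Points are uniformly spaced across the full length [-L/2, L/2]
    (tips included).  Smart-family sources are generated in the canonical
    pointed-negative-x orientation, blend sources in their native flipped
    orientation; the output is converted to ``cfg.orientation``.
    """
    dims = cfg.source.dims
    x = np.linspace(-dims.L / 2.0, dims.L / 2.0, cfg.n_points)
    if isinstance(cfg.source, BlendSpec):
        y = np.asarray(blend_contour(cfg.source, x))
        native = Orientation.POINTED_POSITIVE_X
    else:
        y = np.asarray(canonical_contour(cfg.source, x))
        native = Orientation.POINTED_NEGATIVE_X
    y = np.maximum(y, 0.0)

    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        y = np.maximum(y + rng.normal(0.0, cfg.noise_sd, size=y.shape), 0.0)
        y[0] = y[-1] = 0.0  # tips are pinned by the egg length
    if cfg.quantize:
        y = np.rint(y)

    if native is not cfg.orientation:
        x, y = -x[::-1], y[::-1]
    return DigitizedProfile(
        x=x, y=y, units=cfg.units, scale=cfg.scale, orientation=cfg.orientation
    )


#: standard fixture recipes: (dims in px, blend lambda, n_points, mm/px).
#: Shape ratios are realistic for each class (chicken B/L ~ 0.74 and nearly
#: Hugelschaffer-shaped; pyriform eggs slimmer, strongly offset, near the
#: parabolic bound), with w/L inside the empirical band [0, 0.2].
FIXTURE_PARAMS: dict[str, dict] = {
    "ovoid": dict(L=398.0, B=296.0, w=20.0, lam=0.9, n_points=398, scale=None),
    "conical": dict(L=215.0, B=150.0, w=19.0, lam=0.5, n_points=215, scale=57.0 / 215.0),
    "pyriform": dict(L=215.0, B=140.0, w=30.0, lam=0.15, n_points=215, scale=57.0 / 215.0),
}


def standard_fixtures(seed: int = 0) -> dict[str, DigitizedProfile]:
    """The three standard test profiles (ovoid, conical, pyriform).

    Noiseless, pixel-quantized, in the canonical orientation; ``seed`` is
    accepted for interface uniformity (it only matters when a caller
    rebuilds the configs with noise).
    """
    out = {}
    for name, p in FIXTURE_PARAMS.items():
        blend = BlendSpec(AxialDims(L=p["L"], B=p["B"], w=p["w"]), lam=p["lam"])
        cfg = SynthConfig(
            source=blend,
            n_points=p["n_points"],
            quantize=True,
            noise_sd=0.0,
            seed=seed,
            scale=p["scale"],
        )
        out[name] = synth_profile(cfg)
    return out
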