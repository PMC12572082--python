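"""Smart-model (SM) egg contour family.

Smart's model describes the half-breadth of an avian egg as an ellipse whose
minor semi-axis grows linearly along the long axis:

    y(x) = (P + Q (x - w)) * sqrt(L^2 - 4 x^2),   -L/2 <= x <= L/2

with P = B / (2 sqrt(L^2 - 4 w^2)) and Q = tan(theta) / L.  Every member of
the family shares this canonical form and differs only in how the slope
parameter tan(theta) is resolved from measurements:

========  =====================================  =========================
variant   extra measurements                     tan(theta)
========  =====================================  =========================
SM        tan(theta) given directly              as supplied
SM_r      quarter-length diameters r, R          4 (R - r) / (sqrt(3) L)
SM_B0     mid-length breadth B0                  from (0, B0/2) on contour
SM_B02    none (B0 taken from Hugelschaffer)     SM_B0 with B0 eliminated
SM_r2     none (r, R taken from Hugelschaffer)   SM_r with r, R eliminated
SM_MA     none (Main-Axiom constraint)           2 B L w / (L^2-4w^2)^(3/2)
SM_U      pointed quarter-diameter r             hybrid of SM_MA and SM_r
========  =====================================  =========================

Orientation convention: the pointed end sits at x < 0 and the blunt end at
x > 0, so the breadth offset w >= 0 shifts the maximum breadth toward the
blunt end.  The classical parabola and Hugelschaffer boundary contours are
printed in the opposite orientation (pointed end at x > 0); they are provided
here in that native orientation and conversion is an explicit x -> -x flip
with the roles of r and R swapped.

All lengths are unit-agnostic (px or mm) but must be homogeneous per call.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Variant",
    "Orientation",
    "AxialDims",
    "AuxMeasures",
    "ModelSpec",
    "AdmissibilityWarning",
    "DomainError",
    "ConfigurationError",
    "SQRT3",
    "canonical_contour",
    "contour_slope",
    "tan_theta_resolve",
    "b0_from_dims",
    "parabola_contour",
    "huegelschaeffer_contour",
    "ellipse_contour",
]

SQRT3 = np.sqrt(3.0)

#: empirical band of the breadth-offset ratio w/L for real eggs; values above
#: it are legal (super-elongated eggs) but trigger a warning.
WL_EMPIRICAL_MAX = 0.2


class DomainError(ValueError):
    """Axial coordinate outside [-L/2, L/2] or ratio outside its domain."""


class ConfigurationError(ValueError):
    """A variant was asked to resolve without its required measurements."""


class AdmissibilityWarning(UserWarning):
    """Parameters outside the empirical band for real eggs (w/L > 0.2)."""


class Variant(str, enum.Enum):
    """Members of the Smart contour family."""

    SM = "SM"
    SM_R = "SM_r"
    SM_B0 = "SM_B0"
    SM_B02 = "SM_B02"
    SM_R2 = "SM_r2"
    SM_MA = "SM_MA"
    SM_U = "SM_U"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: number of directly measured lengths each variant consumes (L, B, w plus
#: any auxiliary measurement); used for reporting parsimony alongside fit
#: accuracy.
N_PARAMS = {
    Variant.SM: 4,
    Variant.SM_R: 5,
    Variant.SM_B0: 4,
    Variant.SM_B02: 3,
    Variant.SM_R2: 3,
    Variant.SM_MA: 3,
    Variant.SM_U: 4,
}


class Orientation(str, enum.Enum):
    POINTED_NEGATIVE_X = "pointed_negative_x"
    POINTED_POSITIVE_X = "pointed_positive_x"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AxialDims:
    """The three basic egg measurements.

    Parameters
    ----------
    L : float
        Egg length (distance between the two tips), > 0.
    B : float
        Maximum breadth (full diameter at the widest section), > 0.
    w : float
        Axial offset of the maximum-breadth section from the mid-length
        point.  Non-negative in the canonical orientation (pointed end at
        x < 0): w >= 0 shifts B toward the blunt end.  Must satisfy
        w < L/2 so that sqrt(L^2 - 4 w^2) is real and nonzero.
    """

    L: float
    B: float
    w: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L) and self.L > 0):
            raise ValueError(f"L must be finite and > 0, got {self.L!r}")
        if not (np.isfinite(self.B) and self.B > 0):
            raise ValueError(f"B must be finite and > 0, got {self.B!r}")
        if not (np.isfinite(self.w) and 0 <= self.w < self.L / 2):
            raise ValueError(
                f"w must satisfy 0 <= w < L/2 = {self.L / 2}, got {self.w!r}"
            )
        if self.w / self.L > WL_EMPIRICAL_MAX:
            warnings.warn(
                f"w/L = {self.w / self.L:.3f} exceeds the empirical band "
                f"[0, {WL_EMPIRICAL_MAX}] for real eggs",
                AdmissibilityWarning,
                stacklevel=2,
            )

    @property
    def half_span(self) -> float:
        """sqrt(L^2 - 4 w^2); denominator shared by the whole family."""
        return float(np.sqrt(self.L**2 - 4 * self.w**2))


@dataclass(frozen=True)
class AuxMeasures:
    """Optional auxiliary measurements.

    B0 is the full breadth at mid-length (x = 0); r and R are the *radii*
    (half-breadths, y-values of the contour) at one quarter length from
    the pointed (x = -L/4) and blunt (x = +L/4) ends in the canonical
    orientation; tan_theta is the dimensionless slope of Smart's
    tangential line.  R < r is legal input and yields tan(theta) < 0.
    """

    B0: float | None = None
    r: float | None = None
    R: float | None = None
    tan_theta: float | None = None

    def __post_init__(self) -> None:
        for name in ("B0", "r", "R"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0 when given")
        if self.tan_theta is not None and not np.isfinite(self.tan_theta):
            raise ValueError("tan_theta must be finite when given")


def tan_theta_resolve(
    variant: Variant | str, dims: AxialDims, aux: AuxMeasures | None = None
) -> float:
    """Resolve the slope parameter tan(theta) for a family member.

    Each variant consumes a different set of measurements (see module
    docstring).  The w -> 0 limits are handled analytically: the
    mid-breadth route has w in a denominator, but at w = 0 the geometry
    forces B0 = B and the slope tends to 0; B0 != B at w = 0 is therefore
    an inconsistent configuration, not a division by zero.

    Raises
    ------
    ConfigurationError
        If a required auxiliary measurement is missing or inconsistent.
    """
    variant = Variant(variant)
    aux = aux or AuxMeasures()
    L, B, w = dims.L, dims.B, dims.w
    s = dims.half_span  # sqrt(L^2 - 4 w^2)

    if variant is Variant.SM:
        if aux.tan_theta is None:
            raise ConfigurationError("SM requires tan_theta")
        return float(aux.tan_theta)

    if variant is Variant.SM_R:
        if aux.r is None or aux.R is None:
            raise ConfigurationError("SM_r requires both r and R")
        return float(4.0 / SQRT3 * (aux.R - aux.r) / L)

    if variant is Variant.SM_B0:
        if aux.B0 is None:
            raise ConfigurationError("SM_B0 requires B0")
        if w == 0:
            if not np.isclose(aux.B0, B, rtol=1e-9, atol=0.0):
                raise ConfigurationError(
                    "at w = 0 the contour forces B0 = B; "
                    f"got B0 = {aux.B0}, B = {B}"
                )
            return 0.0
        return float((B * L - aux.B0 * s) / (2 * w * s))

    if variant is Variant.SM_B02:
        # B0 eliminated via the Hugelschaffer mid-breadth ratio
        # B0 = B L / sqrt(L^2 + 4 w^2); the w -> 0 limit is 0.
        if w == 0:
            return 0.0
        p = np.sqrt(L**2 + 4 * w**2)
        return float(B * L * (p - s) / (2 * w * s * p))

    if variant is Variant.SM_R2:
        # r and R eliminated via the Hugelschaffer quarter-diameters.
        return float(
            B
            * (
                1.0 / np.sqrt(L**2 - 2 * w * L + 4 * w**2)
                - 1.0 / np.sqrt(L**2 + 2 * w * L + 4 * w**2)
            )
        )

    if variant is Variant.SM_MA:
        return float(2 * B * L * w / (s**3))

    if variant is Variant.SM_U:
        if aux.r is None:
            raise ConfigurationError("SM_U requires r")
        return float(
            B / np.sqrt(L**2 - 2 * w * L + 4 * w**2) - 4 * aux.r / (SQRT3 * L)
        )

    raise ConfigurationError(f"unknown variant {variant!r}")  # pragma: no cover


@dataclass(frozen=True)
class ModelSpec:
    """A fully resolved contour model: variant tag + canonical coefficients.

    ``P = B / (2 sqrt(L^2 - 4 w^2))`` is the intercept coefficient shared by
    every variant (all contours pass through (w, B/2) by construction) and
    ``Q = tan(theta) / L`` is the slope coefficient.
    """

    variant: Variant
    dims: AxialDims
    aux: AuxMeasures = field(default_factory=AuxMeasures)
    tan_theta: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.tan_theta):
            object.__setattr__(
                self, "tan_theta", tan_theta_resolve(self.variant, self.dims, self.aux)
            )
        if not np.isfinite(self.tan_theta):
            raise ConfigurationError(
                f"non-finite tan_theta for variant {self.variant}"
            )

    @classmethod
    def build(
        cls,
        variant: Variant | str,
        dims: AxialDims,
        aux: AuxMeasures | None = None,
    ) -> "ModelSpec":
        return cls(Variant(variant), dims, aux or AuxMeasures())

    @property
    def P(self) -> float:
        return self.dims.B / (2.0 * self.dims.half_span)

    @property
    def Q(self) -> float:
        return self.tan_theta / self.dims.L

    def __call__(self, x):
        return canonical_contour(self, x)


def _check_domain(x: np.ndarray, L: float) -> None:
    if np.any(np.abs(x) > L / 2 * (1 + 1e-12)):
        bad = np.asarray(x)[np.abs(x) > L / 2 * (1 + 1e-12)]
        raise DomainError(
            f"x outside [-L/2, L/2] = [{-L / 2}, {L / 2}]: {bad[:3]!r}"
        )


def canonical_contour(spec: ModelSpec, x):
    """Upper half-breadth y(x) of the canonical Smart contour.

    Evaluates ``y = (P + Q (x - w)) sqrt(L^2 - 4 x^2)`` elementwise.  The
    value is signed: for extreme parameters the linear factor can go
    negative near a tip, and the signed value is returned (with no
    clamping) so diagnostics can detect non-physical parameter
    combinations; see :func:`contour_is_physical`.
    """
    x = np.asarray(x, dtype=float)
    L = spec.dims.L
    _check_domain(x, L)
    rad = np.sqrt(np.maximum(L**2 - 4.0 * x**2, 0.0))
    y = (spec.P + spec.Q * (x - spec.dims.w)) * rad
    return y if y.shape else float(y)


def contour_is_physical(spec: ModelSpec, x) -> np.ndarray | bool:
    """True where the linear factor of the canonical form is non-negative."""
    x = np.asarray(x, dtype=float)
    ok = spec.P + spec.Q * (x - spec.dims.w) >= 0.0
    return ok if ok.shape else bool(ok)


def contour_slope(spec: ModelSpec, x):
    """Analytic derivative dy/dx of the canonical contour.

    ``y' = Q sqrt(L^2-4x^2) - (P + Q (x-w)) 4x / sqrt(L^2-4x^2)``; the tips
    x = +-L/2 have a vertical tangent and return +-inf accordingly.
    """
    x = np.asarray(x, dtype=float)
    L, w = spec.dims.L, spec.dims.w
    _check_domain(x, L)
    rad = np.sqrt(np.maximum(L**2 - 4.0 * x**2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = spec.Q * rad - (spec.P + spec.Q * (x - w)) * 4.0 * x / rad
    return d if d.shape else float(d)


def b0_from_dims(dims: AxialDims, tan_theta: float) -> float:
    """Mid-length breadth B0 implied by (L, B, w) and the slope parameter.

    ``B0 = B L / sqrt(L^2 - 4 w^2) - 2 w tan(theta)``.  This is the exact
    inverse of the SM_B0 slope resolver.  A non-positive result means the
    parameter combination is non-physical (the contour dips below the axis
    at mid-length) and raises ``ValueError``.
    """
    b0 = dims.B * dims.L / dims.half_span - 2.0 * dims.w * tan_theta
    if b0 <= 0:
        raise ValueError(
            f"non-physical parameter combination: implied B0 = {b0} <= 0"
        )
    return float(b0)


def ellipse_contour(dims: AxialDims, x):
    """Half-breadth of the ellipse with axes L and B (the tan(theta)=0 egg)."""
    x = np.asarray(x, dtype=float)
    _check_domain(x, dims.L)
    y = dims.B / 2.0 * np.sqrt(np.maximum(1.0 - (2.0 * x / dims.L) ** 2, 0.0))
    return y if y.shape else float(y)


def parabola_contour(dims: AxialDims, x):
    """Parabolic pointed-end boundary contour (native orientation).

    ``y = (B/2) sqrt((L - 2x) / (L + 2w))``.  NOTE the orientation is the
    opposite of the canonical family: the pointed end sits at x = +L/2 and
    the maximum breadth at x = -w.  This contour is the lower bound of the
    pointed-end shape continuum; it is meaningful on the pointed side only.
    """
    x = np.asarray(x, dtype=float)
    L, B, w = dims.L, dims.B, dims.w
    _check_domain(x, L)
    y = B / 2.0 * np.sqrt(np.maximum(L - 2.0 * x, 0.0) / (L + 2.0 * w))
    return y if y.shape else float(y)


def huegelschaeffer_contour(dims: AxialDims, x):
    """Hugelschaffer ovoid contour (native orientation).

    ``y = (B/2) sqrt((L^2 - 4x^2) / (L^2 + 8wx + 4w^2))``.  Same flipped
    orientation as :func:`parabola_contour` (pointed end at x = +L/2).  The
    interior extremum sits exactly at x = -w with value B/2, i.e. this
    classical three-parameter ovoid satisfies the Main Axiom in its own
    orientation; it is the upper bound of the pointed-end continuum and
    models the blunt half for every egg shape.
    """
    x = np.asarray(x, dtype=float)
    L, B, w = dims.L, dims.B, dims.w
    _check_domain(x, L)
    y = B / 2.0 * np.sqrt(
        np.maximum(L**2 - 4.0 * x**2, 0.0) / (L**2 + 8.0 * w * x + 4.0 * w**2)
    )
    return y if y.shape else float(y)
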