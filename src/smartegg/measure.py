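"""Parameter measurement from digitized egg profiles.

A digitized profile is an ordered run of (x, half-breadth) samples along
the long axis, typically produced by pixel-wise measurement of an egg
photograph.  From it the Smart-family parameter set is extracted:

* L  — tip-to-tip length (the x span);
* B  — maximum breadth, with the maximizing abscissa found to sub-pixel
  accuracy (see below);
* w  — offset of the maximum-breadth section from mid-length;
* B0 — full breadth interpolated at mid-length;
* r, R — half-breadths (radii) interpolated a quarter length from the
  pointed and blunt ends.

Sub-pixel (B, w) refinement exploits the structure shared by the whole
contour family: y / sqrt(L^2 - 4 x^2) is exactly linear in x for every
Smart variant and very nearly linear for any smooth egg-like outline, so
a linear fit of that transform followed by a closed-form extremum solve
recovers the breadth section far below the pixel quantization floor,
where a local quadratic fit through quantized samples is degenerate (the
contour is flat to within one pixel over tens of pixels around its
maximum).  A windowed quadratic fit and the raw discrete maximum remain
available as fallbacks for data that defeat the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AuxMeasures, AxialDims, Orientation

__all__ = [
    "DigitizedProfile",
    "MeasuredParams",
    "InsufficientDataError",
    "DegenerateProfileError",
    "measure_profile",
    "refit_tan_theta",
    "fold_closed_outline",
]

MIN_POINTS = 7


class InsufficientDataError(ValueError):
    """Too few points to place the six measurements meaningfully."""


class DegenerateProfileError(ValueError):
    """Profile shape defeats measurement (e.g. maximum at an endpoint)."""


@dataclass(frozen=True)
class DigitizedProfile:
    """Ordered (x, y) samples of an egg half-outline.

    x must be strictly increasing and y (the half-breadth) non-negative;
    the two endpoints are the tips and must carry the smallest breadths.
    ``scale`` is mm per px when the units are px and a physical scale is
    known.
    """

    x: np.ndarray
    y: np.ndarray
    units: str = "px"
    scale: float | None = None
    orientation: Orientation = Orientation.POINTED_NEGATIVE_X

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < MIN_POINTS:
            raise InsufficientDataError(
                f"need at least {MIN_POINTS} points, got {len(x)}"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("profile contains non-finite values")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("half-breadth y must be non-negative")
        interior_min = y[1:-1].min()
        if y[0] > interior_min or y[-1] > interior_min:
            raise ValueError("endpoints must carry the smallest breadths (tips)")

    @property
    def n_points(self) -> int:
        return len(self.x)

    def to_canonical(self) -> "DigitizedProfile":
        """Flip to the pointed-end-at-negative-x convention if needed."""
        if self.orientation is Orientation.POINTED_NEGATIVE_X:
            return self
        return replace(
            self,
            x=-self.x[::-1],
            y=self.y[::-1].copy(),
            orientation=Orientation.POINTED_NEGATIVE_X,
        )

    def centered(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Canonical-orientation (x - midpoint, y, L)."""
        p = self.to_canonical()
        mid = 0.5 * (p.x[0] + p.x[-1])
        return p.x - mid, p.y, float(p.x[-1] - p.x[0])


@dataclass(frozen=True)
class MeasuredParams:
    """Extracted Smart-family parameters plus interpolation provenance."""

    dims: AxialDims
    aux: AuxMeasures
    units: str = "px"
    provenance: tuple[str, ...] = field(default_factory=tuple)


def fold_closed_outline(
    x: np.ndarray, y: np.ndarray, **profile_kwargs
) -> DigitizedProfile:
    """Fold a closed outline (both branches, signed y) to a half-profile.

    The upper (y >= 0) and lower (y < 0) branches are matched on the upper
    branch's x grid and |y| is averaged, which symmetrizes digitization
    noise the way comparison against axially symmetric models expects.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    upper = y >= 0
    lower = ~upper
    if not lower.any():
        order = np.argsort(x)
        return DigitizedProfile(x[order], y[order], **profile_kwargs)
    xu, yu = x[upper], np.abs(y[upper])
    xl, yl = x[lower], np.abs(y[lower])
    iu, il = np.argsort(xu), np.argsort(xl)
    xu, yu = xu[iu], yu[iu]
    xl, yl = xl[il], yl[il]
    y_low = np.interp(xu, xl, yl)
    # average only where the lower branch actually covers x; beyond its
    # span (the tips often carry exact zeros on one branch only) keep the
    # upper-branch value rather than extrapolating
    covered = (xu >= xl[0]) & (xu <= xl[-1])
    folded = np.where(covered, 0.5 * (yu + y_low), yu)
    keep = np.ones_like(xu, dtype=bool)
    keep[1:] = np.diff(xu) > 0  # collapse duplicate x from branch overlap
    return DigitizedProfile(xu[keep], folded[keep], **profile_kwargs)


def _structural_vertex(xc, y, L):
    """(x*, y*) of the contour maximum via the linear-transform fit.

    Fits z = y / sqrt(L^2 - 4 x^2) = a + b x over interior points and
    solves the closed-form extremum 8 b x^2 + 4 a x - b L^2 = 0 in its
    cancellation-free form x* = b L^2 / (2 (a + sqrt(a^2 + 2 b^2 L^2))).
    """
    rad = np.sqrt(np.maximum(L**2 - 4.0 * xc**2, 0.0))
    ok = rad > 0.0
    if ok.sum() < 3:
        raise DegenerateProfileError("too few interior points for refinement")
    # least squares on y = (a + b x) rad directly: pixel quantization is
    # homoscedastic in y, so fitting the transform z = y/rad unweighted would
    # let the near-tip samples dominate
    A = np.column_stack([rad[ok], xc[ok] * rad[ok]])
    (a, b), *_ = np.linalg.lstsq(A, y[ok], rcond=None)
    disc = a + np.sqrt(a**2 + 2.0 * b**2 * L**2)
    if not (np.isfinite(disc) and disc > 0):
        raise DegenerateProfileError("degenerate transform fit")
    x_star = b * L**2 / (2.0 * disc)
    if not (-L / 2 < x_star < L / 2):
        raise DegenerateProfileError("refined maximum outside the profile span")
    y_star = (a + b * x_star) * np.sqrt(L**2 - 4.0 * x_star**2)
    return float(x_star), float(y_star)


def _quadratic_vertex(xc, y, L, i_max, halfwidth_frac=0.08):
    """(x*, y*) from a quadratic fit in a window around the discrete max."""
    h = halfwidth_frac * L
    win = np.abs(xc - xc[i_max]) <= h
    if win.sum() < 3:
        win = slice(max(i_max - 1, 0), i_max + 2)
    c2, c1, c0 = np.polyfit(xc[win], y[win], 2)
    if c2 >= 0:
        return float(xc[i_max]), float(y[i_max])
    x_star = -c1 / (2.0 * c2)
    return float(x_star), float(c0 + c1 * x_star + c2 * x_star**2)


def measure_profile(
    profile: DigitizedProfile, refinement: str = "structural"
) -> MeasuredParams:
    """Extract (L, B, w) and the auxiliary breadths (B0, r, R).

    The profile is first normalized to the pointed-end-at-negative-x
    convention and centered on the midpoint of its tips.  ``refinement``
    selects the sub-pixel policy for the maximum-breadth section:
    ``"structural"`` (default, see module docstring), ``"quadratic"``
    (windowed quadratic fit) or ``"discrete"`` (raw sample maximum).

    Raises
    ------
    DegenerateProfileError
        If the breadth maximum sits at an endpoint (no interior maximum).
    """
    xc, y, L = profile.centered()
    notes: list[str] = []

    i_max = int(np.argmax(y))
    if i_max in (0, len(y) - 1):
        raise DegenerateProfileError("breadth maximum at an endpoint")

    if refinement == "structural":
        try:
            x_star, y_star = _structural_vertex(xc, y, L)
            notes.append("B,w: linear-transform refinement")
        except DegenerateProfileError:
            x_star, y_star = _quadratic_vertex(xc, y, L, i_max)
            notes.append("B,w: quadratic fallback (transform degenerate)")
    elif refinement == "quadratic":
        x_star, y_star = _quadratic_vertex(xc, y, L, i_max)
        notes.append("B,w: windowed quadratic refinement")
    elif refinement == "discrete":
        x_star, y_star = float(xc[i_max]), float(y[i_max])
        notes.append("B,w: discrete maximum")
    else:
        raise ValueError(f"unknown refinement {refinement!r}")

    flipped = False
    if x_star < 0:
        # w >= 0 by convention: the maximum fell on the pointed side, so the
        # declared orientation was reversed; fold the measurement instead of
        # failing (tiny negatives from noise land here too and become w ~ 0).
        flipped = True
        notes.append("w < 0 measured: orientation folded (r and R swapped)")

    w = abs(x_star)
    if w >= L / 2:
        raise DegenerateProfileError("refined |w| >= L/2")
    B = 2.0 * y_star

    def interp(at: float) -> float:
        return float(np.interp(at, xc, y))

    B0 = 2.0 * interp(0.0)  # B0 is a full breadth; r, R are half-breadths
    r = interp(-L / 4.0)
    R = interp(L / 4.0)
    if flipped:
        r, R = R, r
    notes.append("B0,r,R: piecewise-linear interpolation")

    return MeasuredParams(
        dims=AxialDims(L=L, B=B, w=w),
        aux=AuxMeasures(B0=B0, r=r, R=R),
        units=profile.units,
        provenance=tuple(notes),
    )


def refit_tan_theta(profile: DigitizedProfile, dims: AxialDims) -> float:
    """Least-squares slope parameter given the measured (L, B, w).

    With P = B / (2 sqrt(L^2 - 4 w^2)) held fixed, minimizes the summed
    squared residuals of y / sqrt(L^2 - 4 x^2) against P + Q (x - w) over
    interior points; returns tan(theta) = Q L.  A one-parameter linear
    problem, so the solution is closed-form.
    """
    xc, y, L = profile.centered()
    rad = np.sqrt(np.maximum(L**2 - 4.0 * xc**2, 0.0))
    ok = rad > 0.05 * L
    u = xc[ok] - dims.w
    denom = float(np.sum(u**2))
    if not ok.any() or denom == 0.0:
        raise DegenerateProfileError("no usable interior points for the slope fit")
    P = dims.B / (2.0 * dims.half_span)
    z = y[ok] / rad[ok]
    Q = float(np.sum(u * (z - P)) / denom)
    return Q * dims.L
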