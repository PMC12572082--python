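"""Closed-form volumes of Smart-model solids of revolution.

Rotating the contour about the long axis and integrating pi y^2 dx over
each half gives closed forms in the original (L, B0, tan theta)
parameterization — the frame in which the contour reads
y = (B0 + 2 x tan(theta)) sqrt(L^2 - 4 x^2) / (2 L):

    V_p = (pi L / 4) (B0^2/3 - B0 L tan(theta)/4 + L^2 tan^2(theta)/15)
    V_b = (pi L / 4) (B0^2/3 + B0 L tan(theta)/4 + L^2 tan^2(theta)/15)
    V   = (pi L / 6) (B0^2 + L^2 tan^2(theta)/5)

(pointed half x < 0, blunt half x > 0).  Comparing V with the volume of
the ellipsoid of the same length shows the two agree only for
tan(theta) = 0: an ovoid holds *more* volume than the ellipsoid of equal
length and mid-breadth, by exactly pi L^3 tan^2(theta) / 30.  The
ellipsoid of equal volume is longer:

    L_el = L [1 + (1/5) (L/B0)^2 tan^2(theta)]

Callers holding the measured frame (L, B, w, tan theta) convert to B0
first via :func:`smartegg.geometry.b0_from_dims`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AxialDims, ModelSpec, b0_from_dims

__all__ = [
    "VolumeReport",
    "volume_parts",
    "ellipsoid_volume",
    "ellipsoid_equiv_length",
    "conservation_check",
    "volume_report",
    "volume_report_from_spec",
]


@dataclass(frozen=True)
class VolumeReport:
    """Volumes of the two egg halves, their total, and ellipsoid equivalents.

    Units: length^3 for volumes, length for L_el.  ``V = V_p + V_b``
    algebraically; ``V_el`` is the volume of the ellipsoid with length
    ``L_el`` and breadth B0, which equals V by construction of L_el.
    """

    V_p: float
    V_b: float
    V: float
    V_el: float
    L_el: float


def _check_pos(**kw: float) -> None:
    for k, v in kw.items():
        if not (np.isfinite(v) and v > 0):
            raise ValueError(f"{k} must be finite and > 0, got {v!r}")


def volume_parts(L: float, B0: float, tan_theta: float) -> tuple[float, float, float]:
    """Closed-form (V_p, V_b, V) of the Smart solid of revolution."""
    _check_pos(L=L, B0=B0)
    t = tan_theta
    common = B0**2 / 3.0 + L**2 * t**2 / 15.0
    cross = B0 * L * t / 4.0
    V_p = np.pi * L / 4.0 * (common - cross)
    V_b = np.pi * L / 4.0 * (common + cross)
    V = np.pi * L / 6.0 * (B0**2 + L**2 * t**2 / 5.0)
    return float(V_p), float(V_b), float(V)


def ellipsoid_volume(L_el: float, B0: float) -> float:
    """Volume of a prolate spheroid of length L_el and breadth B0."""
    _check_pos(L_el=L_el, B0=B0)
    return float(np.pi * L_el * B0**2 / 6.0)


def ellipsoid_equiv_length(L: float, B0: float, tan_theta: float) -> float:
    """Length of the ellipsoid holding the same volume as the Smart ovoid.

    L_el = L [1 + (1/5)(L/B0)^2 tan^2(theta)] >= L, with equality iff
    tan(theta) = 0.  The excess is the length the oviduct would have to
    squeeze away for Smart's constant-length postulate to conserve volume.
    """
    _check_pos(L=L, B0=B0)
    return float(L * (1.0 + (L / B0) ** 2 * tan_theta**2 / 5.0))


def conservation_check(
    L: float, B0: float, tan_theta: float, rtol: float = 1e-12
) -> tuple[bool, float]:
    """Does the ovoid volume match the equal-length ellipsoid volume?

    Returns ``(conserved, discrepancy)`` with discrepancy
    V - V_el(length L) = pi L^3 tan^2(theta) / 30 >= 0.  Conservation holds
    iff tan(theta) = 0 (the egg is the ellipsoid itself).  The discrepancy
    is evaluated from its algebraic form, which subtracts the two closed
    forms exactly (no floating cancellation at tan(theta) = 0).
    """
    _, _, V = volume_parts(L, B0, tan_theta)
    disc = np.pi * L**3 * tan_theta**2 / 30.0
    return bool(abs(disc) <= rtol * V), float(disc)


def volume_report(L: float, B0: float, tan_theta: float) -> VolumeReport:
    """Full volume report in the (L, B0, tan theta) frame."""
    V_p, V_b, V = volume_parts(L, B0, tan_theta)
    L_el = ellipsoid_equiv_length(L, B0, tan_theta)
    return VolumeReport(V_p=V_p, V_b=V_b, V=V, V_el=ellipsoid_volume(L_el, B0), L_el=L_el)


def volume_report_from_spec(spec: ModelSpec) -> VolumeReport:
    """Volume report for a resolved contour in the measured (L, B, w) frame."""
    dims: AxialDims = spec.dims
    B0 = b0_from_dims(dims, spec.tan_theta)
    return volume_report(dims.L, B0, spec.tan_theta)
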