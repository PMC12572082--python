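"""Independent oracles: the per-variant closed forms transcribed directly
from their printed equations, plus a quadrature volume oracle.

These are deliberately written term-by-term from the printed formulas (not
via the canonical P/Q machinery) so that equivalence tests compare two
independent code paths.
"""

import numpy as np
from scipy.integrate import quad

S3 = np.sqrt(3.0)


def printed_sm(L, B, w, tan_theta, x):
    x = np.asarray(x, dtype=float)
    s = np.sqrt(L**2 - 4 * w**2)
    return (B / (2 * s) + tan_theta * (x - w) / L) * np.sqrt(L**2 - 4 * x**2)


def printed_sm_r(L, B, w, r, R, x):
    x = np.asarray(x, dtype=float)
    s = np.sqrt(L**2 - 4 * w**2)
    return (B / (2 * s) + 4 * (R - r) / (S3 * L**2) * (x - w)) * np.sqrt(L**2 - 4 * x**2)


def printed_sm_b0(L, B, w, B0, x):
    x = np.asarray(x, dtype=float)
    s = np.sqrt(L**2 - 4 * w**2)
    return (1 / L) * ((B * L - B0 * s) / (2 * w * s) * x + B0 / 2) * np.sqrt(L**2 - 4 * x**2)


def printed_sm_b02(L, B, w, x):
    x = np.asarray(x, dtype=float)
    s = np.sqrt(L**2 - 4 * w**2)
    p = np.sqrt(L**2 + 4 * w**2)
    return B / (2 * p) * ((p - s) / (w * s) * x + 1) * np.sqrt(L**2 - 4 * x**2)


def printed_sm_r2(L, B, w, x):
    x = np.asarray(x, dtype=float)
    s = np.sqrt(L**2 - 4 * w**2)
    bracket = 1 / np.sqrt(L**2 - 2 * w * L + 4 * w**2) - 1 / np.sqrt(L**2 + 2 * w * L + 4 * w**2)
    return B * (1 / (2 * s) + bracket * (x - w) / L) * np.sqrt(L**2 - 4 * x**2)


def printed_sm_ma(L, B, w, x):
    x = np.asarray(x, dtype=float)
    q = L**2 - 4 * w**2
    return B / 2 * (1 + 4 * w / q * (x - w)) * np.sqrt((L**2 - 4 * x**2) / q)


def printed_sm_u(L, B, w, r, x):
    x = np.asarray(x, dtype=float)
    s = np.sqrt(L**2 - 4 * w**2)
    bracket = 1 / np.sqrt(L**2 - 2 * w * L + 4 * w**2) - 4 * r / (S3 * B * L)
    return B * (1 / (2 * s) + bracket * (x - w) / L) * np.sqrt(L**2 - 4 * x**2)


def quad_volume_halves(L, B0, tan_theta):
    """(V_p, V_b) by adaptive quadrature of pi * y^2 in the original frame."""

    def integrand(x):
        y = (B0 + 2 * x * tan_theta) / (2 * L) * np.sqrt(L**2 - 4 * x**2)
        return np.pi * y**2

    vp, _ = quad(integrand, -L / 2, 0.0, epsabs=1e-12, epsrel=1e-12)
    vb, _ = quad(integrand, 0.0, L / 2, epsabs=1e-12, epsrel=1e-12)
    return vp, vb
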