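"""Deterministic low-dimensional multivariate normal probabilities.

The design engine repeatedly needs P(X1 <= b1, X2 <= b2, X3 <= b3) for a
trivariate normal with unit variances, both inside root finders (critical
values, boundary calibration) and across allocation grids.  scipy's generic
``multivariate_normal.cdf`` is quasi-Monte-Carlo based; here we instead use

* the bivariate CDF expressed exactly through Owen's T function, and
* the trivariate CDF reduced, by conditioning on the first coordinate, to a
  one-dimensional integral of a bivariate CDF, evaluated with fixed
  Gauss-Legendre quadrature.

Both routines are fully deterministic and accurate well below 1e-6 in
absolute terms, so solved critical values are reproducible to the third
decimal place bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf", "tvn_cdf", "norm_cdf"]

#: integration cut-off in standard deviations; the neglected mass is < 1e-17
_TAIL = 8.5

norm_cdf = ndtr


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    ``h`` and ``k`` may be arrays (broadcast together); ``rho`` is scalar.
    Uses Owen (1956): Phi2(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k)
    - delta, with the usual special-casing of zero arguments and |rho| -> 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    if abs(rho) >= 1.0 - 1e-12:
        if rho > 0:
            return ndtr(np.minimum(h, k))
        return np.clip(ndtr(h) + ndtr(k) - 1.0, 0.0, 1.0)

    s = np.sqrt(1.0 - rho * rho)
    # nudge exact zeros; the formula is continuous and the perturbation is
    # far below the quadrature tolerance of any caller
    hs = np.where(h == 0.0, 1e-13, h)
    ks = np.where(k == 0.0, 1e-13, k)
    ah = (k - rho * hs) / (s * hs)
    ak = (h - rho * ks) / (s * ks)
    delta = np.where(hs * ks < 0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(hs, ah) - owens_t(ks, ak) - delta
    both_zero = (h == 0.0) & (k == 0.0)
    if np.any(both_zero):
        out = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), out)
    return np.clip(out, 0.0, 1.0)


def _gl_nodes(n: int, lo: float, hi: float):
    x, w = leggauss(n)
    half = 0.5 * (hi - lo)
    return lo + half * (x + 1.0), half * w


def tvn_cdf(upper, corr, nodes: int = 96) -> float:
    """Trivariate normal CDF P(X <= upper) for a correlation matrix ``corr``.

    Conditions on X1: given X1 = t, (X2, X3) is bivariate normal with means
    r12*t, r13*t, reduced variances and partial correlation r23|1; the outer
    integral over the standard normal density of X1 is done with ``nodes``
    Gauss-Legendre points on [-8.5, b1].

    Raises ``np.linalg.LinAlgError`` (with context) if ``corr`` is not a
    valid positive definite correlation matrix.
    """
    b = np.asarray(upper, dtype=float)
    R = np.asarray(corr, dtype=float)
    if b.shape != (3,) or R.shape != (3, 3):
        raise ValueError("tvn_cdf expects a 3-vector of limits and a 3x3 matrix")
    if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0):
        raise ValueError("corr must be symmetric with unit diagonal")
    if np.linalg.eigvalsh(R)[0] < -1e-8:
        raise np.linalg.LinAlgError(
            f"correlation matrix is not positive semidefinite: {R!r}"
        )
    if max(abs(R[0, 1]), abs(R[0, 2])) >= 1.0 - 1e-12:
        raise np.linalg.LinAlgError(
            "a correlation with the first coordinate is +-1; the law is "
            "degenerate in a direction the conditional reduction cannot handle"
        )

    b1, b2, b3 = b
    if b1 <= -_TAIL:
        return 0.0
    b1 = min(b1, _TAIL)
    r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
    s12 = np.sqrt(1.0 - r12 * r12)
    s13 = np.sqrt(1.0 - r13 * r13)
    rc = np.clip((r23 - r12 * r13) / (s12 * s13), -1.0, 1.0)

    # a singular law (e.g. the balanced factorial design, where ZAB is a
    # linear combination of ZA and ZB) makes the conditional correlation
    # +-1 and the inner CDF piecewise linear in t; split at the kink so the
    # Gauss-Legendre rule only ever sees smooth pieces
    segments = [(-_TAIL, b1)]
    if abs(rc) >= 1.0 - 1e-9 and abs(r13 * s12 - r12 * s13) > 1e-12:
        t_kink = (b3 * s12 - b2 * s13) / (r13 * s12 - r12 * s13)
        if -_TAIL < t_kink < b1:
            segments = [(-_TAIL, t_kink), (t_kink, b1)]

    total = 0.0
    for lo, hi in segments:
        t, w = _gl_nodes(nodes, lo, hi)
        inner = bvn_cdf((b2 - r12 * t) / s12, (b3 - r13 * t) / s13, rc)
        dens = np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)
        total += float(np.sum(w * inner * dens))
    return float(np.clip(total, 0.0, 1.0))
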