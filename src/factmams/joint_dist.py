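"""Joint distributions of the treatment-versus-control test statistics.

A trial evaluates two treatments A and B and their combination AB against a
shared control, testing the one-sided family H0A: muA <= mu0, H0B: muB <= mu0,
H0AB: muAB <= mu0 with a common critical value k chosen so that the
familywise error rate (the probability of rejecting any true null) equals
alpha.  Under normality with known sigma the three z-statistics are jointly
trivariate normal; this module builds their correlation matrix and mean
vector for

* the 2x2 factorial design, where the statistics for A and B pool the
  single-arm contrast with the combination-minus-other-arm contrast under
  the additivity assumption, and
* the multi-arm (Dunnett) design, where each arm is compared to control on
  its own data only,

and solves for critical values / rejection probabilities.

Allocation is parametrised by r = nA/n0 = nB/n0 and q = nAB/n0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from ._mvn import norm_cdf, tvn_cdf

__all__ = [
    "AllocationRatios",
    "EffectScenario",
    "JointLaw",
    "DesignCriteria",
    "factorial_covariance",
    "factorial_mean",
    "ma_covariance",
    "ma_mean",
    "rejection_prob",
    "critical_value",
]

#: mean configurations (muA-mu0, muB-mu0, muAB-mu0) in units of (delta, delta0)
_PRESETS = {
    "0": (lambda d, d0: (0.0, 0.0, 0.0)),
    "i": (lambda d, d0: (d, d0, d0)),
    "ii": (lambda d, d0: (d0, d0, d)),
    "iii": (lambda d, d0: (d, d0, d + d0)),
    "iv": (lambda d, d0: (d0, d0, 2.0 * d0)),
}


def _positive_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a positive finite number, got {value}")
    return value


@dataclass(frozen=True)
class AllocationRatios:
    """Group sizes relative to control: nA = nB = r*n0, nAB = q*n0."""

    r: float
    q: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", _positive_finite("r", self.r))
        object.__setattr__(self, "q", _positive_finite("q", self.q))

    def group_sizes(self, n0: float) -> tuple[float, float, float, float]:
        """(n0, nA, nB, nAB) implied by a control-group size n0."""
        return (n0, self.r * n0, self.r * n0, self.q * n0)


@dataclass(frozen=True)
class EffectScenario:
    """The four group means and common standard deviation of the responses.

    ``delta`` (interesting effect) and ``delta0`` (positive but uninteresting
    effect) are carried along when the scenario was built from a named
    preset, purely for reporting.
    """

    mu0: float
    muA: float
    muB: float
    muAB: float
    sigma: float
    delta: Optional[float] = None
    delta0: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", _positive_finite("sigma", self.sigma))
        for name in ("mu0", "muA", "muB", "muAB"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)

    @classmethod
    def from_preset(
        cls,
        preset: str | int,
        delta: float,
        delta0: float,
        sigma: float,
        mu0: float = 0.0,
    ) -> "EffectScenario":
        """Named alternatives (0), (i)-(iv).

        (0) global null; (i) muA-mu0 = delta, others delta0 (antagonistic
        least favourable configuration); (ii) combination has delta, singles
        delta0 (synergistic LFC); (iii) additive: delta, delta0, delta+delta0;
        (iv) both singles weak: delta0, delta0, 2*delta0.
        """
        key = str(preset).lower()
        if key not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        eA, eB, eAB = _PRESETS[key](float(delta), float(delta0))
        return cls(mu0, mu0 + eA, mu0 + eB, mu0 + eAB, sigma,
                   delta=float(delta), delta0=float(delta0))

    @classmethod
    def from_coefficients(
        cls, beta0: float, beta1: float, beta2: float, beta3: float, sigma: float
    ) -> "EffectScenario":
        """Cell means of the full linear model with interaction beta3."""
        return cls(beta0, beta0 + beta1, beta0 + beta2,
                   beta0 + beta1 + beta2 + beta3, sigma)

    @property
    def effects(self) -> tuple[float, float, float]:
        """(muA-mu0, muB-mu0, muAB-mu0)."""
        return (self.muA - self.mu0, self.muB - self.mu0, self.muAB - self.mu0)

    @property
    def is_null(self) -> bool:
        return all(e == 0.0 for e in self.effects)


@dataclass(frozen=True)
class JointLaw:
    """Mean vector and correlation matrix of (ZA, ZB, ZAB)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (3,) or cov.shape != (3, 3):
            raise ValueError("JointLaw needs a 3-vector mean and 3x3 cov")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if not np.allclose(np.diag(cov), 1.0, atol=1e-10):
            raise ValueError("statistics are standardised: unit diagonal required")
        if not np.isclose(cov[0, 2], cov[1, 2], atol=1e-10):
            raise ValueError("cov[A,AB] and cov[B,AB] must coincide by symmetry")
        # positive semidefinite: the balanced factorial law is singular
        # (ZA + ZB = sqrt(2) ZAB exactly), so full rank cannot be required
        if np.linalg.eigvalsh(cov)[0] < -1e-8:
            raise np.linalg.LinAlgError(
                f"covariance is not positive semidefinite: {cov!r}"
            )
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)


@dataclass
class DesignCriteria:
    """Error-rate requirements of a design, plus the solved critical value."""

    alpha: float
    power_target: float
    k: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError(f"power_target must lie in (0, 1), got {self.power_target}")


def _weights(alloc: AllocationRatios, n0: float) -> tuple[float, float]:
    # information weights of the two independent estimates of a single
    # treatment effect: the own-arm contrast and the combination contrast
    r, q = alloc.r, alloc.q
    return n0 * r / (1.0 + r), n0 * r * q / (r + q)


def factorial_covariance(alloc: AllocationRatios) -> np.ndarray:
    """Correlation matrix V of the factorial statistics (ZA, ZB, ZAB).

    corr(ZA, ZB) = [r(r+q)^2 + qr(1+r)^2 - 2q(1+r)(r+q)]
                   / [(1+r)(r+q)(r+2q+rq)]
    corr(ZA, ZAB) = corr(ZB, ZAB)
                  = (1+2r+q) * sqrt(rq / [(1+r)(1+q)(r+q)(r+2q+rq)])

    The off-diagonal between ZA and ZB vanishes exactly when q = r^2.
    """
    r, q = alloc.r, alloc.q
    denom = (1.0 + r) * (r + q) * (r + 2.0 * q + r * q)
    v_ab = (r * (r + q) ** 2 + q * r * (1.0 + r) ** 2
            - 2.0 * q * (1.0 + r) * (r + q)) / denom
    v_jab = (1.0 + 2.0 * r + q) * np.sqrt(r * q / ((1.0 + q) * denom))
    return np.array([
        [1.0, v_ab, v_jab],
        [v_ab, 1.0, v_jab],
        [v_jab, v_jab, 1.0],
    ])


def factorial_mean(alloc: AllocationRatios, n0: float, scen: EffectScenario) -> np.ndarray:
    """Mean of (ZA, ZB, ZAB) under the alternative, for control size n0."""
    n0 = _positive_finite("n0", n0)
    w1, w2 = _weights(alloc, n0)
    s = scen.sigma * np.sqrt(w1 + w2)
    e_a = (w1 * (scen.muA - scen.mu0) + w2 * (scen.muAB - scen.muB)) / s
    e_b = (w1 * (scen.muB - scen.mu0) + w2 * (scen.muAB - scen.muA)) / s
    e_ab = np.sqrt(n0 * alloc.q / (1.0 + alloc.q)) * (scen.muAB - scen.mu0) / scen.sigma
    return np.array([e_a, e_b, e_ab])


def ma_covariance(alloc: AllocationRatios) -> np.ndarray:
    """Correlation matrix W of the multi-arm (Dunnett) statistics.

    All three arms share only the control data, giving r/(1+r) between the
    single-arm statistics and sqrt(rq/((1+r)(1+q))) to the combination arm.
    """
    r, q = alloc.r, alloc.q
    w_ab = r / (1.0 + r)
    w_jab = np.sqrt(r * q / ((1.0 + r) * (1.0 + q)))
    return np.array([
        [1.0, w_ab, w_jab],
        [w_ab, 1.0, w_jab],
        [w_jab, w_jab, 1.0],
    ])


def ma_mean(alloc: AllocationRatios, n0: float, scen: EffectScenario) -> np.ndarray:
    """Mean of the multi-arm statistics: sqrt(n0*nj/(n0+nj)) (muj-mu0)/sigma."""
    n0 = _positive_finite("n0", n0)
    r, q = alloc.r, alloc.q
    eff = scen.effects
    info = np.array([n0 * r / (1.0 + r), n0 * r / (1.0 + r), n0 * q / (1.0 + q)])
    return np.sqrt(info) * np.asarray(eff) / scen.sigma


def rejection_prob(law: JointLaw, k: float) -> float:
    """P(reject at least one hypothesis) = 1 - P(all statistics <= k)."""
    upper = float(k) - law.mean
    return 1.0 - tvn_cdf(upper, law.cov)


def critical_value(cov: np.ndarray, alpha: float) -> float:
    """Common critical value k with familywise error rate alpha.

    Solves P(ZA <= k, ZB <= k, ZAB <= k) = 1 - alpha under the zero-mean
    trivariate normal law.  k is bracketed between the single-test bound
    Phi^-1(1-alpha) and the Bonferroni bound Phi^-1(1-alpha/3).
    """
    if not 0.0 < float(alpha) < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    law = JointLaw(np.zeros(3), np.asarray(cov, dtype=float))
    lo = ndtri(1.0 - alpha) - 0.01
    hi = ndtri(1.0 - alpha / 3.0) + 0.01
    return float(brentq(
        lambda k: tvn_cdf(np.full(3, k), law.cov) - (1.0 - alpha),
        lo, hi, xtol=1e-8,
    ))
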