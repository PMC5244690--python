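"""Two-stage multi-arm multi-stage (MAMS) design with three active arms.

The design runs the Dunnett comparison group-sequentially in two equally
sized stages with equal allocation (r = q = 1): at the interim, any
statistic above the efficacy bound u1 stops the trial with rejection; arms
below the futility bound l1 are dropped; surviving arms are retested on
cumulative data against u2 at the end.  The efficacy bounds follow the
O'Brien-Fleming shape u1 = u2*sqrt(2), with the futility bound fixed at
l1 = 0 and l2 = u2.

Both operating characteristics have exact low-dimensional integral
representations obtained by conditioning on the control arm's standardised
stage increments (and, for power, additionally on the effective arm's own
path):

* familywise error rate:  1 - E[g0(t1, t2)^3]  over independent standard
  normal (t1, t2), where g0 is the per-arm probability of never rejecting;
* power under the least favourable configuration (muAB = Delta,
  muA = muB = delta0): the probability that H0AB is rejected with the
  combination arm carrying the maximal statistic at the deciding stage,
  which is the event the printed design software calibrates.

The between-stage correlation of a cumulative statistic is 1/sqrt(2)
(equal information increments).  Integrals use Gauss-Hermite quadrature,
making every number deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri, roots_hermitenorm

from ._mvn import bvn_cdf
from .joint_dist import EffectScenario, _positive_finite

__all__ = [
    "StageBoundaries",
    "MamsDesign",
    "obf_boundaries",
    "type_one_error",
    "lfc_power",
    "mams_power",
    "mams_sample_size",
    "expected_sample_size",
]

_SQRT2 = np.sqrt(2.0)
_RHO = 1.0 / _SQRT2  # correlation between stage-1 and cumulative statistics
_N_ACTIVE = 3


@dataclass(frozen=True)
class StageBoundaries:
    """Efficacy (u1, u2) and futility (l1, l2) bounds of the two stages."""

    u1: float
    u2: float
    l1: float
    l2: float

    def __post_init__(self) -> None:
        if self.l1 > self.u1:
            raise ValueError("stage-1 futility bound must not exceed the efficacy bound")
        if not np.isclose(self.l2, self.u2, atol=1e-9):
            raise ValueError("final-stage bounds must coincide (l2 = u2)")


@dataclass(frozen=True)
class MamsDesign:
    """A fully specified two-stage design (3 active arms + control, r = q = 1).

    ``n_per_stage`` is the number of patients per arm per stage; the interim
    sits at half the maximum sample size of 8 * n_per_stage.
    """

    boundaries: StageBoundaries
    n_per_stage: int
    alpha: float
    power_target: float
    delta: float
    delta0: float
    sigma: float

    def __post_init__(self) -> None:
        if int(self.n_per_stage) != self.n_per_stage or self.n_per_stage < 1:
            raise ValueError("n_per_stage must be a positive integer")
        _positive_finite("sigma", self.sigma)

    @property
    def n_cumulative(self) -> int:
        """Per-arm sample size if the trial runs to the final analysis."""
        return 2 * int(self.n_per_stage)

    @property
    def max_sample_size(self) -> int:
        """Total patients if no arm is dropped and the trial never stops early."""
        return (_N_ACTIVE + 1) * self.n_cumulative


@lru_cache(maxsize=8)
def _gh(n: int = 80) -> tuple[np.ndarray, np.ndarray]:
    x, w = roots_hermitenorm(n)
    return x, w / np.sqrt(2.0 * np.pi)


def type_one_error(bounds: StageBoundaries, nodes: int = 80) -> float:
    """Familywise error rate of the design under the global null.

    Conditioning on the control arm's standardised stage increments
    (t1, t2), the three active arms are independent and each avoids
    rejection with probability

        g0 = Phi(sqrt(2) l1 + t1)
             + Phi2(sqrt(2) u1 + t1, sqrt(2) u2 + (t1+t2)/sqrt(2); 1/sqrt(2))
             - Phi2(sqrt(2) l1 + t1, sqrt(2) u2 + (t1+t2)/sqrt(2); 1/sqrt(2)).
    """
    t, w = _gh(nodes)
    t1, t2 = np.meshgrid(t, t, indexing="ij")
    b2 = _SQRT2 * bounds.u2 + (t1 + t2) / _SQRT2
    g0 = (
        ndtr(_SQRT2 * bounds.l1 + t1)
        + bvn_cdf(_SQRT2 * bounds.u1 + t1, b2, _RHO)
        - bvn_cdf(_SQRT2 * bounds.l1 + t1, b2, _RHO)
    )
    return float(1.0 - np.sum(w[:, None] * w[None, :] * g0**_N_ACTIVE))


def obf_boundaries(alpha: float, nodes: int = 80) -> StageBoundaries:
    """Solve the FWER equation for the O'Brien-Fleming constant.

    With u1 = u2*sqrt(2), l1 = 0 and l2 = u2, finds u2 such that the
    familywise error rate equals alpha to within 1e-4 (the root itself is
    resolved far tighter).
    """
    if not 0.0 < float(alpha) < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    def fwer_of(u2: float) -> float:
        return type_one_error(StageBoundaries(u2 * _SQRT2, u2, 0.0, u2), nodes)

    lo, hi = ndtri(1.0 - alpha) - 0.5, ndtri(1.0 - alpha / _N_ACTIVE) + 2.0
    try:
        u2 = brentq(lambda u: fwer_of(u) - alpha, lo, hi, xtol=1e-9)
    except ValueError as err:
        raise RuntimeError(
            f"boundary calibration failed to bracket alpha={alpha} on "
            f"[{lo:.3f}, {hi:.3f}]"
        ) from err
    return StageBoundaries(u1=float(u2 * _SQRT2), u2=float(u2), l1=0.0, l2=float(u2))


def lfc_power(
    n_per_stage: float,
    delta: float,
    delta0: float,
    sigma: float,
    bounds: StageBoundaries,
    nodes: int = 80,
) -> float:
    """P(reject H0AB with AB maximal | muAB = Delta, muA = muB = delta0).

    Stage-1 term: conditioning on the combination arm's standardised noise t,
    the trial stops with AB rejected and maximal with probability
    Phi(t + dD - sqrt(2) u1) * Phi(t + (dD - dd))^2, where dD = sqrt(n)
    Delta/sigma and dd = sqrt(n) delta0/sigma (the control cancels from the
    between-arm comparison).

    Stage-2 term: a double integral over the control's stage-1 increment and
    the combination arm's standardised cumulative noise, with each rival arm
    contributing independently the probability of being dropped, or of
    surviving below u1 and finishing below the combination arm.
    """
    n = _positive_finite("n_per_stage", n_per_stage)
    d_big = np.sqrt(n) * delta / sigma
    d_small = np.sqrt(n) * delta0 / sigma
    u1, u2, l1 = bounds.u1, bounds.u2, bounds.l1
    t, w = _gh(nodes)

    term1 = float(np.sum(
        w * ndtr(t + d_big - _SQRT2 * u1) * ndtr(t + (d_big - d_small)) ** 2
    ))

    tau, s = np.meshgrid(t, t, indexing="ij")  # control stage-1; AB cumulative
    rival_b2 = s + _SQRT2 * (d_big - d_small)
    g = (
        ndtr(_SQRT2 * l1 + tau - d_small)
        + bvn_cdf(_SQRT2 * u1 + tau - d_small, rival_b2, _RHO)
        - bvn_cdf(_SQRT2 * l1 + tau - d_small, rival_b2, _RHO)
    )
    in_band = (
        ndtr(2.0 * u1 + _SQRT2 * (tau - d_big) - s)
        - ndtr(2.0 * l1 + _SQRT2 * (tau - d_big) - s)
    )
    final_cross = ndtr(_SQRT2 * s + 2.0 * d_big - 2.0 * u2 - tau)
    term2 = float(np.sum(w[:, None] * w[None, :] * g**2 * in_band * final_cross))
    return term1 + term2


def mams_power(design: MamsDesign) -> float:
    """Least-favourable-configuration power of a calibrated design."""
    return lfc_power(design.n_per_stage, design.delta, design.delta0,
                     design.sigma, design.boundaries)


def mams_sample_size(
    alpha: float,
    power_target: float,
    delta: float,
    delta0: float,
    sigma: float,
    boundaries: Optional[StageBoundaries] = None,
) -> MamsDesign:
    """Smallest per-arm per-stage size with LFC power >= the target."""
    if delta <= 0:
        raise ValueError("the interesting effect delta must be positive")
    if not 0.0 < power_target < 1.0:
        raise ValueError(f"power_target must lie in (0, 1), got {power_target}")
    bounds = obf_boundaries(alpha) if boundaries is None else boundaries

    def pw(n: float) -> float:
        return lfc_power(n, delta, delta0, sigma, bounds)

    hi = 8.0
    while pw(hi) < power_target:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("MAMS sample-size search failed to bracket the target")
    n_cont = brentq(lambda n: pw(n) - power_target, 1e-2, hi, xtol=1e-6)
    n = max(1, int(np.ceil(n_cont - 1e-9)))
    while pw(n) < power_target:
        n += 1
    while n > 1 and pw(n - 1) >= power_target:
        n -= 1
    return MamsDesign(
        boundaries=bounds, n_per_stage=n, alpha=alpha, power_target=power_target,
        delta=delta, delta0=delta0, sigma=sigma,
    )


def expected_sample_size(
    design: MamsDesign,
    scen: EffectScenario,
    nsim: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo expected total trial size under the stopping rules.

    Returns (estimate, standard error).  Early efficacy stopping and
    futility dropping shrink the realised size below the maximum of
    8 * n_per_stage; with u1 = l1 every trial stops at stage 1.
    """
    from .trial_sim import _simulate_mams  # local import: trial_sim imports us

    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    res = _simulate_mams(design, scen, nsim, seed)
    return res["expected_n"], res["expected_n_se"]
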