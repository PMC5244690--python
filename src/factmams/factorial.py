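"""2x2 factorial design: statistics from data, power, sample size, allocation.

The factorial statistics for the single treatments pool two independent
estimates of each effect -- the own-arm-versus-control contrast and the
combination-minus-other-arm contrast -- which is efficient under additivity
(no interaction).  The combination hypothesis is tested on its own arm and
control only.  Power is disjunctive throughout: the probability of rejecting
at least one of the three hypotheses at the common FWER-calibrated critical
value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .joint_dist import (
    AllocationRatios,
    EffectScenario,
    JointLaw,
    critical_value,
    factorial_covariance,
    factorial_mean,
    rejection_prob,
)

__all__ = [
    "GroupSummary",
    "SampleSizeResult",
    "GridSearchResult",
    "z_statistics",
    "power",
    "sample_size",
    "optimize_allocation",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample means and sizes of one realised trial (sigma known)."""

    ybar0: float
    ybarA: float
    ybarB: float
    ybarAB: float
    n0: int
    nA: int
    nB: int
    nAB: int
    sigma: float

    def __post_init__(self) -> None:
        for name in ("n0", "nA", "nB", "nAB"):
            n = getattr(self, name)
            if int(n) != n or n < 1:
                raise ValueError(f"{name} must be a positive integer, got {n}")
        # sigma = 0 is allowed so noiseless simulated data can be summarised;
        # computing z-statistics from such a summary is rejected instead
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size search at one allocation.

    ``n0_continuous`` solves power(n0) = target on the real line; ``n0`` is
    the smallest integer control-group size whose power reaches the target.
    ``total`` follows the convention round(n0 * (1 + 2r + q)); per-group
    sizes are individually rounded to the nearest patient.
    """

    n0_continuous: float
    n0: int
    nA: int
    nB: int
    nAB: int
    total: int
    power: float
    k: float
    alloc: AllocationRatios


class GridSearchResult(NamedTuple):
    table: pd.DataFrame  # columns r, q, objective, is_optimum
    r: float
    q: float
    value: float


def z_statistics(summary: GroupSummary, alloc: AllocationRatios) -> tuple[float, float, float]:
    """(ZA, ZB, ZAB) from observed group means.

    Requires nA = nB and group sizes consistent with (r, q) up to rounding;
    the statistics use the actual integer sizes.
    """
    if summary.sigma <= 0:
        raise ValueError("z-statistics need a positive sigma")
    if summary.nA != summary.nB:
        raise ValueError("the single-treatment arms must have equal size")
    for name, n, target in (
        ("nA", summary.nA, alloc.r * summary.n0),
        ("nB", summary.nB, alloc.r * summary.n0),
        ("nAB", summary.nAB, alloc.q * summary.n0),
    ):
        if abs(n - target) > 0.5 + 1e-9:
            raise ValueError(
                f"{name}={n} is inconsistent with the declared ratios "
                f"(expected about {target:.1f})"
            )
    n0, nA, nB, nAB = summary.n0, summary.nA, summary.nB, summary.nAB
    w1 = n0 * nA / (n0 + nA)
    w2 = nAB * nB / (nB + nAB)
    s = summary.sigma * np.sqrt(w1 + w2)
    z_a = (w1 * (summary.ybarA - summary.ybar0) + w2 * (summary.ybarAB - summary.ybarB)) / s
    z_b = (w1 * (summary.ybarB - summary.ybar0) + w2 * (summary.ybarAB - summary.ybarA)) / s
    z_ab = (summary.ybarAB - summary.ybar0) / (
        summary.sigma * np.sqrt((n0 + nAB) / (n0 * nAB))
    )
    return float(z_a), float(z_b), float(z_ab)


def power(
    alloc: AllocationRatios,
    n0: float,
    scen: EffectScenario,
    alpha: float,
    k: Optional[float] = None,
) -> float:
    """Disjunctive power of the factorial design with control size n0."""
    cov = factorial_covariance(alloc)
    if k is None:
        k = critical_value(cov, alpha)
    law = JointLaw(factorial_mean(alloc, n0, scen), cov)
    return rejection_prob(law, k)


def _smallest_integer_n0(power_fn: Callable[[float], float], target: float) -> tuple[float, int]:
    """Continuous root of power(n0)=target, then minimal integer achieving it.

    Power is strictly increasing in n0 whenever some treatment is effective,
    so bracketing by doubling is safe.
    """
    hi = 8.0
    while power_fn(hi) < target:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("sample-size search failed to bracket the target power")
    n_cont = brentq(lambda n: power_fn(n) - target, 1e-3, hi, xtol=1e-6)
    n0 = max(1, int(np.ceil(n_cont - 1e-9)))
    while power_fn(n0) < target:
        n0 += 1
    while n0 > 1 and power_fn(n0 - 1) >= target:
        n0 -= 1
    return float(n_cont), n0


def sample_size(
    alloc: AllocationRatios,
    scen: EffectScenario,
    alpha: float,
    power_target: float,
    *,
    _power=power,
    _cov=factorial_covariance,
) -> SampleSizeResult:
    """Smallest integer control-group size reaching the target power."""
    if not any(e > 0 for e in scen.effects):
        raise ValueError(
            "no treatment is superior to control in this scenario; "
            "the target power cannot be reached at any sample size"
        )
    k = critical_value(_cov(alloc), alpha)
    n_cont, n0 = _smallest_integer_n0(
        lambda n: _power(alloc, n, scen, alpha, k=k), power_target
    )
    r, q = alloc.r, alloc.q
    return SampleSizeResult(
        n0_continuous=n_cont,
        n0=n0,
        nA=int(round(r * n0)),
        nB=int(round(r * n0)),
        nAB=int(round(q * n0)),
        total=int(round(n0 * (1.0 + 2.0 * r + q))),
        power=_power(alloc, n0, scen, alpha, k=k),
        k=k,
        alloc=alloc,
    )


def optimize_allocation(
    r_grid,
    q_grid,
    objective: str = "critical-value",
    scen: Optional[EffectScenario] = None,
    alpha: float = 0.05,
    power_target: Optional[float] = None,
) -> GridSearchResult:
    """Evaluate an objective over the (r, q) grid and locate its minimum.

    ``objective`` is ``"critical-value"`` (minimise the FWER critical value)
    or ``"sample-size"`` (minimise the total trial size for the given
    scenario and power target).  Ties break to the first point in row-major
    (r-then-q) order.
    """
    r_grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    q_grid = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if r_grid.size == 0 or q_grid.size == 0:
        raise ValueError("allocation grids must be non-empty")
    if objective not in ("critical-value", "sample-size"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "sample-size" and (scen is None or power_target is None):
        raise ValueError("sample-size optimisation needs a scenario and a power target")

    rows = []
    best = None
    for r in r_grid:
        for q in q_grid:
            alloc = AllocationRatios(r, q)
            if objective == "critical-value":
                val = critical_value(factorial_covariance(alloc), alpha)
            else:
                val = float(sample_size(alloc, scen, alpha, power_target).total)
            rows.append((float(r), float(q), val))
            if best is None or val < best[2]:
                best = (float(r), float(q), val)

    table = pd.DataFrame(rows, columns=["r", "q", "objective"])
    table["is_optimum"] = (table["r"] == best[0]) & (table["q"] == best[1])
    # keep a single optimum flag under exact duplicates of the argmin point
    first = table.index[table["is_optimum"]][0]
    table["is_optimum"] = table.index == first
    return GridSearchResult(table=table, r=best[0], q=best[1], value=best[2])
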