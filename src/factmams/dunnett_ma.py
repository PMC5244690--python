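"""Single-stage multi-arm design: three active arms versus a shared control.

Each arm is compared with control on its own data only, so the three
z-statistics are a classic many-to-one (Dunnett) comparison: the joint null
law is trivariate normal with correlations induced solely by the shared
control arm.  Contracts mirror the factorial module with (ma_mean,
ma_covariance) in place of the factorial law; in particular the combination
statistic is the same in both designs, while the single-arm statistics here
ignore the combination arm entirely and are therefore unaffected by any
interaction between the treatments.
"""

from __future__ import annotations

from typing import Optional

from .joint_dist import (
    AllocationRatios,
    EffectScenario,
    JointLaw,
    critical_value,
    ma_covariance,
    ma_mean,
    rejection_prob,
)
from .factorial import SampleSizeResult, sample_size as _factorial_sample_size

__all__ = ["ma_critical_value", "ma_power", "ma_sample_size"]


def ma_critical_value(alloc: AllocationRatios, alpha: float) -> float:
    """One-sided Dunnett critical value (known sigma) at FWER alpha."""
    return critical_value(ma_covariance(alloc), alpha)


def ma_power(
    alloc: AllocationRatios,
    n0: float,
    scen: EffectScenario,
    alpha: float,
    k: Optional[float] = None,
) -> float:
    """Disjunctive power of the multi-arm design with control size n0."""
    cov = ma_covariance(alloc)
    if k is None:
        k = critical_value(cov, alpha)
    law = JointLaw(ma_mean(alloc, n0, scen), cov)
    return rejection_prob(law, k)


def ma_sample_size(
    alloc: AllocationRatios,
    scen: EffectScenario,
    alpha: float,
    power_target: float,
) -> SampleSizeResult:
    """Smallest integer control-group size reaching the target power."""
    return _factorial_sample_size(
        alloc, scen, alpha, power_target, _power=ma_power, _cov=ma_covariance
    )
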