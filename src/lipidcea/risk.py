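"""Cholesterol-mediated risk equations.

The engine links LDL-C levels to annual cardiovascular event rates
through the proportional-risk relationship popularised by the European
Atherosclerosis Society consensus statement and the Cholesterol
Treatment Trialists' meta-analyses: each 1 mmol/L of LDL-C carries a
multiplicative relative risk ``RR`` per event type, so

* relative risk reduction from treatment:  ``1 - RR**(LDL * Tx)``
* rate of a cholesterol subgroup at level ``c``:  ``R_x = R0 * RR**(-c)``
* observed cohort rate as a mixture over subgroups:
  ``R_all = R0 * sum_i p_i * RR**(-c_i)``

``R0`` is the hypothetical annual rate the cohort would incur at an
LDL-C of zero; it is back-solved from the observed rate and the baseline
cholesterol distribution, then used to re-scale rates as cholesterol
changes under treatment and drift.

A direct treatment effect on mortality (all-cause RR 0.90 per mmol/L)
is applied alongside the event-mediated pathway.  Because treated
cohorts also experience fewer high-mortality acute-event years, applying
the full direct effect would double-count part of the benefit; a
calibration factor ``k`` scales the direct effect (applied as
``RR**(k * LDL)``) so that the model's overall mortality reduction per
1 mmol/L matches the trial meta-analysis target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from .states import TIA


class DomainError(ValueError):
    """Raised when an argument is outside the mathematical domain."""


class CalibrationError(RuntimeError):
    """Raised when the mortality calibration cannot bracket a root."""


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a 95% interval (used for probabilistic draws)."""

    point: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.point <= self.upper):
                raise DomainError(
                    f"interval ({self.lower}, {self.upper}) does not contain point {self.point}"
                )

    @property
    def interval(self) -> tuple[float, float]:
        lo = self.point if self.lower is None else self.lower
        hi = self.point if self.upper is None else self.upper
        return (lo, hi)

    @property
    def degenerate(self) -> bool:
        lo, hi = self.interval
        return lo == hi == self.point


# Per-1-mmol/L relative risks from the CTT meta-analyses.  Unstable
# angina and TIA are not reported separately and default to the major
# cardiovascular event composite.
DEFAULT_EVENT_RR: dict[str, Estimate] = {
    "ischaemic_stroke": Estimate(0.78, 0.69, 0.80),
    "mi": Estimate(0.73, 0.67, 0.80),
    "unstable_angina": Estimate(0.78, 0.76, 0.80),
    "elective_revasc": Estimate(0.74, 0.71, 0.79),
    "pad": Estimate(0.78, 0.76, 0.80),
    TIA: Estimate(0.78, 0.76, 0.80),
}

MACE_RR = Estimate(0.78, 0.76, 0.80)


@dataclass(frozen=True)
class RelativeRiskSet:
    """Per-event relative risks per 1 mmol/L LDL-C reduction.

    ``mortality_adjustment`` is the calibration factor ``k`` in (0, 1]
    applied to the direct mortality effect.
    """

    events: Mapping[str, Estimate] = field(default_factory=lambda: dict(DEFAULT_EVENT_RR))
    rr_allcause_mortality: Estimate = Estimate(0.90, 0.87, 0.93)
    rr_cvd_death: Estimate = Estimate(0.80, 0.74, 0.87)
    mortality_adjustment: float = 1.0

    def __post_init__(self) -> None:
        for name, est in self.events.items():
            if not 0.0 < est.point <= 1.0:
                raise DomainError(f"relative risk for {name} must be in (0, 1]: {est.point}")
        if not 0.0 < self.mortality_adjustment <= 1.0:
            raise DomainError(
                f"mortality_adjustment must be in (0, 1]: {self.mortality_adjustment}"
            )

    def rr(self, event: str) -> float:
        try:
            return self.events[event].point
        except KeyError:
            raise DomainError(f"no relative risk configured for event {event!r}") from None

    def with_adjustment(self, k: float) -> "RelativeRiskSet":
        return replace(self, mortality_adjustment=k)

    def as_single_mace(self) -> "RelativeRiskSet":
        """Scenario variant: one composite MACE effect for all event types."""
        return replace(self, events={e: MACE_RR for e in self.events})


def risk_reduction(rr: float, ldl: float, tx: float) -> float:
    """Relative risk reduction ``1 - RR**(LDL * Tx)``.

    ``tx`` is the treatment effect as a fractional LDL-C reduction, so
    ``ldl * tx`` is the absolute reduction in mmol/L.
    """
    if rr <= 0:
        raise DomainError(f"relative risk must be positive: {rr}")
    if rr > 1:
        raise DomainError(f"relative risk must be <= 1: {rr}")
    if ldl < 0:
        raise DomainError(f"LDL-C must be non-negative: {ldl}")
    if not 0.0 <= tx <= 1.0:
        raise DomainError(f"treatment effect must be in [0, 1]: {tx}")
    return 1.0 - rr ** (ldl * tx)


def subgroup_rate(r0: float, rr: float, ldl: float) -> float:
    """Annual event rate of a subgroup at LDL-C level ``ldl``.

    ``rr`` is the relative risk per 1 mmol/L *reduction*, so each
    mmol/L of LDL-C above zero multiplies risk by ``1/rr``:
    ``R_x = R0 * rr**(-ldl)``.  Strictly increasing in ``ldl`` for
    ``rr < 1``, and reducing LDL-C by ``d`` multiplies the rate by
    ``rr**d``, consistent with :func:`risk_reduction`.
    """
    if r0 < 0:
        raise DomainError(f"baseline rate R0 must be non-negative: {r0}")
    if rr <= 0:
        raise DomainError(f"relative risk must be positive: {rr}")
    return r0 * rr ** (-ldl)


def solve_r0(
    observed_rate: float,
    rr: float,
    subgroups: Sequence[tuple[float, float]],
) -> float:
    """Back-solve the hypothetical zero-LDL rate from an observed cohort rate.

    ``subgroups`` is a sequence of ``(weight, ldl)`` pairs whose weights
    sum to 1.  Satisfies the round-trip identity
    ``sum_i w_i * subgroup_rate(r0, rr, ldl_i) == observed_rate``.
    """
    if observed_rate < 0:
        raise DomainError(f"observed rate must be non-negative: {observed_rate}")
    if not subgroups:
        raise DomainError("subgroup list must be non-empty")
    if rr <= 0:
        raise DomainError(f"relative risk must be positive: {rr}")
    total_w = math.fsum(w for w, _ in subgroups)
    if abs(total_w - 1.0) > 1e-9:
        raise DomainError(f"subgroup weights must sum to 1 (got {total_w})")
    denom = math.fsum(w * rr ** (-ldl) for w, ldl in subgroups)
    return observed_rate / denom


def calibrate_mortality_adjustment(
    model_runner: Callable[[float], float],
    target_rr: float = 0.90,
    tolerance: float = 1e-4,
    max_iter: int = 60,
) -> float:
    """Find the factor ``k`` scaling the direct mortality effect.

    ``model_runner(k)`` must return the model's overall mortality rate
    ratio under a uniform 1 mmol/L LDL-C reduction when the direct
    effect is applied as ``rr_allcause**(k * dLDL)``.  The ratio is
    monotone decreasing in ``k`` (stronger direct effect, lower treated
    mortality), so bisection on ``k in [0, 1]`` is used.  Returns the
    ``k`` for which the ratio matches ``target_rr`` within ``tolerance``.
    """
    if not 0.0 < target_rr <= 1.0:
        raise DomainError(f"target_rr must be in (0, 1]: {target_rr}")
    if target_rr == 1.0:
        # Null direct effect requested; any k is equivalent.
        return 1.0

    lo, hi = 0.0, 1.0
    f_lo = model_runner(lo) - target_rr
    if abs(f_lo) <= tolerance:
        # Guard against k=0: the factor must stay in (0, 1].
        return min(max(1e-9, lo), 1.0) if lo > 0 else 1e-9
    f_hi = model_runner(hi) - target_rr
    if abs(f_hi) <= tolerance:
        return hi
    if f_lo * f_hi > 0:
        raise CalibrationError(
            "mortality calibration cannot bracket the target: "
            f"ratio(k=0)={f_lo + target_rr:.6f}, ratio(k=1)={f_hi + target_rr:.6f}, "
            f"target={target_rr:.6f}. The indirect (event-mediated) channel alone "
            "either overshoots the target or the direct effect at k=1 is insufficient."
        )
    k = 0.5
    for _ in range(max_iter):
        k = 0.5 * (lo + hi)
        f_mid = model_runner(k) - target_rr
        if abs(f_mid) <= tolerance:
            return k
        if f_lo * f_mid < 0:
            hi = k
            f_hi = f_mid
        else:
            lo = k
            f_lo = f_mid
    return k
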