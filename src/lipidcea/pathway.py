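"""Threshold-triggered treatment escalation pathway.

People enter on background statin therapy.  At the start of each yearly
cycle their lipid level (LDL-C or non-HDL-C) is measured; if it sits
above the escalation threshold, the next line of therapy is added:
ezetimibe first, then an injectable (inclisiran or a PCSK9 inhibitor).
Escalation can happen twice within a cycle when the first added drug is
not enough to bring the cohort's mean level below the threshold.  The
pathway deliberately prefers the cheaper drug: if ezetimibe alone brings
the level just below the threshold, the injectable is not added.

All treatment effects are relative reductions versus placebo on a
background of statins, and compose multiplicatively on the
statin-background lipid level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .risk import Estimate
from .states import ConfigurationError

STATIN = "statin_background"
EZETIMIBE = "ezetimibe"
INCLISIRAN = "inclisiran"
PCSK9 = "pcsk9"

LDL = "LDL-C"
NON_HDL = "non-HDL-C"

GP_VISIT = "gp_visit"
OUTPATIENT_VISIT = "outpatient_visit"
NURSE_VISIT = "nurse_visit"
LIPID_TEST = "lipid_test"


@dataclass(frozen=True)
class Therapy:
    """One line of lipid-lowering therapy.

    Reductions are fractional decreases of the lipid measure versus
    placebo on background statin (network meta-analysis point estimates
    with 95% credible intervals).  ``line`` orders the escalation
    sequence; the background statin is line 0 and has no incremental
    effect (it is the reference).
    """

    name: str
    ldl_reduction: Estimate
    nonhdl_reduction: Estimate
    annual_drug_cost: float
    initiation_resource: str = GP_VISIT
    line: int = 0
    trigger_threshold: float | None = None  # absolute trigger, e.g. PCSK9 above 3.5 mmol/L

    def __post_init__(self) -> None:
        for est in (self.ldl_reduction, self.nonhdl_reduction):
            if not 0.0 <= est.point < 1.0:
                raise ConfigurationError(
                    f"{self.name}: reduction must be in [0, 1): {est.point}"
                )

    def reduction(self, measure: str) -> float:
        if measure == LDL:
            return self.ldl_reduction.point
        if measure == NON_HDL:
            return self.nonhdl_reduction.point
        raise ConfigurationError(f"unknown lipid measure: {measure!r}")


def default_therapies(
    inclisiran_annual_cost: float,
    pcsk9_annual_cost: float,
    ezetimibe_annual_cost: float,
    statin_annual_cost: float,
) -> dict[str, Therapy]:
    """Therapy catalogue with meta-analysis effects; drug prices are inputs.

    Injectable prices are commercial-in-confidence in the source
    material, so callers always provide placeholder or local prices.
    """
    return {
        STATIN: Therapy(
            STATIN,
            Estimate(0.0),
            Estimate(0.0),
            annual_drug_cost=statin_annual_cost,
            line=0,
        ),
        EZETIMIBE: Therapy(
            EZETIMIBE,
            Estimate(0.178, 0.119, 0.237),
            Estimate(0.200, 0.069, 0.330),
            annual_drug_cost=ezetimibe_annual_cost,
            initiation_resource=GP_VISIT,
            line=1,
        ),
        INCLISIRAN: Therapy(
            INCLISIRAN,
            Estimate(0.513, 0.405, 0.619),
            Estimate(0.451, 0.310, 0.586),
            annual_drug_cost=inclisiran_annual_cost,
            initiation_resource=GP_VISIT,
            line=2,
        ),
        PCSK9: Therapy(
            PCSK9,
            Estimate(0.550, 0.494, 0.603),
            Estimate(0.470, 0.394, 0.543),
            annual_drug_cost=pcsk9_annual_cost,
            initiation_resource=OUTPATIENT_VISIT,
            line=2,
        ),
    }


@dataclass(frozen=True)
class EscalationPolicy:
    """A candidate policy: escalate whenever the measured level exceeds ``threshold``."""

    threshold: float
    measure: str = LDL
    sequence: tuple[str, ...] = (EZETIMIBE, INCLISIRAN)
    injectable_choice: str = "inclisiran_only"
    adherence: Mapping[str, float] = field(default_factory=dict)
    allow_double_escalation: bool = True
    statin_background: bool = True

    def __post_init__(self) -> None:
        for name, a in self.adherence.items():
            if not 0.0 <= a <= 1.0:
                raise ConfigurationError(f"adherence for {name} must be in [0, 1]: {a}")

    def adherence_of(self, therapy_name: str) -> float:
        return float(self.adherence.get(therapy_name, 1.0))

    def with_threshold(self, threshold: float) -> "EscalationPolicy":
        return replace(self, threshold=threshold)


@dataclass(frozen=True)
class TreatmentState:
    """Therapy status of one cohort arm.

    ``initiated`` records every line that has been offered (including
    lines a non-adherent arm does not benefit from); ``active`` records
    the lines actually taken (cost and effect).
    """

    initiated: frozenset[str] = frozenset()
    active: frozenset[str] = frozenset()
    cycle_of_last_initiation: int = -1
    last_initiations: tuple[str, ...] = ()

    def initiated_this_cycle(self, cycle: int) -> tuple[str, ...]:
        return self.last_initiations if self.cycle_of_last_initiation == cycle else ()


def effective_ldl(
    baseline_ldl: float,
    therapies: Iterable[Therapy],
    measure: str = LDL,
) -> float:
    """Lipid level on ``measure`` scale after composing active therapy effects.

    ``baseline_ldl`` is the statin-background level on the measure's own
    scale.  Effects compose multiplicatively: each non-statin therapy
    scales the level by ``(1 - reduction)``; order is irrelevant.
    """
    level = baseline_ldl
    for t in therapies:
        level *= 1.0 - t.reduction(measure)
    return level


def escalate(
    state: TreatmentState,
    measured: float,
    policy: EscalationPolicy,
    catalogue: Mapping[str, Therapy],
    cycle: int,
) -> tuple[TreatmentState, list[tuple[str, str]]]:
    """Escalation decision for one cycle, assuming full adherence.

    Returns the updated state and the initiation resource events as
    ``(resource, therapy_name)`` pairs.  Lines are tried in sequence
    order; a second line is added in the same cycle only when the first
    does not bring the measured level to or below the threshold (and
    double escalation is allowed).  A line with an absolute
    ``trigger_threshold`` (the PCSK9-above-3.5 rule) is only started
    when the current level exceeds that trigger.
    """
    for name in policy.sequence:
        if name not in catalogue:
            raise ConfigurationError(f"unknown therapy in sequence: {name!r}")
    if measured <= policy.threshold:
        return state, []

    initiated = set(state.initiated)
    active = set(state.active)
    events: list[tuple[str, str]] = []
    value = measured
    max_initiations = 2 if policy.allow_double_escalation else 1
    started: list[str] = []
    for name in policy.sequence:
        if len(started) >= max_initiations:
            break
        if value <= policy.threshold:
            break
        if name in initiated:
            continue
        therapy = catalogue[name]
        if therapy.trigger_threshold is not None and value <= therapy.trigger_threshold:
            continue
        initiated.add(name)
        active.add(name)
        started.append(name)
        events.append((therapy.initiation_resource, name))
        value *= 1.0 - therapy.reduction(policy.measure)
    if not started:
        return state, []
    new_state = TreatmentState(
        initiated=frozenset(initiated),
        active=frozenset(active),
        cycle_of_last_initiation=cycle,
        last_initiations=tuple(started),
    )
    return new_state, events


def apply_adherence(therapy: Therapy, adherence: float) -> list[tuple[float, bool]]:
    """Cohort split for a newly initiated line.

    Returns ``(fraction, takes_drug)`` branches: the adherent fraction
    bears the full drug cost and effect, the non-adherent fraction
    neither (and is not re-offered the line).
    """
    if not 0.0 <= adherence <= 1.0:
        raise ConfigurationError(f"adherence must be in [0, 1]: {adherence}")
    branches = []
    if adherence > 0.0:
        branches.append((adherence, True))
    if adherence < 1.0:
        branches.append((1.0 - adherence, False))
    return branches


def monitoring_schedule(
    state: TreatmentState,
    cycle: int,
    catalogue: Mapping[str, Therapy],
) -> list[tuple[str, int]]:
    """Resource events for routine monitoring in one cycle.

    Everyone alive has an annual lipid test; a cycle with at least one
    treatment initiation adds one post-initiation lipid test, plus the
    initiation visit (GP appointment, or hospital outpatient visit for
    PCSK9 inhibitors) per started line.
    """
    events: list[tuple[str, int]] = [(LIPID_TEST, 1)]
    started = state.initiated_this_cycle(cycle)
    if started:
        events.append((LIPID_TEST, 1))
        for name in started:
            events.append((catalogue[name].initiation_resource, 1))
    return events
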