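"""Cohort Markov engine.

Each subgroup ("super patient") is advanced through yearly cycles over
a lifetime horizon.  Within a cycle the order of operations is: LDL-C
drift -> measurement -> threshold-triggered escalation (with adherence
splitting the cohort into arms) -> LDL-adjusted rates -> transition.

Annual rates convert to probabilities via ``1 - exp(-R)`` on the total
rate, allocated proportionally among competing transitions (new events
and death), the standard competing-risks discretisation.  Acute states
last exactly one cycle and then resolve to a post state; the post state
kept is that of the more severe event in the person's history, encoded
by acute tunnel states (see :mod:`lipidcea.states`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np

from .inputs import InputBundle, Subgroup, apply_drift
from .pathway import (
    EZETIMIBE,
    INCLISIRAN,
    LDL,
    PCSK9,
    STATIN,
    EscalationPolicy,
    TreatmentState,
    Therapy,
)
from .states import EVENTS, RANK_TO_EVENT, SEVERITY_RANK, TIA, StateSpace


class NumericIntegrityError(RuntimeError):
    """Raised when occupancy or transition probabilities lose integrity."""


# ---------------------------------------------------------------------------
# State-space assembly indices (cached per space)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _assembly(space: StateSpace) -> dict:
    n = space.n_states
    alive = space.alive_indices()
    n_alive = len(alive)
    dest = np.empty((n_alive, len(EVENTS)), dtype=np.intp)
    remain = np.empty(n_alive, dtype=np.intp)
    ctx = np.empty(n_alive, dtype=np.intp)  # 0 = post context, 1+e = acute context of event e
    for i in alive:
        resolved = space.resolved_event(i)
        for g_idx, g in enumerate(EVENTS):
            worse = RANK_TO_EVENT[min(SEVERITY_RANK[g], SEVERITY_RANK[resolved])]
            dest[i, g_idx] = space.acute_index(g, worse)
        remain[i] = space.post_index(resolved)
        acute_ev = space.acute_event(i)
        ctx[i] = 0 if acute_ev is None else 1 + EVENTS.index(acute_ev)
    flat_event = (np.arange(n_alive)[:, None] * n + dest).ravel()
    flat_remain = np.arange(n_alive) * n + remain
    flat_death = np.arange(n_alive) * n + space.dead_index
    return {
        "dest": dest,
        "remain": remain,
        "ctx": ctx,
        "flat_event": flat_event,
        "flat_remain": flat_remain,
        "flat_death": flat_death,
    }


def _transition_probs(
    event_rates: np.ndarray, death_rates: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Competing-risks allocation of annual rates to probabilities.

    Returns ``(p_event, p_death, p_remain)`` for each alive state:
    total rate ``R`` converts to ``1 - exp(-R)`` shared among causes in
    proportion to their rates, so rows sum exactly to 1.
    """
    if np.any(event_rates < 0) or np.any(death_rates < 0):
        raise NumericIntegrityError("negative annual rates supplied")
    total = event_rates.sum() + death_rates
    p_any = -np.expm1(-total)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, p_any / np.where(total > 0, total, 1.0), 0.0)
    p_event = frac[:, None] * event_rates[None, :]
    p_death = frac * death_rates
    p_remain = 1.0 - p_any
    return p_event, p_death, p_remain


def build_transition_matrix(
    space: StateSpace,
    event_rates: Mapping[str, float] | np.ndarray,
    death_rates: Mapping[str, float] | np.ndarray,
) -> np.ndarray:
    """Row-stochastic transition matrix for one cycle.

    ``event_rates`` gives the annual rate of each new acute event
    (applying to every alive state); ``death_rates`` gives the annual
    death rate per alive state, either as a vector over alive states or
    as a mapping with keys ``"post"`` and ``"acute:<event>"``.
    """
    asm = _assembly(space)
    n = space.n_states
    n_alive = n - 1
    if isinstance(event_rates, Mapping):
        ev = np.array([float(event_rates.get(e, 0.0)) for e in EVENTS])
    else:
        ev = np.asarray(event_rates, dtype=float)
    if isinstance(death_rates, Mapping):
        m = np.empty(n_alive)
        for i in range(n_alive):
            c = asm["ctx"][i]
            key = "post" if c == 0 else f"acute:{EVENTS[c - 1]}"
            m[i] = float(death_rates.get(key, death_rates.get("post", 0.0)))
    else:
        m = np.asarray(death_rates, dtype=float)
        if m.shape == ():
            m = np.full(n_alive, float(m))
    p_event, p_death, p_remain = _transition_probs(ev, m)
    mat = np.zeros((n, n))
    flat = mat.ravel()
    np.add.at(flat, asm["flat_event"], p_event.ravel())
    np.add.at(flat, asm["flat_remain"], p_remain)
    np.add.at(flat, asm["flat_death"], p_death)
    mat[space.dead_index, space.dead_index] = 1.0
    rows = mat.sum(axis=1)
    if np.any(mat < -1e-15) or np.max(np.abs(rows - 1.0)) > 1e-12:
        raise NumericIntegrityError("transition matrix rows do not sum to 1")
    return mat


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------


@dataclass
class CohortTrace:
    """Per-cycle occupancy, incidence and valued outcomes for one subgroup."""

    space: StateSpace
    occupancy: np.ndarray  # (T+1, n_states)
    incidence: np.ndarray  # (T, n_events) new acute events entering each cycle
    tia_incidence: np.ndarray  # (T,)
    deaths: np.ndarray  # (T,)
    person_years: np.ndarray  # (T,) alive mass at each accrual cycle
    coverage: dict[str, np.ndarray]  # therapy -> (T,) fraction of alive on drug
    mean_ldl: np.ndarray  # (T,) alive-weighted measured lipid level after treatment
    cost: np.ndarray  # (T,) undiscounted GBP
    qaly: np.ndarray  # (T,) undiscounted QALYs
    disc_cost: float = 0.0
    disc_qaly: float = 0.0

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    def coverage_at(self, therapy: str, cycle: int) -> float:
        arr = self.coverage.get(therapy)
        if arr is None or len(arr) == 0:
            return 0.0
        return float(arr[min(cycle, len(arr) - 1)])

    def mean_ldl_at(self, cycle: int) -> float:
        if len(self.mean_ldl) == 0:
            return math.nan
        return float(self.mean_ldl[min(cycle, len(self.mean_ldl) - 1)])


@dataclass
class _Arm:
    weight: float
    state: TreatmentState
    occ: np.ndarray
    measured: float = 0.0
    risk_ldl: float = 0.0
    n_adherent_initiations: int = 0
    initiation_resources: tuple[str, ...] = ()


def _escalate_with_adherence(
    arm: _Arm,
    policy: EscalationPolicy,
    catalogue: Mapping[str, Therapy],
    cycle: int,
    resource_lists: Mapping[str, tuple[str, ...]],
) -> list[_Arm]:
    """Escalation step for one arm, splitting on per-line adherence.

    Non-adherent branches incur neither drug cost nor initiation
    resources nor benefit, but are not re-offered the line.
    """
    work = [arm]
    done: list[_Arm] = []
    max_init = 2 if policy.allow_double_escalation else 1
    while work:
        a = work.pop()
        if a.measured <= policy.threshold:
            done.append(a)
            continue
        n_offered = len(a.state.initiated_this_cycle(cycle))
        if n_offered >= max_init:
            done.append(a)
            continue
        nxt: Therapy | None = None
        for name in policy.sequence:
            if name in a.state.initiated:
                continue
            t = catalogue[name]
            if t.trigger_threshold is not None and a.measured <= t.trigger_threshold:
                continue
            nxt = t
            break
        if nxt is None:
            done.append(a)
            continue
        adherence = policy.adherence_of(nxt.name)
        started = a.state.initiated_this_cycle(cycle) + (nxt.name,)
        base_initiated = a.state.initiated | {nxt.name}
        if adherence > 0.0:
            st = TreatmentState(
                initiated=frozenset(base_initiated),
                active=a.state.active | {nxt.name},
                cycle_of_last_initiation=cycle,
                last_initiations=started,
            )
            work.append(
                _Arm(
                    weight=a.weight * adherence,
                    state=st,
                    occ=a.occ * adherence,
                    measured=a.measured * (1.0 - nxt.reduction(policy.measure)),
                    n_adherent_initiations=a.n_adherent_initiations + 1,
                    initiation_resources=a.initiation_resources
                    + resource_lists[nxt.name],
                )
            )
        if adherence < 1.0:
            st = TreatmentState(
                initiated=frozenset(base_initiated),
                active=a.state.active,
                cycle_of_last_initiation=cycle,
                last_initiations=started,
            )
            work.append(
                _Arm(
                    weight=a.weight * (1.0 - adherence),
                    state=st,
                    occ=a.occ * (1.0 - adherence),
                    measured=a.measured,
                    n_adherent_initiations=a.n_adherent_initiations,
                    initiation_resources=a.initiation_resources,
                )
            )
    return done


def run_cohort(
    subgroup: Subgroup,
    policy: EscalationPolicy,
    prepared,
    horizon: int | None = None,
    ldl_shift: float = 0.0,
) -> CohortTrace:
    """Run one subgroup through its lifetime under an escalation policy.

    ``prepared`` is a :class:`lipidcea.model.PreparedModel` carrying the
    calibrated zero-LDL rates and precomputed valuation tables.
    ``ldl_shift`` adds a uniform offset to the risk-determining LDL-C
    (used by the mortality calibration).
    """
    bundle: InputBundle = prepared.bundle
    space: StateSpace = prepared.space
    asm = _assembly(space)
    cfg = bundle.config
    sex = subgroup.sex
    n = space.n_states
    dead = space.dead_index
    alive_sl = slice(0, n - 1)

    age_cap = float(cfg.get("age_cap", 100.0))
    alive_floor = float(cfg.get("alive_floor", 1e-9))
    ldl_floor = bundle.drift.ldl_floor
    half_cycle = bool(cfg.get("half_cycle_correction", False))
    offset = float(cfg.get("nonhdl_offset", 0.65))
    measure = policy.measure
    discount_rate = bundle.costs.discount_rate
    cvd_fraction = bundle.mortality.cvd_fraction
    lipid_test_cost = bundle.costs.unit("lipid_test")
    vd_cost = bundle.costs.vascular_death_acute
    tia_acute_cost = bundle.costs.flat_acute_costs.get(TIA, 0.0)
    catalogue = bundle.therapies
    resource_lists = prepared.initiation_resources

    max_cycles = int(age_cap - subgroup.entry_age) + 1
    if horizon is not None:
        max_cycles = min(max_cycles, horizon)
    max_cycles = max(max_cycles, 0)

    # Initial occupancy over post states.
    occ0 = np.zeros(n)
    for i, name in enumerate(space.posts):
        occ0[i] = bundle.baseline_states.fraction(name)

    active0 = frozenset({STATIN}) if policy.statin_background else frozenset()
    arms: list[_Arm] = [_Arm(weight=1.0, state=TreatmentState(active=active0), occ=occ0)]

    T = max_cycles
    occupancy = np.zeros((T + 1, n))
    occupancy[0] = occ0
    incidence = np.zeros((T, len(EVENTS)))
    tia_inc_arr = np.zeros(T)
    deaths_arr = np.zeros(T)
    person_years = np.zeros(T)
    cost_arr = np.zeros(T)
    qaly_arr = np.zeros(T)
    cov = {name: np.zeros(T) for name in (EZETIMIBE, INCLISIRAN, PCSK9)}
    mean_ldl = np.zeros(T)
    disc_cost = 0.0
    disc_qaly = 0.0

    untreated = subgroup.baseline_ldl
    escalation_on = math.isfinite(policy.threshold)
    drug_cost_cache: dict[frozenset, float] = {}

    t_done = 0
    for t in range(T):
        total_alive = sum(float(a.occ[alive_sl].sum()) for a in arms)
        if total_alive < alive_floor:
            break
        if t >= 1:
            untreated = apply_drift(untreated, subgroup, t, bundle.drift)

        baseline_measured = untreated + (offset if measure != LDL else 0.0)
        # Measure on treated level, escalate, then fix each arm's risk LDL.
        new_arms: list[_Arm] = []
        for arm in arms:
            level = baseline_measured
            for name in arm.state.active:
                level *= 1.0 - catalogue[name].reduction(measure)
            arm.measured = level
            arm.n_adherent_initiations = 0
            arm.initiation_resources = ()
            if escalation_on and level > policy.threshold:
                new_arms.extend(
                    _escalate_with_adherence(arm, policy, catalogue, t, resource_lists)
                )
            else:
                new_arms.append(arm)
        arms = new_arms
        for arm in arms:
            risk = arm.measured - (offset if measure != LDL else 0.0)
            arm.risk_ldl = max(risk + ldl_shift, ldl_floor)

        age = subgroup.entry_age + t
        band = prepared.band_of(age)
        df = (1.0 + discount_rate) ** (-t)
        u_base = prepared.baseline_utility[sex][band]
        state_costs = prepared.state_cost[sex][band]
        mult_vec = prepared.multiplier_vec

        occ_next_total = np.zeros(n)
        cost_t = 0.0
        qaly_t = 0.0
        deaths_t = 0.0
        tia_t = 0.0
        inc_t = np.zeros(len(EVENTS))
        cov_t = {name: 0.0 for name in cov}
        ldl_t = 0.0

        for arm in arms:
            occ = arm.occ
            alive = float(occ[alive_sl].sum())
            if occ.sum() <= 0.0:
                continue
            r = arm.risk_ldl
            ev = prepared.event_rates_at(sex, band, r)
            tia_rate = prepared.tia_rate_at(sex, band, r)
            m = prepared.death_rates_at(sex, band, r, asm["ctx"])
            p_event, p_death, p_remain = _transition_probs(ev, m)

            occ_alive = occ[alive_sl]
            occ_next = np.zeros(n)
            np.add.at(occ_next, asm["dest"].ravel(), (occ_alive[:, None] * p_event).ravel())
            np.add.at(occ_next, asm["remain"], occ_alive * p_remain)
            d = float(occ_alive @ p_death)
            occ_next[dead] = occ[dead] + d

            inc_t += occ_alive @ p_event
            tia_arm = alive * tia_rate
            tia_t += tia_arm
            deaths_t += d

            occ_for_accrual = occ
            if half_cycle:
                occ_for_accrual = 0.5 * (occ + occ_next)
            qaly_t += u_base * float(occ_for_accrual @ mult_vec)

            active = arm.state.active
            key = active
            drug = drug_cost_cache.get(key)
            if drug is None:
                drug = sum(catalogue[name].annual_drug_cost for name in active)
                drug_cost_cache[key] = drug
            c = float(occ_for_accrual @ state_costs)
            c += alive * (drug + lipid_test_cost)
            if arm.n_adherent_initiations:
                c += alive * lipid_test_cost  # post-initiation re-test
                for resource in arm.initiation_resources:
                    c += alive * bundle.costs.unit(resource)
            c += tia_arm * tia_acute_cost
            c += d * cvd_fraction * vd_cost
            cost_t += c

            for name in cov_t:
                if name in active:
                    cov_t[name] += alive
            ldl_t += alive * arm.measured

            arm.occ = occ_next
            occ_next_total += occ_next

        total = float(occ_next_total.sum())
        if not math.isfinite(total):
            raise NumericIntegrityError("non-finite occupancy encountered")
        if abs(total - 1.0) > 1e-10:
            raise NumericIntegrityError(
                f"occupancy mass not conserved at cycle {t}: {total}"
            )

        occupancy[t + 1] = occ_next_total
        incidence[t] = inc_t
        tia_inc_arr[t] = tia_t
        deaths_arr[t] = deaths_t
        person_years[t] = total_alive
        cost_arr[t] = cost_t
        qaly_arr[t] = qaly_t
        for name in cov:
            cov[name][t] = cov_t[name] / total_alive if total_alive > 0 else 0.0
        mean_ldl[t] = ldl_t / total_alive if total_alive > 0 else math.nan
        disc_cost += cost_t * df
        disc_qaly += qaly_t * df
        t_done = t + 1

        # Merge arms that have converged to identical treatment status.
        if len(arms) > 1:
            merged: dict[tuple, _Arm] = {}
            for arm in arms:
                key = (arm.state.initiated, arm.state.active)
                if key in merged:
                    merged[key].weight += arm.weight
                    merged[key].occ = merged[key].occ + arm.occ
                else:
                    merged[key] = arm
            arms = list(merged.values())

    return CohortTrace(
        space=space,
        occupancy=occupancy[: t_done + 1],
        incidence=incidence[:t_done],
        tia_incidence=tia_inc_arr[:t_done],
        deaths=deaths_arr[:t_done],
        person_years=person_years[:t_done],
        coverage={k: v[:t_done] for k, v in cov.items()},
        mean_ldl=mean_ldl[:t_done],
        cost=cost_arr[:t_done],
        qaly=qaly_arr[:t_done],
        disc_cost=disc_cost,
        disc_qaly=disc_qaly,
    )
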