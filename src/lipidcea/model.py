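"""Calibrated model preparation.

Turns an :class:`~lipidcea.inputs.InputBundle` into the precomputed
arrays the cohort engine consumes:

* per-cell hypothetical zero-LDL rates ``R0`` back-solved from the
  observed admission rates and the baseline LDL-C mixture (the observed
  cohort rate is the subgroup-weighted mean of ``R0 * RR**(-c_i)``,
  ``RR`` being the relative risk per 1 mmol/L reduction);
* mortality baselines per context (post vs the 12 months after each
  admission type), with the direct mortality treatment effect applied
  as ``RR_mort**(k * LDL)`` where ``k`` is the calibration factor;
* valuation tables (state costs and utility multipliers) resolved per
  sex and age band.

The calibration factor ``k`` is found by bisection so that a uniform
1 mmol/L LDL-C reduction changes the model's overall death rate (deaths
per person-year over a follow-up window) by exactly the trial target
(all-cause mortality rate ratio 0.90 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .bands import AGE_BAND_EDGES, band_index
from .economics import state_cost_vector, state_multiplier_vector
from .inputs import SEXES, InputBundle
from .pathway import GP_VISIT, INCLISIRAN, NURSE_VISIT, EscalationPolicy
from .risk import calibrate_mortality_adjustment
from .states import EVENTS, TIA, StateSpace


@dataclass
class PreparedModel:
    """Bundle plus everything precomputed for fast cohort runs."""

    bundle: InputBundle
    space: StateSpace
    k: float
    rr_event_vec: np.ndarray  # (n_events,)
    rr_tia: float
    rr_mort_eff: float  # RR_mort ** k, applied per mmol/L
    r0_event: Mapping[str, np.ndarray]  # sex -> (N_BANDS, n_events)
    r0_tia: Mapping[str, np.ndarray]  # sex -> (N_BANDS,)
    mort_coeff: Mapping[str, np.ndarray]  # sex -> (N_BANDS, 1 + n_events), LDL-linked part
    mort_flat: Mapping[str, np.ndarray]  # sex -> (N_BANDS, 1 + n_events), LDL-free part
    baseline_utility: Mapping[str, np.ndarray]  # sex -> (N_BANDS,)
    state_cost: Mapping[str, np.ndarray]  # sex -> (N_BANDS, n_states)
    multiplier_vec: np.ndarray  # (n_states,)
    initiation_resources: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @staticmethod
    def band_of(age: float) -> int:
        return band_index(age)

    def event_rates_at(self, sex: str, band: int, ldl: float) -> np.ndarray:
        return self.r0_event[sex][band] * self.rr_event_vec ** (-ldl)

    def tia_rate_at(self, sex: str, band: int, ldl: float) -> float:
        return float(self.r0_tia[sex][band] * self.rr_tia ** (-ldl))

    def death_rates_at(self, sex: str, band: int, ldl: float, ctx: np.ndarray) -> np.ndarray:
        row = self.mort_flat[sex][band] + self.mort_coeff[sex][band] * self.rr_mort_eff ** (-ldl)
        return row[ctx]


def _sex_mixture(bundle: InputBundle, sex: str) -> tuple[np.ndarray, np.ndarray]:
    subs = bundle.subgroups_of_sex(sex)
    w = np.array([s.weight for s in subs])
    if w.sum() <= 0:
        raise ValueError(f"no subgroups for sex {sex!r}")
    return w / w.sum(), np.array([s.baseline_ldl for s in subs])


def _solve_r0_arrays(
    bundle: InputBundle, rr_events: np.ndarray, rr_tia: float
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    r0_event: dict[str, np.ndarray] = {}
    r0_tia: dict[str, np.ndarray] = {}
    for sex in SEXES:
        w, c = _sex_mixture(bundle, sex)
        denom_ev = np.array([(w * rr ** (-c)).sum() for rr in rr_events])
        obs = np.stack([bundle.event_rates.array(e, sex) for e in EVENTS], axis=1)
        r0_event[sex] = obs / denom_ev[None, :]
        denom_tia = (w * rr_tia ** (-c)).sum()
        r0_tia[sex] = bundle.event_rates.array(TIA, sex) / denom_tia
    return r0_event, r0_tia


def _solve_mortality_arrays(
    bundle: InputBundle, rr_mort_eff: float
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Split observed mortality into an LDL-linked and a flat component.

    In the all-cause mode the whole rate is LDL-linked; in the CVD-only
    mode only the CVD share of deaths responds to LDL-C and the
    remainder enters as a flat hazard.
    """
    mode = bundle.config.get("mortality_mode", "all_cause")
    cvd_share = bundle.mortality.cvd_fraction if mode == "cvd_only" else 1.0
    coeff: dict[str, np.ndarray] = {}
    flat: dict[str, np.ndarray] = {}
    for sex in SEXES:
        w, c = _sex_mixture(bundle, sex)
        denom = (w * rr_mort_eff ** (-c)).sum()
        cols_obs = [bundle.mortality.array(sex, "post")] + [
            bundle.mortality.array(sex, f"acute:{e}") for e in EVENTS
        ]
        obs = np.stack(cols_obs, axis=1)  # (N_BANDS, 1 + n_events)
        coeff[sex] = obs * cvd_share / denom
        flat[sex] = obs * (1.0 - cvd_share)
    return coeff, flat


def _initiation_resources(bundle: InputBundle) -> dict[str, tuple[str, ...]]:
    variant = bundle.config.get("escalation_resource_variant", "one_gp")
    resources = {
        name: (therapy.initiation_resource,) for name, therapy in bundle.therapies.items()
    }
    if variant == "two_gp_one_nurse" and INCLISIRAN in resources:
        resources[INCLISIRAN] = (GP_VISIT, GP_VISIT, NURSE_VISIT)
    return resources


def _prepare_with_k(bundle: InputBundle, k: float, space: StateSpace) -> PreparedModel:
    rrset = bundle.relative_risks
    rr_events = np.array([rrset.rr(e) for e in EVENTS])
    rr_tia = rrset.rr(TIA)
    mode = bundle.config.get("mortality_mode", "all_cause")
    rr_mort = (
        rrset.rr_cvd_death.point if mode == "cvd_only" else rrset.rr_allcause_mortality.point
    )
    rr_mort_eff = rr_mort**k
    r0_event, r0_tia = _solve_r0_arrays(bundle, rr_events, rr_tia)
    mort_coeff, mort_flat = _solve_mortality_arrays(bundle, rr_mort_eff)

    baseline_utility = {
        sex: np.asarray(bundle.utilities.baseline[sex], dtype=float) for sex in SEXES
    }
    state_cost = {}
    for sex in SEXES:
        rows = []
        for lo, _hi in AGE_BAND_EDGES:
            rows.append(state_cost_vector(space, sex, lo + 2.0, bundle.costs))
        state_cost[sex] = np.stack(rows, axis=0)

    return PreparedModel(
        bundle=bundle,
        space=space,
        k=k,
        rr_event_vec=rr_events,
        rr_tia=rr_tia,
        rr_mort_eff=rr_mort_eff,
        r0_event=r0_event,
        r0_tia=r0_tia,
        mort_coeff=mort_coeff,
        mort_flat=mort_flat,
        baseline_utility=baseline_utility,
        state_cost=state_cost,
        multiplier_vec=state_multiplier_vector(space, bundle.utilities),
        initiation_resources=_initiation_resources(bundle),
    )


def mortality_rate_ratio(
    bundle: InputBundle,
    k: float,
    delta_ldl: float = -1.0,
    window: int | None = None,
    space: StateSpace | None = None,
) -> float:
    """Overall death-rate ratio under a uniform LDL-C shift.

    Runs every subgroup with no treatment pathway twice -- at observed
    LDL-C and shifted by ``delta_ldl`` -- and compares deaths per
    person-year over the follow-up ``window`` (config default).
    """
    from .markov import run_cohort  # deferred: markov consumes PreparedModel

    space = space or StateSpace.default()
    if window is None:
        window = int(bundle.config.get("mortality_calibration", {}).get("window", 10))
    prepared = _prepare_with_k(bundle, k, space)
    policy = EscalationPolicy(threshold=math.inf)
    totals = {"control": [0.0, 0.0], "shifted": [0.0, 0.0]}
    for sub in bundle.subgroups:
        for label, shift in (("control", 0.0), ("shifted", delta_ldl)):
            trace = run_cohort(sub, policy, prepared, horizon=window, ldl_shift=shift)
            totals[label][0] += sub.weight * trace.deaths.sum()
            totals[label][1] += sub.weight * trace.person_years.sum()
    rate_control = totals["control"][0] / totals["control"][1]
    rate_shifted = totals["shifted"][0] / totals["shifted"][1]
    return rate_shifted / rate_control


def prepare_model(
    bundle: InputBundle,
    k: float | None = None,
    space: StateSpace | None = None,
) -> PreparedModel:
    """Prepare a calibrated model, calibrating ``k`` if not supplied.

    The CVD-mortality-only scenario applies its death effect without
    further calibration (``k = 1``): restricting the direct effect to
    the CVD share of deaths is itself the guard against double counting
    there.
    """
    space = space or StateSpace.default()
    if k is None:
        mode = bundle.config.get("mortality_mode", "all_cause")
        if mode == "cvd_only":
            k = 1.0
        else:
            target = bundle.relative_risks.rr_allcause_mortality.point
            cal = bundle.config.get("mortality_calibration", {})
            tol = float(cal.get("tolerance", 1e-4))
            window = int(cal.get("window", 10))
            k = calibrate_mortality_adjustment(
                lambda kk: mortality_rate_ratio(bundle, kk, window=window, space=space),
                target_rr=target,
                tolerance=tol,
            )
    return _prepare_with_k(bundle, k, space)
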