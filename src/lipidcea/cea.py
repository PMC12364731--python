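"""Threshold sweep, fully incremental analysis and probabilistic
sensitivity analysis.

The decision problem compares escalation thresholds on a 0.1 mmol/L
grid.  For each threshold the population-weighted lifetime discounted
costs and QALYs are computed; options are then ranked by effectiveness,
strictly and extendedly dominated options removed, and the optimal
option at a willingness-to-pay ``lambda`` identified on the efficiency
frontier (equivalently, by maximising net monetary benefit
``lambda * QALY - cost``).

The PSA re-draws uncertain parameters per simulation -- gamma for rates
and costs, beta for utility multipliers, lognormal for relative risks
and treatment effects, matched to the printed means and 95% intervals
-- and reports the probability each threshold is optimal at each
``lambda`` (the cost-effectiveness acceptability estimator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .economics import UtilityMultiplier
from .inputs import InputBundle
from .markov import run_cohort
from .model import PreparedModel, prepare_model
from .pathway import (
    EZETIMIBE,
    INCLISIRAN,
    LDL,
    PCSK9,
    EscalationPolicy,
)
from .risk import Estimate, RelativeRiskSet
from .states import EVENTS, TIA, ConfigurationError


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def threshold_grid(lower: float, upper: float, step: float) -> np.ndarray:
    if step <= 0 or upper < lower:
        raise ConfigurationError(f"invalid grid: ({lower}, {upper}, {step})")
    n = int(round((upper - lower) / step))
    return np.round(lower + step * np.arange(n + 1), 10)


def default_grid(bundle: InputBundle, measure: str | None = None) -> np.ndarray:
    measure = measure or bundle.config.get("measure", LDL)
    lo, hi, step = bundle.config["grid"][measure]
    return threshold_grid(lo, hi, step)


def default_policy(bundle: InputBundle, threshold: float = math.inf) -> EscalationPolicy:
    """Escalation policy implied by the bundle's configuration."""
    cfg = bundle.config
    choice = cfg.get("injectable_choice", "inclisiran_only")
    if choice == "inclisiran_only":
        sequence: tuple[str, ...] = (EZETIMIBE, INCLISIRAN)
    elif choice == "pcsk9_only":
        sequence = (EZETIMIBE, PCSK9)
    elif choice == "pcsk9_above_3.5":
        sequence = (EZETIMIBE, INCLISIRAN, PCSK9)
    else:
        raise ConfigurationError(f"unknown injectable_choice: {choice!r}")
    adh_cfg = cfg.get("adherence", {})
    inj = float(adh_cfg.get("injectable", 1.0))
    adherence = {EZETIMIBE: float(adh_cfg.get(EZETIMIBE, 1.0)), INCLISIRAN: inj, PCSK9: inj}
    return EscalationPolicy(
        threshold=threshold,
        measure=cfg.get("measure", LDL),
        sequence=sequence,
        injectable_choice=choice,
        adherence=adherence,
        allow_double_escalation=bool(cfg.get("allow_double_escalation", True)),
        statin_background=cfg.get("population", "any_statin") != "statin_intolerant",
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Population-weighted outcomes of one escalation threshold."""

    threshold: float
    cost: float  # mean discounted GBP per person
    qaly: float  # mean discounted QALYs per person
    frac_ezetimibe_1y: float
    frac_injectable_1y: float
    mean_ldl_1y: float

    def __post_init__(self) -> None:
        if self.qaly < 0:
            raise ConfigurationError(f"QALYs must be non-negative: {self.qaly}")


def evaluate_threshold(
    bundle: InputBundle,
    prepared: PreparedModel,
    policy: EscalationPolicy,
) -> ThresholdResult:
    cost = qaly = 0.0
    alive1 = ez1 = inj1 = ldl1 = 0.0
    for sub in bundle.subgroups:
        trace = run_cohort(sub, policy, prepared)
        cost += sub.weight * trace.disc_cost
        qaly += sub.weight * trace.disc_qaly
        c1 = min(1, trace.n_cycles - 1) if trace.n_cycles else 0
        if trace.n_cycles:
            a = sub.weight * trace.person_years[c1]
            alive1 += a
            ez1 += a * trace.coverage_at(EZETIMIBE, c1)
            inj1 += a * (
                trace.coverage_at(INCLISIRAN, c1) + trace.coverage_at(PCSK9, c1)
            )
            ldl1 += a * trace.mean_ldl_at(c1)
    if alive1 <= 0:
        raise ConfigurationError("no surviving population at one year")
    return ThresholdResult(
        threshold=policy.threshold,
        cost=cost,
        qaly=qaly,
        frac_ezetimibe_1y=ez1 / alive1,
        frac_injectable_1y=inj1 / alive1,
        mean_ldl_1y=ldl1 / alive1,
    )


def sweep_thresholds(
    bundle: InputBundle,
    policy_template: EscalationPolicy | None = None,
    grid: Sequence[float] | None = None,
    prepared: PreparedModel | None = None,
) -> list[ThresholdResult]:
    """One deterministic, population-weighted result per grid threshold."""
    if grid is None:
        grid = default_grid(bundle)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("threshold grid is empty")
    if policy_template is None:
        policy_template = default_policy(bundle)
    if prepared is None:
        prepared = prepare_model(bundle)
    return [
        evaluate_threshold(bundle, prepared, policy_template.with_threshold(float(th)))
        for th in grid
    ]


# ---------------------------------------------------------------------------
# Fully incremental analysis
# ---------------------------------------------------------------------------

_QTOL = 1e-12


def _nmb_key(r: ThresholdResult, lam: float) -> tuple[float, float, float]:
    """Sort key for NMB maximisation; ties to lower cost, then lower threshold."""
    return (lam * r.qaly - r.cost, -r.cost, -r.threshold)


@dataclass
class IncrementalAnalysis:
    options: list[ThresholdResult]  # ordered by effectiveness (ascending QALYs)
    frontier: list[ThresholdResult]  # efficient options, ascending QALYs
    dominated: dict[float, str]  # threshold -> "dominated" | "extended"
    icers: dict[float, float]  # frontier threshold -> ICER vs previous frontier option
    lam: float
    optimal: ThresholdResult


def incremental_analysis(
    results: Sequence[ThresholdResult], lam: float
) -> IncrementalAnalysis:
    """Dominance pruning, frontier ICERs, and the optimum at ``lam``."""
    if len(results) < 2:
        raise ConfigurationError("incremental analysis needs at least two options")
    options = sorted(results, key=lambda r: (r.qaly, -r.cost, -r.threshold))
    dominated: dict[float, str] = {}

    # Strict dominance (same or more QALYs for same or lower cost).
    frontier: list[ThresholdResult] = []
    best_cost = math.inf
    for r in sorted(options, key=lambda r: (-r.qaly, r.cost, r.threshold)):
        if r.cost < best_cost - 1e-12:
            frontier.append(r)
            best_cost = r.cost
        else:
            dominated[r.threshold] = "dominated"
    frontier.reverse()  # ascending QALYs

    # Extended dominance: ICERs along the frontier must increase.
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_mid = (mid.cost - lo.cost) / max(mid.qaly - lo.qaly, _QTOL)
            icer_hi = (hi.cost - mid.cost) / max(hi.qaly - mid.qaly, _QTOL)
            if icer_mid > icer_hi + 1e-12:
                dominated[mid.threshold] = "extended"
                del frontier[i]
                changed = True
                break

    icers: dict[float, float] = {}
    for prev, cur in zip(frontier, frontier[1:]):
        icers[cur.threshold] = (cur.cost - prev.cost) / max(cur.qaly - prev.qaly, _QTOL)

    optimal = frontier[0]
    for cur in frontier[1:]:
        if icers[cur.threshold] <= lam:
            optimal = cur
    return IncrementalAnalysis(
        options=options,
        frontier=frontier,
        dominated=dominated,
        icers=icers,
        lam=lam,
        optimal=optimal,
    )


def nmb_optimal(results: Sequence[ThresholdResult], lam: float) -> ThresholdResult:
    """Brute-force net-monetary-benefit maximiser (cross-check for the frontier)."""
    return max(results, key=lambda r: _nmb_key(r, lam))


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsaParameter:
    """One uncertain input with its sampling distribution.

    ``dist`` is ``lognormal`` (both 95% quantiles matched exactly on the
    log scale, so draws reproduce the printed interval even when it is
    asymmetric around the point estimate), ``beta`` (moment-matched to
    mean and SD) or ``gamma`` (moment-matched; SD from the 95%
    half-width when not given directly).
    """

    name: str
    dist: str
    mean: float
    lower: float | None = None
    upper: float | None = None
    sd: float | None = None

    def _sigma_log(self) -> float:
        if self.lower is None or self.upper is None:
            return 0.0
        if not 0 < self.lower <= self.mean <= self.upper:
            raise ConfigurationError(
                f"parameter {self.name}: interval ({self.lower}, {self.upper}) "
                f"inconsistent with lognormal support and mean {self.mean}"
            )
        return (math.log(self.upper) - math.log(self.lower)) / (2 * 1.959963984540054)

    def _sd(self) -> float:
        if self.sd is not None:
            return self.sd
        if self.lower is None or self.upper is None:
            return 0.0
        return (self.upper - self.lower) / (2 * 1.959963984540054)

    def draw(self, rng: np.random.Generator) -> float:
        if self.dist == "lognormal":
            sigma = self._sigma_log()
            if sigma == 0.0:
                return self.mean
            mu = 0.5 * (math.log(self.lower) + math.log(self.upper))
            return float(np.exp(mu + sigma * rng.standard_normal()))
        if self.dist == "beta":
            s = self._sd()
            if s == 0.0:
                return self.mean
            m = self.mean
            if not 0 < m < 1 or s * s >= m * (1 - m):
                raise ConfigurationError(
                    f"parameter {self.name}: mean {m} / sd {s} inconsistent with beta support"
                )
            nu = m * (1 - m) / (s * s) - 1.0
            return float(rng.beta(m * nu, (1 - m) * nu))
        if self.dist == "gamma":
            s = self._sd()
            if s == 0.0 or self.mean == 0.0:
                return self.mean
            if self.mean < 0:
                raise ConfigurationError(
                    f"parameter {self.name}: gamma mean must be non-negative"
                )
            shape = (self.mean / s) ** 2
            scale = s * s / self.mean
            return float(rng.gamma(shape, scale))
        raise ConfigurationError(f"parameter {self.name}: unknown distribution {self.dist!r}")


def build_psa_spec(bundle: InputBundle) -> list[PsaParameter]:
    """Uncertain-parameter registry for the base-case PSA."""
    cfg = bundle.config
    degenerate = bool(cfg.get("psa", {}).get("degenerate", False))
    rate_hw = float(cfg.get("psa", {}).get("rate_rel_halfwidth", 0.2))
    cost_hw = float(cfg.get("psa", {}).get("cost_rel_halfwidth", 0.2))
    if degenerate:
        rate_hw = cost_hw = 0.0
    params: list[PsaParameter] = []

    def interval(est: Estimate) -> tuple[float | None, float | None]:
        if degenerate or est.degenerate:
            return None, None
        return est.lower, est.upper

    rrset = bundle.relative_risks
    seen: dict[tuple, str] = {}
    for event in EVENTS + (TIA,):
        est = rrset.events[event]
        key = (est.point, est.lower, est.upper)
        if key in seen:
            continue
        seen[key] = event
        lo, hi = interval(est)
        params.append(PsaParameter(f"rr:{event}", "lognormal", est.point, lo, hi))
    lo, hi = interval(rrset.rr_allcause_mortality)
    params.append(
        PsaParameter("rr:allcause_mortality", "lognormal", rrset.rr_allcause_mortality.point, lo, hi)
    )

    measure = cfg.get("measure", LDL)
    for name, therapy in bundle.therapies.items():
        est = therapy.ldl_reduction if measure == LDL else therapy.nonhdl_reduction
        if est.point == 0.0:
            continue
        retained = Estimate(1 - est.point, 1 - (est.upper or est.point), 1 - (est.lower or est.point))
        lo, hi = interval(retained)
        params.append(PsaParameter(f"tx:{name}", "lognormal", retained.point, lo, hi))

    for event, mult in bundle.utilities.multipliers.items():
        sd = 0.0 if degenerate else mult.post_sd
        params.append(PsaParameter(f"umult_post:{event}", "beta", mult.post, sd=sd))
        if mult.acute is not None:
            sd = 0.0 if degenerate else mult.acute_sd
            params.append(PsaParameter(f"umult_acute:{event}", "beta", mult.acute, sd=sd))

    for _, row in bundle.event_rates.frame.iterrows():
        r = float(row["rate"])
        params.append(
            PsaParameter(
                f"rate:{row['event_type']}:{row['sex']}:{row['age_band']}",
                "gamma",
                r,
                sd=rate_hw * r / 1.959963984540054,
            )
        )
    for _, row in bundle.mortality.frame.iterrows():
        r = float(row["rate"])
        params.append(
            PsaParameter(
                f"mrate:{row['sex']}:{row['context']}:{row['age_band']}",
                "gamma",
                r,
                sd=rate_hw * r / 1.959963984540054,
            )
        )

    for event in EVENTS:
        params.append(
            PsaParameter(f"cscale_acute:{event}", "gamma", 1.0, sd=cost_hw / 1.959963984540054)
        )
        params.append(
            PsaParameter(f"cscale_post:{event}", "gamma", 1.0, sd=cost_hw / 1.959963984540054)
        )
    return params


def draw_psa_parameters(
    bundle: InputBundle,
    seed: int | Sequence[int],
    spec: Sequence[PsaParameter] | None = None,
) -> dict[str, float]:
    """One deterministic parameter realization for the given seed."""
    if spec is None:
        spec = build_psa_spec(bundle)
    rng = np.random.default_rng(seed)
    return {p.name: p.draw(rng) for p in spec}


def apply_psa_realization(bundle: InputBundle, realization: Mapping[str, float]) -> InputBundle:
    """New bundle with the drawn parameter values substituted."""
    new = bundle.copy()

    rrset = bundle.relative_risks
    events = {}
    for event in rrset.events:
        est = rrset.events[event]
        drawn = realization.get(f"rr:{event}")
        if drawn is None:  # shared estimate drawn once under another event's name
            for other, oest in rrset.events.items():
                if f"rr:{other}" in realization and (
                    oest.point,
                    oest.lower,
                    oest.upper,
                ) == (est.point, est.lower, est.upper):
                    drawn = realization[f"rr:{other}"]
                    break
        if drawn is None:
            drawn = est.point
        events[event] = Estimate(min(float(drawn), 1.0), None, None)
    rr_all = realization.get("rr:allcause_mortality", rrset.rr_allcause_mortality.point)
    new.relative_risks = RelativeRiskSet(
        events=events,
        rr_allcause_mortality=Estimate(min(float(rr_all), 1.0), None, None),
        rr_cvd_death=rrset.rr_cvd_death,
        mortality_adjustment=rrset.mortality_adjustment,
    )

    measure = bundle.config.get("measure", LDL)
    therapies = {}
    for name, therapy in bundle.therapies.items():
        drawn = realization.get(f"tx:{name}")
        if drawn is None:
            therapies[name] = therapy
            continue
        reduction = Estimate(min(max(1.0 - float(drawn), 0.0), 0.999), None, None)
        if measure == LDL:
            therapies[name] = dc_replace(therapy, ldl_reduction=reduction)
        else:
            therapies[name] = dc_replace(therapy, nonhdl_reduction=reduction)
    new.therapies = therapies

    mults = {}
    for event, mult in bundle.utilities.multipliers.items():
        post = realization.get(f"umult_post:{event}", mult.post)
        acute = realization.get(f"umult_acute:{event}", mult.acute)
        mults[event] = UtilityMultiplier(
            post=min(float(post), 1.0),
            acute=None if mult.acute is None else min(float(acute), 1.0),
            post_sd=mult.post_sd,
            acute_sd=mult.acute_sd,
        )
    new.utilities = bundle.utilities.with_multipliers(mults)

    frame = bundle.event_rates.frame.copy()
    keys = [
        f"rate:{e}:{s}:{b}"
        for e, s, b in zip(frame["event_type"], frame["sex"], frame["age_band"])
    ]
    frame["rate"] = [realization.get(k, r) for k, r in zip(keys, frame["rate"])]
    new.event_rates = type(bundle.event_rates)(frame)

    mframe = bundle.mortality.frame.copy()
    mkeys = [
        f"mrate:{s}:{c}:{b}"
        for s, c, b in zip(mframe["sex"], mframe["context"], mframe["age_band"])
    ]
    mframe["rate"] = [realization.get(k, r) for k, r in zip(mkeys, mframe["rate"])]
    new.mortality = type(bundle.mortality)(mframe, cvd_fraction=bundle.mortality.cvd_fraction)

    costs = bundle.costs
    acute_age = {
        event: {
            sex: tuple(c * realization.get(f"cscale_acute:{event}", 1.0) for c in row)
            for sex, row in table.items()
        }
        for event, table in costs.acute_age_costs.items()
    }
    flat = {
        e: c * realization.get(f"cscale_acute:{e}", 1.0)
        for e, c in costs.flat_acute_costs.items()
    }
    post = {
        e: c * realization.get(f"cscale_post:{e}", 1.0) for e, c in costs.post_costs.items()
    }
    new.costs = dc_replace(
        costs, acute_age_costs=acute_age, flat_acute_costs=flat, post_costs=post
    )
    return new


@dataclass
class PSAResult:
    n_sims: int
    seed: int
    thresholds: np.ndarray
    costs: np.ndarray  # (n_valid, n_thresholds)
    qalys: np.ndarray  # (n_valid, n_thresholds)
    prob_optimal: dict[float, np.ndarray]  # lambda -> probability per threshold
    n_rejected: int = 0

    @property
    def mean_cost(self) -> np.ndarray:
        return self.costs.mean(axis=0)

    @property
    def mean_qaly(self) -> np.ndarray:
        return self.qalys.mean(axis=0)


def run_psa(
    bundle: InputBundle,
    policy_template: EscalationPolicy | None = None,
    n_sims: int | None = None,
    lambdas: Sequence[float] = (20000.0,),
    seed: int = 0,
    grid: Sequence[float] | None = None,
    evaluator: Callable[[Mapping[str, float], np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
    compare_thresholds: Sequence[float] | None = None,
) -> PSAResult:
    """Monte-Carlo uncertainty analysis over the threshold grid.

    Each simulation re-draws every uncertain parameter, re-runs the
    sweep and records which threshold maximises net monetary benefit at
    each willingness-to-pay.  The mortality-calibration factor is held
    at its base-case value across simulations.  ``evaluator`` may
    replace the model run (e.g. a stub when only the draws matter); it
    receives the parameter realization and the threshold grid and
    returns per-threshold ``(costs, qalys)``.
    """
    if n_sims is None:
        n_sims = int(bundle.config.get("psa", {}).get("n_sims", 10000))
    if n_sims < 1:
        raise ConfigurationError(f"n_sims must be >= 1: {n_sims}")
    if grid is None:
        grid = default_grid(bundle)
    grid = np.asarray(grid, dtype=float)
    if policy_template is None:
        policy_template = default_policy(bundle)
    spec = build_psa_spec(bundle)

    base_k: float | None = None
    if evaluator is None:
        base_k = prepare_model(bundle).k

        def evaluator(
            realization: Mapping[str, float], thresholds: np.ndarray
        ) -> tuple[np.ndarray, np.ndarray]:
            b = apply_psa_realization(bundle, realization)
            prepared = prepare_model(b, k=base_k)
            res = [
                evaluate_threshold(b, prepared, policy_template.with_threshold(float(t)))
                for t in thresholds
            ]
            return (
                np.array([r.cost for r in res]),
                np.array([r.qaly for r in res]),
            )

    mask = (
        np.isin(grid, np.asarray(compare_thresholds, dtype=float))
        if compare_thresholds is not None
        else np.ones(grid.size, dtype=bool)
    )
    if compare_thresholds is not None and mask.sum() != len(compare_thresholds):
        raise ConfigurationError("compare_thresholds must be a subset of the grid")

    costs_rows, qaly_rows = [], []
    counts = {lam: np.zeros(grid.size) for lam in lambdas}
    n_rejected = 0
    for i in range(n_sims):
        realization = draw_psa_parameters(bundle, [seed, i], spec=spec)
        c, q = evaluator(realization, grid)
        c = np.asarray(c, dtype=float)
        q = np.asarray(q, dtype=float)
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(q))):
            n_rejected += 1
            continue
        costs_rows.append(c)
        qaly_rows.append(q)
        for lam in lambdas:
            nmb = lam * q - c
            nmb_sub = np.where(mask, nmb, -np.inf)
            # ties resolve to lower cost, then lower threshold
            order = np.lexsort((grid, c, -nmb_sub))
            counts[lam][order[0]] += 1.0
    n_valid = len(costs_rows)
    if n_valid == 0:
        raise ConfigurationError("all PSA simulations were rejected")
    prob = {lam: counts[lam] / n_valid for lam in lambdas}
    return PSAResult(
        n_sims=n_sims,
        seed=seed,
        thresholds=grid,
        costs=np.vstack(costs_rows),
        qalys=np.vstack(qaly_rows),
        prob_optimal=prob,
        n_rejected=n_rejected,
    )
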