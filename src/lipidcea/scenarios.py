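"""Scenario registry and runners.

Each scenario is a named set of configuration overrides on the base
case: willingness-to-pay, relative-risk mode, mortality effect mode,
injectable choice, population, event inclusion, utility set, adherence,
price variant, escalation resourcing, prescription fee and drift mode.
Scenarios never mutate the base configuration; re-running the base case
after any scenario reproduces it exactly.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cea import (
    IncrementalAnalysis,
    ThresholdResult,
    default_grid,
    default_policy,
    incremental_analysis,
    sweep_thresholds,
)
from .inputs import InputBundle, default_config, synthesize_inputs
from .states import ConfigurationError


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    description: str = ""
    overrides: Mapping = field(default_factory=dict)


SCENARIOS: dict[str, ScenarioSpec] = {
    s.id: s
    for s in [
        ScenarioSpec("base", "Base-case assumptions"),
        ScenarioSpec("wtp_15000", "Willingness-to-pay £15,000/QALY", {"wtp": 15000.0}),
        ScenarioSpec("wtp_30000", "Willingness-to-pay £30,000/QALY", {"wtp": 30000.0}),
        ScenarioSpec(
            "single_mace_rr",
            "Single MACE treatment effect for all CVD outcomes",
            {"rr_mode": "single_mace"},
        ),
        ScenarioSpec(
            "cvd_mortality",
            "LDL-C reduction affects CVD mortality only",
            {"mortality_mode": "cvd_only"},
        ),
        ScenarioSpec("pcsk9_only", "PCSK9 inhibitors as the injectable", {"injectable_choice": "pcsk9_only"}),
        ScenarioSpec(
            "pcsk9_above_3.5",
            "PCSK9 inhibitors added above 3.5 mmol/L",
            {"injectable_choice": "pcsk9_above_3.5"},
        ),
        ScenarioSpec(
            "atorvastatin_80",
            "Population on high-intensity atorvastatin 80 mg",
            {"population": "atorvastatin_80"},
        ),
        ScenarioSpec(
            "statin_intolerant",
            "Mixed population including statin-intolerant people",
            {"population": "plus_statin_intolerant"},
        ),
        ScenarioSpec(
            "exclude_unstable_angina",
            "Exclude unstable angina admissions",
            {"include_unstable_angina": False},
        ),
        ScenarioSpec("exclude_tia", "Exclude TIA costs", {"include_tia": False}),
        ScenarioSpec(
            "utilities_previous_model",
            "Utility multipliers from the previous statins model",
            {"utility_set": "previous_model"},
        ),
        ScenarioSpec(
            "utilities_inclisiran_ta",
            "Utility multipliers from the inclisiran appraisal",
            {"utility_set": "inclisiran_ta"},
        ),
        ScenarioSpec("ezetimibe_adherence_80", "80% adherence to ezetimibe", {"adherence": {"ezetimibe": 0.8}}),
        ScenarioSpec("ezetimibe_adherence_50", "50% adherence to ezetimibe", {"adherence": {"ezetimibe": 0.5}}),
        ScenarioSpec("ezetimibe_adherence_0", "0% adherence to ezetimibe", {"adherence": {"ezetimibe": 0.0}}),
        ScenarioSpec("injectable_adherence_80", "80% adherence to injectables", {"adherence": {"injectable": 0.8}}),
        ScenarioSpec("injectable_adherence_50", "50% adherence to injectables", {"adherence": {"injectable": 0.5}}),
        ScenarioSpec("injectable_adherence_0", "0% adherence to injectables", {"adherence": {"injectable": 0.0}}),
        ScenarioSpec(
            "inclisiran_volume_price",
            "Volume-discounted inclisiran price (placeholder)",
            {"inclisiran_price_variant": "volume_discount"},
        ),
        ScenarioSpec(
            "higher_escalation_cost",
            "Two GP attendances and one nurse attendance per inclisiran escalation",
            {"escalation_resource_variant": "two_gp_one_nurse"},
        ),
        ScenarioSpec(
            "ezetimibe_prescription_fee",
            "Ezetimibe cost includes the pharmacist prescription fee",
            {"include_ezetimibe_fee": True},
        ),
        ScenarioSpec(
            "drift_three_cycle",
            "LDL-C regresses to the mean over three cycles",
            {"drift": {"mode": "three_cycle_regression"}},
        ),
        ScenarioSpec(
            "alt_event_costs",
            "Alternative CVD event cost table (synthetic)",
            {"event_cost_scale": 0.9},
        ),
    ]
}


def _validate_overrides(overrides: Mapping, template: Mapping, path: str = "") -> None:
    for key, value in overrides.items():
        if key not in template:
            raise ConfigurationError(f"unknown scenario override key: {path}{key}")
        if isinstance(value, Mapping) and isinstance(template[key], Mapping):
            _validate_overrides(value, template[key], path=f"{path}{key}.")


def apply_scenario(config: Mapping | None, scenario: ScenarioSpec) -> dict:
    """Base config with the scenario's overrides applied (no mutation)."""
    base = _merge(default_config(), dict(config) if config else {})
    _validate_overrides(scenario.overrides, default_config())
    return _merge(base, scenario.overrides)


def _merge(base: dict, overrides: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _intolerant_config(cfg: dict) -> dict:
    """Configuration for the statin-intolerant sub-population.

    No statin background and a higher untreated LDL-C distribution; the
    escalation sequence itself is unchanged (ezetimibe, then the
    injectable).
    """
    icfg = copy.deepcopy(cfg)
    icfg["population"] = "statin_intolerant"
    uplift = float(cfg.get("intolerant", {}).get("ldl_uplift", 1.3))
    for sex in icfg["ldl_distribution"]:
        icfg["ldl_distribution"][sex]["location"] += math.log(uplift)
    return icfg


def bundle_for_config(cfg: dict, seed: int) -> InputBundle:
    cfg = copy.deepcopy(cfg)
    if cfg.get("population") == "atorvastatin_80":
        alt = cfg["atorvastatin80"]
        cfg["ldl_distribution"] = copy.deepcopy(alt["ldl_distribution"])
        cfg["entry_ages"] = copy.deepcopy(alt["entry_ages"])
    return synthesize_inputs(cfg, seed=seed)


@dataclass
class ScenarioReport:
    scenario_id: str
    wtp: float
    optimal_threshold: float
    mean_qalys: float
    pct_ezetimibe: float
    pct_injectable: float
    results: list[ThresholdResult]
    analysis: IncrementalAnalysis


def run_statin_intolerant_mix(
    base_results: Sequence[ThresholdResult],
    intolerant_results: Sequence[ThresholdResult],
    mix_weight: float,
) -> list[ThresholdResult]:
    """Population-weighted average of two sweeps on the same grid.

    ``mix_weight`` is the statin-intolerant fraction of the combined
    population.
    """
    if not 0.0 <= mix_weight <= 1.0:
        raise ConfigurationError(f"mix weight must be in [0, 1]: {mix_weight}")
    base_grid = [r.threshold for r in base_results]
    intol_grid = [r.threshold for r in intolerant_results]
    if base_grid != intol_grid:
        raise ConfigurationError("threshold grids of the two populations do not match")
    w = mix_weight
    out = []
    for b, i in zip(base_results, intolerant_results):
        out.append(
            ThresholdResult(
                threshold=b.threshold,
                cost=(1 - w) * b.cost + w * i.cost,
                qaly=(1 - w) * b.qaly + w * i.qaly,
                frac_ezetimibe_1y=(1 - w) * b.frac_ezetimibe_1y + w * i.frac_ezetimibe_1y,
                frac_injectable_1y=(1 - w) * b.frac_injectable_1y + w * i.frac_injectable_1y,
                mean_ldl_1y=(1 - w) * b.mean_ldl_1y + w * i.mean_ldl_1y,
            )
        )
    return out


def run_scenario(
    base_config: Mapping | None,
    scenario: ScenarioSpec | str,
    seed: int = 0,
    grid: Sequence[float] | None = None,
) -> ScenarioReport:
    """Run one registered scenario end to end (sweep + incremental analysis)."""
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ConfigurationError(f"unknown scenario id: {scenario!r}") from None
    cfg = apply_scenario(base_config, scenario)
    wtp = float(cfg.get("wtp", 20000.0))

    if cfg.get("population") == "plus_statin_intolerant":
        base_cfg = copy.deepcopy(cfg)
        base_cfg["population"] = "any_statin"
        bundle = bundle_for_config(base_cfg, seed)
        grid_arr = np.asarray(grid, dtype=float) if grid is not None else default_grid(bundle)
        base_results = sweep_thresholds(bundle, grid=grid_arr)
        intol_bundle = bundle_for_config(_intolerant_config(base_cfg), seed)
        intol_results = sweep_thresholds(
            intol_bundle, policy_template=default_policy(intol_bundle), grid=grid_arr
        )
        mix_w = float(cfg.get("intolerant", {}).get("mix_weight", 0.10))
        results = run_statin_intolerant_mix(base_results, intol_results, mix_w)
    else:
        bundle = bundle_for_config(cfg, seed)
        grid_arr = np.asarray(grid, dtype=float) if grid is not None else default_grid(bundle)
        results = sweep_thresholds(bundle, grid=grid_arr)

    analysis = incremental_analysis(results, wtp)
    opt = analysis.optimal
    return ScenarioReport(
        scenario_id=scenario.id,
        wtp=wtp,
        optimal_threshold=opt.threshold,
        mean_qalys=opt.qaly,
        pct_ezetimibe=opt.frac_ezetimibe_1y,
        pct_injectable=opt.frac_injectable_1y,
        results=results,
        analysis=analysis,
    )
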