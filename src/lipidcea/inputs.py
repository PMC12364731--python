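"""Input bundle: data model, synthetic generator and (de)serialisation.

The model is driven by a structured bundle of tables that, in the
original analysis, were estimated from linked English primary-care,
hospital-admission and death-registration records (CPRD Aurum - HES APC
- ONS).  Those extracts are confidential, so this module generates
synthetic inputs that reproduce their *structural* features:

* right-skewed (truncated lognormal) baseline LDL-C distributions per
  sex, divided into equal-probability subgroups ("super patients");
* annual CVD admission rates by event type, sex and age band that rise
  with age;
* all-cause mortality by sex, age band and context, with the 12 months
  after an acute admission carrying higher mortality than the chronic
  post-event phase;
* a slow upward drift of LDL-C over time (or a regression-to-the-mean
  alternative over the first three cycles);
* utility and cost tables (published values where available; synthetic
  placeholders, flagged as such, where the source values are
  confidential or unpublished).

Everything is a pure function of ``(config, seed)`` so any run can be
regenerated exactly.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .bands import AGE_BAND_EDGES, AGE_BAND_LABELS, N_BANDS, band_index
from .economics import (
    HSE2017_MULTIPLIERS,
    CostInputs,
    UtilityInputs,
    UtilityMultiplier,
    tablet_annual_cost,
)
from .pathway import EZETIMIBE, PCSK9, Therapy, default_therapies
from .risk import DEFAULT_EVENT_RR, RelativeRiskSet
from .states import EVENTS, TIA, ConfigurationError, post_state

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)


class InvalidSpecError(ConfigurationError):
    """Raised for invalid distribution or banding specifications."""


# ---------------------------------------------------------------------------
# Distribution of baseline LDL-C
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDLDistributionSpec:
    """Truncated lognormal baseline LDL-C distribution for one sex.

    ``location`` is the log-scale location (ln of the untruncated
    median, mmol/L) and ``scale`` the log-scale standard deviation.
    """

    sex: str
    location: float
    scale: float
    lower_trunc: float = 0.3
    upper_trunc: float = 6.0
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InvalidSpecError(f"scale must be positive: {self.scale}")
        if not 0.0 <= self.lower_trunc < self.upper_trunc:
            raise InvalidSpecError(
                f"require 0 <= lower_trunc < upper_trunc: "
                f"({self.lower_trunc}, {self.upper_trunc})"
            )
        if self.family != "lognormal":
            raise InvalidSpecError(f"unsupported family: {self.family!r}")

    # -- truncated lognormal helpers -----------------------------------
    def _z(self, x: float) -> float:
        return (math.log(x) - self.location) / self.scale

    def cdf_untruncated(self, x: float) -> float:
        if x <= 0:
            return 0.0
        return float(norm.cdf(self._z(x)))

    def ppf_untruncated(self, q: float) -> float:
        return float(math.exp(self.location + self.scale * norm.ppf(q)))

    def _partial_expectation(self, a: float, b: float) -> float:
        """E[X ; a < X <= b] for the untruncated lognormal."""
        mean = math.exp(self.location + 0.5 * self.scale**2)
        za = self._z(a) - self.scale if a > 0 else -math.inf
        zb = self._z(b) - self.scale
        return mean * float(norm.cdf(zb) - norm.cdf(za))

    def band_edges(self, n_bands: int) -> np.ndarray:
        """Equal-probability quantile edges of the truncated distribution."""
        if n_bands < 1:
            raise InvalidSpecError(f"n_bands must be >= 1: {n_bands}")
        q_lo = self.cdf_untruncated(self.lower_trunc)
        q_hi = self.cdf_untruncated(self.upper_trunc)
        if q_hi - q_lo <= 0:
            raise InvalidSpecError("truncation interval has no probability mass")
        qs = q_lo + (q_hi - q_lo) * np.linspace(0.0, 1.0, n_bands + 1)
        edges = np.array([self.ppf_untruncated(q) for q in qs])
        edges[0], edges[-1] = self.lower_trunc, self.upper_trunc
        return edges

    def band_means(self, n_bands: int) -> np.ndarray:
        """Conditional mean LDL-C within each equal-probability band."""
        edges = self.band_edges(n_bands)
        q_lo = self.cdf_untruncated(self.lower_trunc)
        q_hi = self.cdf_untruncated(self.upper_trunc)
        band_prob = (q_hi - q_lo) / n_bands
        if band_prob <= 1e-12:
            raise InvalidSpecError("bands carry no probability mass")
        means = np.empty(n_bands)
        for i in range(n_bands):
            means[i] = self._partial_expectation(edges[i], edges[i + 1]) / band_prob
        return means

    def mean(self) -> float:
        """Mean of the truncated distribution."""
        q_lo = self.cdf_untruncated(self.lower_trunc)
        q_hi = self.cdf_untruncated(self.upper_trunc)
        return self._partial_expectation(self.lower_trunc, self.upper_trunc) / (q_hi - q_lo)


@dataclass(frozen=True)
class Subgroup:
    """One 'super patient' stratum: sex, entry age and baseline LDL-C."""

    id: int
    sex: str
    entry_age: float
    baseline_ldl: float
    weight: float

    def __post_init__(self) -> None:
        if self.baseline_ldl <= 0:
            raise InvalidSpecError(f"baseline_ldl must be positive: {self.baseline_ldl}")
        if not 18.0 <= self.entry_age <= 100.0:
            raise InvalidSpecError(f"entry_age must be in [18, 100]: {self.entry_age}")
        if self.weight < 0:
            raise InvalidSpecError(f"weight must be >= 0: {self.weight}")


def build_subgroups(
    specs: Mapping[str, LDLDistributionSpec] | LDLDistributionSpec,
    n_per_sex: int,
    sex_shares: Mapping[str, float],
    entry_ages: Mapping[str, float] | None = None,
) -> list[Subgroup]:
    """Divide each sex's LDL-C curve into equal-probability subgroups.

    Each subgroup's ``baseline_ldl`` is the conditional mean within its
    quantile band, which preserves the population mean LDL-C exactly;
    its weight is ``sex_share / n_per_sex``.
    """
    if n_per_sex < 1:
        raise InvalidSpecError(f"n_per_sex must be >= 1: {n_per_sex}")
    if isinstance(specs, LDLDistributionSpec):
        specs = {specs.sex: specs}
    total_share = math.fsum(sex_shares.values())
    if abs(total_share - 1.0) > 1e-9:
        raise InvalidSpecError(f"sex shares must sum to 1 (got {total_share})")
    entry_ages = entry_ages or {MALE: 65.0, FEMALE: 70.0}
    subgroups: list[Subgroup] = []
    next_id = 0
    for sex, share in sex_shares.items():
        spec = specs[sex]
        means = spec.band_means(n_per_sex)
        for m in means:
            subgroups.append(
                Subgroup(
                    id=next_id,
                    sex=sex,
                    entry_age=float(entry_ages[sex]),
                    baseline_ldl=float(m),
                    weight=share / n_per_sex,
                )
            )
            next_id += 1
    return subgroups


# ---------------------------------------------------------------------------
# Rate and mortality tables
# ---------------------------------------------------------------------------

RATE_EVENTS = EVENTS + (TIA,)


class EventRateTable:
    """Annual CVD admission rates (events per person-year) by event, sex, age band."""

    COLUMNS = ("event_type", "sex", "age_band", "rate")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        if (frame["rate"] < 0).any():
            raise ConfigurationError("event rates must be non-negative")
        frame = frame.sort_values(["event_type", "sex", "age_band"], key=self._band_key)
        frame = frame.reset_index(drop=True)
        for (event, sex), grp in frame.groupby(["event_type", "sex"]):
            bands = tuple(grp["age_band"])
            if sorted(bands) != sorted(AGE_BAND_LABELS):
                raise ConfigurationError(
                    f"age bands for ({event}, {sex}) do not partition the age range"
                )
        self.frame = frame
        self._arrays: dict[tuple[str, str], np.ndarray] = {}
        for (event, sex), grp in frame.groupby(["event_type", "sex"]):
            ordered = grp.set_index("age_band").loc[list(AGE_BAND_LABELS), "rate"]
            self._arrays[(event, sex)] = ordered.to_numpy(dtype=float)

    @staticmethod
    def _band_key(col: pd.Series) -> pd.Series:
        if col.name == "age_band":
            order = {b: i for i, b in enumerate(AGE_BAND_LABELS)}
            return col.map(order)
        return col

    @property
    def events(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["event_type"].unique()))

    def rate(self, event: str, sex: str, age: float) -> float:
        return float(self._arrays[(event, sex)][band_index(age)])

    def array(self, event: str, sex: str) -> np.ndarray:
        return self._arrays[(event, sex)]

    def scaled(self, factors: Mapping[tuple[str, str, str], float]) -> "EventRateTable":
        """New table with rates multiplied per (event, sex, band) cell."""
        frame = self.frame.copy()
        keys = list(zip(frame["event_type"], frame["sex"], frame["age_band"]))
        frame["rate"] = [r * factors.get(k, 1.0) for k, r in zip(keys, frame["rate"])]
        return EventRateTable(frame)

    def zeroed(self, events: Sequence[str]) -> "EventRateTable":
        frame = self.frame.copy()
        frame.loc[frame["event_type"].isin(list(events)), "rate"] = 0.0
        return EventRateTable(frame)

    def equals(self, other: "EventRateTable") -> bool:
        return self.frame.equals(other.frame)


class MortalityTable:
    """Annual all-cause death rates by sex, age band and context.

    ``context`` is either ``"post"`` (no acute admission in the last 12
    months) or ``"acute:<event>"`` (the 12 months after an admission of
    that type).  ``cvd_fraction`` is the share of deaths attributed to
    CVD, used for vascular-death costing and the CVD-mortality scenario.
    """

    COLUMNS = ("sex", "age_band", "context", "rate")

    def __init__(self, frame: pd.DataFrame, cvd_fraction: float = 0.5):
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        if (frame["rate"] < 0).any():
            raise ConfigurationError("mortality rates must be non-negative")
        if not 0.0 <= cvd_fraction <= 1.0:
            raise ConfigurationError(f"cvd_fraction must be in [0, 1]: {cvd_fraction}")
        order = {b: i for i, b in enumerate(AGE_BAND_LABELS)}
        frame = frame.sort_values(
            ["sex", "context", "age_band"],
            key=lambda c: c.map(order) if c.name == "age_band" else c,
        ).reset_index(drop=True)
        self.frame = frame
        self.cvd_fraction = float(cvd_fraction)
        self._arrays: dict[tuple[str, str], np.ndarray] = {}
        for (sex, context), grp in frame.groupby(["sex", "context"]):
            ordered = grp.set_index("age_band").loc[list(AGE_BAND_LABELS), "rate"]
            self._arrays[(sex, context)] = ordered.to_numpy(dtype=float)

    def rate(self, sex: str, age: float, context: str) -> float:
        return float(self._arrays[(sex, context)][band_index(age)])

    def array(self, sex: str, context: str) -> np.ndarray:
        return self._arrays[(sex, context)]

    def contexts(self, sex: str) -> tuple[str, ...]:
        return tuple(c for s, c in self._arrays if s == sex)

    def equals(self, other: "MortalityTable") -> bool:
        return self.frame.equals(other.frame) and self.cvd_fraction == other.cvd_fraction


# ---------------------------------------------------------------------------
# LDL-C drift over time
# ---------------------------------------------------------------------------

CONSTANT_BY_SEX = "constant_by_sex"
THREE_CYCLE_REGRESSION = "three_cycle_regression"


@dataclass(frozen=True)
class DriftModel:
    """How untreated LDL-C changes from one cycle to the next.

    ``constant_by_sex`` adds a sex-specific increment every cycle (the
    base case).  ``three_cycle_regression`` applies a covariate model --
    intercept, initial LDL-C, age, sex and interactions -- for the first
    ``regression_horizon`` cycles and then holds LDL-C constant,
    emulating regression to the mean: subgroups below the population
    mean drift up, those above drift down.
    """

    mode: str = CONSTANT_BY_SEX
    constant_rate: Mapping[str, float] = field(
        default_factory=lambda: {MALE: 0.02, FEMALE: 0.025}
    )
    regression_coeffs: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 0.16,
            "initial_ldl": -0.08,
            "age": 0.0,
            "female": 0.01,
            "initial_ldl_x_age": 0.0,
            "initial_ldl_x_female": 0.0,
        }
    )
    regression_horizon: int = 3
    ldl_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in (CONSTANT_BY_SEX, THREE_CYCLE_REGRESSION):
            raise ConfigurationError(f"unknown drift mode: {self.mode!r}")
        if self.regression_horizon < 1:
            raise ConfigurationError(
                f"regression_horizon must be >= 1: {self.regression_horizon}"
            )
        if self.ldl_floor <= 0:
            raise ConfigurationError(f"ldl_floor must be positive: {self.ldl_floor}")


def apply_drift(ldl: float, subgroup: Subgroup, cycle: int, drift: DriftModel) -> float:
    """Untreated LDL-C at the start of ``cycle`` given last cycle's level."""
    if ldl <= 0:
        raise ConfigurationError(f"ldl must be positive: {ldl}")
    if cycle < 1:
        raise ConfigurationError(f"cycle must be >= 1: {cycle}")
    if drift.mode == CONSTANT_BY_SEX:
        new = ldl + float(drift.constant_rate[subgroup.sex])
    else:
        if cycle <= drift.regression_horizon:
            c = drift.regression_coeffs
            female = 1.0 if subgroup.sex == FEMALE else 0.0
            delta = (
                c.get("intercept", 0.0)
                + c.get("initial_ldl", 0.0) * subgroup.baseline_ldl
                + c.get("age", 0.0) * subgroup.entry_age
                + c.get("female", 0.0) * female
                + c.get("initial_ldl_x_age", 0.0) * subgroup.baseline_ldl * subgroup.entry_age
                + c.get("initial_ldl_x_female", 0.0) * subgroup.baseline_ldl * female
            )
            new = ldl + delta
        else:
            new = ldl
    return max(new, drift.ldl_floor)


# ---------------------------------------------------------------------------
# Baseline state distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineStateDistribution:
    """Starting occupancy over post-event states (cycle 0)."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        valid = {post_state(e) for e in EVENTS}
        for name in self.fractions:
            if name not in valid:
                raise ConfigurationError(
                    f"baseline occupancy allowed only in post-event states, got {name!r}"
                )
        total = math.fsum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(f"baseline state fractions must sum to 1: {total}")

    def fraction(self, state_name: str) -> float:
        return float(self.fractions.get(state_name, 0.0))


# ---------------------------------------------------------------------------
# The bundle
# ---------------------------------------------------------------------------


@dataclass
class InputBundle:
    """Everything the model needs for one analysis."""

    ldl_specs: dict[str, LDLDistributionSpec]
    subgroups: list[Subgroup]
    event_rates: EventRateTable
    mortality: MortalityTable
    drift: DriftModel
    baseline_states: BaselineStateDistribution
    relative_risks: RelativeRiskSet
    therapies: dict[str, Therapy]
    utilities: UtilityInputs
    costs: CostInputs
    config: dict

    def subgroups_of_sex(self, sex: str) -> list[Subgroup]:
        return [s for s in self.subgroups if s.sex == sex]

    def sex_weight(self, sex: str) -> float:
        return math.fsum(s.weight for s in self.subgroups if s.sex == sex)

    def copy(self) -> "InputBundle":
        return copy.deepcopy(self)

    def replace(self, **kwargs) -> "InputBundle":
        new = self.copy()
        for k, v in kwargs.items():
            setattr(new, k, v)
        return new


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

# Event-year admission costs by age band and sex (GBP): ischaemic stroke
# (including the payer share of social care), MI admissions and elective
# coronary revascularisation admissions.
ACUTE_AGE_COSTS: dict[str, dict[str, tuple[float, ...]]] = {
    "ischaemic_stroke": {
        MALE: (11610, 11636, 11952, 12325, 12545, 12913, 13234, 13573, 14216),
        FEMALE: (11799, 12076, 12438, 12774, 12830, 13109, 13467, 13873, 14632),
    },
    "mi": {
        MALE: (7706, 7869, 8150, 8464, 8856, 9244, 9740, 10321, 11278),
        FEMALE: (8067, 8314, 8474, 8854, 9053, 9308, 10123, 10447, 11378),
    },
    "elective_revasc": {
        MALE: (7667, 7780, 7902, 8027, 8174, 8409, 8619, 8928, 9392),
        FEMALE: (7854, 7955, 8079, 8204, 8340, 8509, 8738, 9064, 9676),
    },
}

# Flat event-year costs (GBP) for the remaining episode types.
FLAT_ACUTE_COSTS: dict[str, float] = {
    "unstable_angina": 8835.0,
    "pad": 2720.0,  # non-coronary revascularisation admissions
    TIA: 3196.0,
}

# Chronic (post-event) annual costs.  TIA and unstable angina values are
# published; the remainder are synthetic placeholders for unpublished
# regression-based estimates.
DEFAULT_POST_COSTS: dict[str, float] = {
    "ischaemic_stroke": 1800.0,
    "mi": 520.0,
    "unstable_angina": 428.0,
    "elective_revasc": 330.0,
    "pad": 640.0,
    TIA: 327.0,
}

# Synthetic alternative utility-multiplier sets for scenario analysis
# (the source sets are not published in usable form).
UTILITY_SETS: dict[str, dict[str, UtilityMultiplier]] = {
    "hse2017": dict(HSE2017_MULTIPLIERS),
    "previous_model": {
        "ischaemic_stroke": UtilityMultiplier(post=0.770, acute=0.710, post_sd=0.013, acute_sd=0.064),
        "mi": UtilityMultiplier(post=0.810, acute=0.800, post_sd=0.010, acute_sd=0.054),
        "unstable_angina": UtilityMultiplier(post=0.840, acute=0.650, post_sd=0.011, acute_sd=0.021),
        "elective_revasc": UtilityMultiplier(post=0.860, acute=None, post_sd=0.028),
        "pad": UtilityMultiplier(post=0.900, acute=None, post_sd=0.016),
    },
    "inclisiran_ta": {
        "ischaemic_stroke": UtilityMultiplier(post=0.856, acute=0.794, post_sd=0.013, acute_sd=0.064),
        "mi": UtilityMultiplier(post=0.889, acute=0.881, post_sd=0.010, acute_sd=0.054),
        "unstable_angina": UtilityMultiplier(post=0.922, acute=0.716, post_sd=0.011, acute_sd=0.021),
        "elective_revasc": UtilityMultiplier(post=0.933, acute=None, post_sd=0.028),
        "pad": UtilityMultiplier(post=0.973, acute=None, post_sd=0.016),
    },
}


def default_config() -> dict:
    """Base-case synthesis and analysis configuration.

    Injectable drug prices are placeholders: the prices used in the
    source analysis are commercial-in-confidence and are not claimed
    here.
    """
    return {
        "n_per_sex": 30,
        "sex_shares": {MALE: 0.617, FEMALE: 0.383},
        "entry_ages": {MALE: 65.0, FEMALE: 70.0},
        "ldl_distribution": {
            MALE: {"location": math.log(1.85), "scale": 0.28, "lower_trunc": 0.3, "upper_trunc": 6.0},
            FEMALE: {"location": math.log(1.95), "scale": 0.30, "lower_trunc": 0.3, "upper_trunc": 6.0},
        },
        # Annual admission rates at the 65-69 band with a per-band growth
        # factor; rates must rise with age.
        "event_rate_params": {
            "mi": {MALE: 0.016, FEMALE: 0.011, "growth": 1.25},
            "ischaemic_stroke": {MALE: 0.010, FEMALE: 0.009, "growth": 1.35},
            "unstable_angina": {MALE: 0.006, FEMALE: 0.004, "growth": 1.15},
            "elective_revasc": {MALE: 0.013, FEMALE: 0.008, "growth": 1.05},
            "pad": {MALE: 0.005, FEMALE: 0.004, "growth": 1.20},
            TIA: {MALE: 0.007, FEMALE: 0.007, "growth": 1.30},
        },
        "rate_jitter": 0.01,
        "mortality_params": {
            "post": {MALE: 0.025, FEMALE: 0.020},
            "growth": {MALE: 1.55, FEMALE: 1.58},
            # Excess mortality in the 12 months after an acute admission.
            "acute_multipliers": {
                "ischaemic_stroke": 5.0,
                "mi": 4.0,
                "unstable_angina": 2.0,
                "elective_revasc": 1.3,
                "pad": 2.5,
            },
            "cvd_fraction": 0.5,
        },
        "baseline_state_distribution": {
            "post_mi": 0.32,
            "post_ischaemic_stroke": 0.14,
            "post_unstable_angina": 0.08,
            "post_elective_revasc": 0.34,
            "post_pad": 0.12,
        },
        "drift": {
            "mode": CONSTANT_BY_SEX,
            "constant_rate": {MALE: 0.02, FEMALE: 0.025},
            "regression_coeffs": {
                "intercept": 0.16,
                "initial_ldl": -0.08,
                "age": 0.0,
                "female": 0.01,
                "initial_ldl_x_age": 0.0,
                "initial_ldl_x_female": 0.0,
            },
            "regression_horizon": 3,
            "ldl_floor": 0.1,
        },
        "utility_curve": {
            MALE: {"at50": 0.87, "slope_per_year": 0.0042},
            FEMALE: {"at50": 0.85, "slope_per_year": 0.0045},
        },
        "utility_set": "hse2017",
        "unit_costs": {
            "lipid_test": 6.0,
            "nurse_visit": 11.0,
            "gp_visit": 38.0,
            "outpatient_visit": 138.0,
        },
        "statin_pack_price": 1.40,
        "ezetimibe_pack_price": 1.47,
        "pack_size": 28,
        # PLACEHOLDER annual prices; real prices are confidential.
        "inclisiran_annual_cost": 1900.0,
        "inclisiran_volume_annual_cost": 950.0,
        "pcsk9_annual_cost": 2300.0,
        "inclisiran_price_variant": "invoice",
        "ezetimibe_fee_annual": 16.0,
        "include_ezetimibe_fee": False,
        "stroke_social_care_annual": 2600.0,
        "stroke_social_care_share": 0.5,
        "event_cost_scale": 1.0,
        "discount_rate": 0.035,
        "measure": "LDL-C",
        "nonhdl_offset": 0.65,
        "grid": {"LDL-C": [0.0, 4.0, 0.1], "non-HDL-C": [0.5, 4.5, 0.1]},
        "wtp": 20000.0,
        "population": "any_statin",
        "rr_mode": "event_specific",
        "mortality_mode": "all_cause",
        "injectable_choice": "inclisiran_only",
        "pcsk9_trigger_threshold": 3.5,
        "adherence": {EZETIMIBE: 1.0, "injectable": 1.0},
        "allow_double_escalation": True,
        "include_unstable_angina": True,
        "include_tia": True,
        "age_cap": 100.0,
        "alive_floor": 1e-9,
        "half_cycle_correction": False,
        "escalation_resource_variant": "one_gp",
        "mortality_calibration": {"window": 10, "tolerance": 1e-4},
        "psa": {
            "n_sims": 10000,
            "rate_rel_halfwidth": 0.2,
            "cost_rel_halfwidth": 0.2,
        },
        # Statin-intolerant sub-population (scenario): no statin
        # background, higher baseline LDL-C, mixed in at this weight.
        "intolerant": {"mix_weight": 0.10, "ldl_uplift": 1.30},
        # Alternative population for the high-intensity statin scenario.
        "atorvastatin80": {
            "ldl_distribution": {
                MALE: {"location": math.log(1.55), "scale": 0.26, "lower_trunc": 0.3, "upper_trunc": 6.0},
                FEMALE: {"location": math.log(1.65), "scale": 0.28, "lower_trunc": 0.3, "upper_trunc": 6.0},
            },
            "entry_ages": {MALE: 60.0, FEMALE: 65.0},
        },
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _monotone_rates(base: float, growth: float, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Age-increasing rate profile with small multiplicative noise."""
    b = np.arange(N_BANDS) - 3  # anchored at the 65-69 band
    rates = base * growth**b
    if jitter > 0:
        rates = rates * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=N_BANDS))
    return rates


def build_ldl_specs(config: dict) -> dict[str, LDLDistributionSpec]:
    return {
        sex: LDLDistributionSpec(sex=sex, **params)
        for sex, params in config["ldl_distribution"].items()
    }


def build_therapies(config: dict) -> dict[str, Therapy]:
    pack = int(config["pack_size"])
    ezetimibe_cost = tablet_annual_cost(config["ezetimibe_pack_price"], pack)
    if config.get("include_ezetimibe_fee", False):
        ezetimibe_cost += float(config["ezetimibe_fee_annual"])
    if config.get("inclisiran_price_variant", "invoice") == "volume_discount":
        inclisiran_cost = float(config["inclisiran_volume_annual_cost"])
    else:
        inclisiran_cost = float(config["inclisiran_annual_cost"])
    therapies = default_therapies(
        inclisiran_annual_cost=inclisiran_cost,
        pcsk9_annual_cost=float(config["pcsk9_annual_cost"]),
        ezetimibe_annual_cost=ezetimibe_cost,
        statin_annual_cost=tablet_annual_cost(config["statin_pack_price"], pack),
    )
    choice = config.get("injectable_choice", "inclisiran_only")
    if choice == "pcsk9_above_3.5":
        therapies[PCSK9] = replace(
            therapies[PCSK9],
            trigger_threshold=float(config["pcsk9_trigger_threshold"]),
            line=3,
        )
    return therapies


def build_costs(config: dict) -> CostInputs:
    scale = float(config.get("event_cost_scale", 1.0))
    acute_age = {
        event: {sex: tuple(scale * c for c in row) for sex, row in table.items()}
        for event, table in ACUTE_AGE_COSTS.items()
    }
    flat = {e: scale * c for e, c in FLAT_ACUTE_COSTS.items()}
    post = {e: scale * c for e, c in DEFAULT_POST_COSTS.items()}
    if not config.get("include_tia", True):
        flat[TIA] = 0.0
        post[TIA] = 0.0
    return CostInputs(
        unit_costs=dict(config["unit_costs"]),
        acute_age_costs=acute_age,
        flat_acute_costs=flat,
        post_costs=post,
        vascular_death_acute=3196.0 * scale,
        vascular_death_post=327.0 * scale,
        stroke_social_care_annual=float(config["stroke_social_care_annual"]),
        stroke_social_care_share=float(config["stroke_social_care_share"]),
        discount_rate=float(config["discount_rate"]),
    )


def build_utilities(config: dict) -> UtilityInputs:
    curve = config["utility_curve"]
    baseline = {}
    for sex, params in curve.items():
        vals = []
        for lo, hi in AGE_BAND_EDGES:
            mid = 0.5 * (lo + min(hi, 100))
            vals.append(params["at50"] - params["slope_per_year"] * (mid - 50.0))
        baseline[sex] = tuple(vals)
    mult_set = config.get("utility_set", "hse2017")
    if mult_set not in UTILITY_SETS:
        raise ConfigurationError(f"unknown utility set: {mult_set!r}")
    return UtilityInputs(baseline=baseline, multipliers=dict(UTILITY_SETS[mult_set]))


def build_relative_risks(config: dict) -> RelativeRiskSet:
    rrset = RelativeRiskSet(events=dict(DEFAULT_EVENT_RR))
    if config.get("rr_mode", "event_specific") == "single_mace":
        rrset = rrset.as_single_mace()
    return rrset


def synthesize_inputs(config: Mapping | None = None, seed: int = 0) -> InputBundle:
    """Generate a complete synthetic input bundle.

    Pure function of ``(config, seed)``: the same arguments always give
    an identical bundle.
    """
    cfg = _deep_merge(default_config(), config or {})
    cfg["synthesis_seed"] = int(seed)
    params = cfg["event_rate_params"]
    missing = [
        e
        for e in RATE_EVENTS
        if not isinstance(params.get(e), Mapping)
        or not {MALE, FEMALE, "growth"} <= set(params[e])
    ]
    if missing:
        raise ConfigurationError(f"event rate parameters missing or invalid for: {missing}")

    rng = np.random.default_rng(seed)
    jitter = float(cfg["rate_jitter"])

    rows = []
    for event in RATE_EVENTS:
        p = params[event]
        for sex in SEXES:
            rates = _monotone_rates(float(p[sex]), float(p["growth"]), jitter, rng)
            for label, r in zip(AGE_BAND_LABELS, rates):
                rows.append((event, sex, label, float(r)))
    event_rates = EventRateTable(
        pd.DataFrame(rows, columns=list(EventRateTable.COLUMNS))
    )
    if not cfg.get("include_unstable_angina", True):
        event_rates = event_rates.zeroed(["unstable_angina"])
    if not cfg.get("include_tia", True):
        event_rates = event_rates.zeroed([TIA])

    mp = cfg["mortality_params"]
    mrows = []
    for sex in SEXES:
        post_rates = _monotone_rates(float(mp["post"][sex]), float(mp["growth"][sex]), jitter, rng)
        for label, r in zip(AGE_BAND_LABELS, post_rates):
            mrows.append((sex, label, "post", float(r)))
        for event in EVENTS:
            mult = float(mp["acute_multipliers"][event])
            if mult < 1.0:
                raise ConfigurationError(
                    f"acute mortality multiplier for {event} must be >= 1: {mult}"
                )
            for label, r in zip(AGE_BAND_LABELS, post_rates):
                mrows.append((sex, label, f"acute:{event}", float(r * mult)))
    mortality = MortalityTable(
        pd.DataFrame(mrows, columns=list(MortalityTable.COLUMNS)),
        cvd_fraction=float(mp["cvd_fraction"]),
    )

    ldl_specs = build_ldl_specs(cfg)
    subgroups = build_subgroups(
        ldl_specs, int(cfg["n_per_sex"]), cfg["sex_shares"], cfg["entry_ages"]
    )

    drift_cfg = cfg["drift"]
    drift = DriftModel(
        mode=drift_cfg["mode"],
        constant_rate=dict(drift_cfg["constant_rate"]),
        regression_coeffs=dict(drift_cfg["regression_coeffs"]),
        regression_horizon=int(drift_cfg["regression_horizon"]),
        ldl_floor=float(drift_cfg["ldl_floor"]),
    )

    return InputBundle(
        ldl_specs=ldl_specs,
        subgroups=subgroups,
        event_rates=event_rates,
        mortality=mortality,
        drift=drift,
        baseline_states=BaselineStateDistribution(dict(cfg["baseline_state_distribution"])),
        relative_risks=build_relative_risks(cfg),
        therapies=build_therapies(cfg),
        utilities=build_utilities(cfg),
        costs=build_costs(cfg),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def save_bundle(bundle: InputBundle, path: str | Path) -> None:
    """Write the bundle as a directory of YAML config + delimited tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
    bundle.event_rates.frame.to_csv(path / "event_rates.csv", index=False)
    mort = bundle.mortality.frame.copy()
    mort.to_csv(path / "mortality.csv", index=False)
    sub = pd.DataFrame(
        [(s.id, s.sex, s.entry_age, s.baseline_ldl, s.weight) for s in bundle.subgroups],
        columns=["id", "sex", "entry_age", "baseline_ldl", "weight"],
    )
    sub.to_csv(path / "subgroups.csv", index=False)


def load_bundle(path: str | Path) -> InputBundle:
    """Rebuild a bundle from a saved directory.

    The config fully determines every derived table, so loading
    regenerates them and verifies the stored tables match.
    """
    path = Path(path)
    with open(path / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    # The synthesis seed is recorded in the config by the CLI.
    seed = int(cfg.get("synthesis_seed", 0))
    bundle = synthesize_inputs(cfg, seed=seed)
    stored = pd.read_csv(path / "event_rates.csv")
    if not np.allclose(
        stored["rate"].to_numpy(), bundle.event_rates.frame["rate"].to_numpy()
    ):
        raise ConfigurationError(
            f"stored event rates at {path} do not match their config/seed"
        )
    return bundle
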