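"""Costs, utilities and discounting.

Each cycle of the cohort trace is valued in GBP and QALYs from the
perspective of the NHS and personal social services:

* QALYs: baseline age/sex EQ-5D utility times a state-specific
  multiplier (the mean utility of people with that CVD history divided
  by the population mean).  Acute multipliers apply during the event
  year; chronic ("post") multipliers afterwards.
* Costs: annualised drug costs, routine monitoring and initiation
  visits, acute event-year admission costs (age/sex-specific for
  stroke, MI and elective revascularisation; flat for the rest),
  chronic post-event costs, the acute cost of vascular deaths, the
  payer share of post-stroke social care, and optional interaction
  adjustments for events co-occurring within a year.
* Discounting at 3.5% per year, cycle 0 undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bands import N_BANDS, band_index
from .pathway import Therapy
from .states import TIA, ConfigurationError, StateSpace


@dataclass(frozen=True)
class UtilityMultiplier:
    """Acute / post utility multipliers for one event (with SDs for PSA)."""

    post: float
    acute: float | None = None
    post_sd: float = 0.0
    acute_sd: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.post, self.acute):
            if v is not None and not 0.0 < v <= 1.0:
                raise ConfigurationError(f"utility multiplier must be in (0, 1]: {v}")

    @property
    def acute_or_post(self) -> float:
        """Multiplier for the event year; falls back to the post value."""
        return self.post if self.acute is None else self.acute


# Health Survey for England 2017 multipliers (mean, SD).
HSE2017_MULTIPLIERS: dict[str, UtilityMultiplier] = {
    "ischaemic_stroke": UtilityMultiplier(post=0.816, acute=0.756, post_sd=0.013, acute_sd=0.064),
    "mi": UtilityMultiplier(post=0.847, acute=0.839, post_sd=0.010, acute_sd=0.054),
    "unstable_angina": UtilityMultiplier(post=0.878, acute=0.682, post_sd=0.011, acute_sd=0.021),
    "elective_revasc": UtilityMultiplier(post=0.889, acute=None, post_sd=0.028),
    "pad": UtilityMultiplier(post=0.927, acute=None, post_sd=0.016),
}


@dataclass(frozen=True)
class UtilityInputs:
    """Baseline utility by sex and age band, plus per-event multipliers."""

    baseline: Mapping[str, tuple[float, ...]]  # sex -> utility per age band
    multipliers: Mapping[str, UtilityMultiplier] = field(
        default_factory=lambda: dict(HSE2017_MULTIPLIERS)
    )

    def __post_init__(self) -> None:
        for sex, vals in self.baseline.items():
            if len(vals) != N_BANDS:
                raise ConfigurationError(
                    f"baseline utility for {sex} must have {N_BANDS} bands, got {len(vals)}"
                )

    def baseline_at(self, sex: str, age: float) -> float:
        return self.baseline[sex][band_index(age)]

    def with_multipliers(self, multipliers: Mapping[str, UtilityMultiplier]) -> "UtilityInputs":
        return replace(self, multipliers=dict(multipliers))


def state_multiplier_vector(space: StateSpace, utilities: UtilityInputs) -> np.ndarray:
    """Per-state utility multiplier (dead contributes 0)."""
    vec = np.zeros(space.n_states)
    for i, name in enumerate(space.posts):
        event = name[len("post_"):]
        mult = utilities.multipliers.get(event)
        if mult is None:
            raise ConfigurationError(f"no utility multiplier for event {event!r}")
        vec[i] = mult.post
    for j, (event, _ret) in enumerate(space.acutes):
        mult = utilities.multipliers.get(event)
        if mult is None:
            raise ConfigurationError(f"no utility multiplier for event {event!r}")
        vec[len(space.posts) + j] = mult.acute_or_post
    vec[space.dead_index] = 0.0
    return vec


def cycle_qaly(
    occupancy: np.ndarray,
    age: float,
    sex: str,
    utilities: UtilityInputs,
    space: StateSpace,
) -> float:
    """Undiscounted QALYs accrued by ``occupancy`` over one cycle."""
    base = utilities.baseline_at(sex, age)
    mult = state_multiplier_vector(space, utilities)
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (space.n_states,):
        raise ConfigurationError(
            f"occupancy has shape {occ.shape}, expected ({space.n_states},)"
        )
    return float(base * occ @ mult)


DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class CostInputs:
    """Unit, event and chronic costs (GBP) with discounting parameters.

    ``acute_age_costs`` maps event -> sex -> per-band event-year cost;
    events absent from it use ``flat_acute_costs``.  Stroke event-year
    costs already include the payer share of acute social care; the
    ongoing post-stroke social-care cost is listed separately with
    ``stroke_social_care_share`` borne by the payer.  Interaction
    coefficients adjust for event pairs occurring in the same year and
    default to zero.
    """

    unit_costs: Mapping[str, float]
    acute_age_costs: Mapping[str, Mapping[str, tuple[float, ...]]]
    flat_acute_costs: Mapping[str, float]
    post_costs: Mapping[str, float]
    vascular_death_acute: float = 3196.0
    vascular_death_post: float = 327.0
    stroke_social_care_annual: float = 0.0
    stroke_social_care_share: float = 0.5
    interaction_coefficients: Mapping[tuple[str, str], float] = field(default_factory=dict)
    discount_rate: float = 0.035

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigurationError(f"discount rate must be >= 0: {self.discount_rate}")
        for name, v in self.unit_costs.items():
            if v < 0:
                raise ConfigurationError(f"unit cost {name!r} must be >= 0: {v}")

    def unit(self, resource: str) -> float:
        try:
            return float(self.unit_costs[resource])
        except KeyError:
            raise ConfigurationError(f"no unit cost for resource {resource!r}") from None

    def acute_event_cost(self, event: str, sex: str, age: float) -> float:
        """Event-year admission cost; ages outside the table clamp to the ends."""
        table = self.acute_age_costs.get(event)
        if table is not None:
            return float(table[sex][band_index(age)])
        try:
            return float(self.flat_acute_costs[event])
        except KeyError:
            raise ConfigurationError(f"no acute cost for event {event!r}") from None

    def post_event_cost(self, event: str) -> float:
        cost = float(self.post_costs.get(event, 0.0))
        if event == "ischaemic_stroke":
            cost += self.stroke_social_care_share * self.stroke_social_care_annual
        return cost


def annual_drug_cost(therapies: Iterable[Therapy]) -> float:
    return float(sum(t.annual_drug_cost for t in therapies))


def tablet_annual_cost(pack_price: float, pack_size: int = 28) -> float:
    """Annualised cost of a once-daily tablet from its pack price."""
    return pack_price / pack_size * DAYS_PER_YEAR


def state_cost_vector(space: StateSpace, sex: str, age: float, costs: CostInputs) -> np.ndarray:
    """Per-state annual cost: acute event-year costs and chronic post costs."""
    vec = np.zeros(space.n_states)
    for i, name in enumerate(space.posts):
        event = name[len("post_"):]
        vec[i] = costs.post_event_cost(event)
    for j, (event, _ret) in enumerate(space.acutes):
        vec[len(space.posts) + j] = costs.acute_event_cost(event, sex, age)
    return vec


def cycle_cost(
    occupancy: np.ndarray,
    space: StateSpace,
    age: float,
    sex: str,
    costs: CostInputs,
    *,
    therapies: Iterable[Therapy] = (),
    resource_events: Sequence[tuple[str, float]] = (),
    alive_mass: float | None = None,
    tia_incidence: float = 0.0,
    cvd_deaths: float = 0.0,
    event_incidence: Mapping[str, float] | None = None,
) -> float:
    """Undiscounted GBP accrued over one cycle.

    ``resource_events`` are (resource, count-per-alive-person) pairs;
    drug costs and monitoring scale with the alive mass, event and post
    costs with state occupancy, and the acute vascular-death cost with
    the cycle's CVD deaths.
    """
    occ = np.asarray(occupancy, dtype=float)
    if alive_mass is None:
        alive_mass = float(occ.sum() - occ[space.dead_index])
    total = float(occ @ state_cost_vector(space, sex, age, costs))
    total += annual_drug_cost(therapies) * alive_mass
    for resource, count in resource_events:
        total += costs.unit(resource) * count * alive_mass
    total += costs.flat_acute_costs.get(TIA, 0.0) * tia_incidence
    total += costs.vascular_death_acute * cvd_deaths
    if costs.interaction_coefficients and event_incidence and alive_mass > 0:
        inc = dict(event_incidence)
        inc["vascular_death"] = cvd_deaths
        for (a, b), coeff in costs.interaction_coefficients.items():
            # Expected co-occurrence mass under within-cycle independence.
            total += coeff * inc.get(a, 0.0) * inc.get(b, 0.0) / alive_mass
    return total


def discount(value: float, cycle: int, rate: float) -> float:
    """Discounted present value; cycle 0 is undiscounted."""
    if rate < 0:
        raise ConfigurationError(f"discount rate must be >= 0: {rate}")
    if cycle < 0:
        raise ConfigurationError(f"cycle must be >= 0: {cycle}")
    return value / (1.0 + rate) ** cycle


def discount_factors(n_cycles: int, rate: float) -> np.ndarray:
    if rate < 0:
        raise ConfigurationError(f"discount rate must be >= 0: {rate}")
    return (1.0 + rate) ** -np.arange(n_cycles, dtype=float)
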