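import math

import numpy as np
import pytest

from lipidcea.bands import N_BANDS
from lipidcea.economics import (
    CostInputs,
    UtilityInputs,
    UtilityMultiplier,
    cycle_cost,
    cycle_qaly,
    discount,
    discount_factors,
    state_cost_vector,
    tablet_annual_cost,
)
from lipidcea.markov import build_transition_matrix
from lipidcea.states import ConfigurationError, StateSpace

SPACE = StateSpace.default()
MALE = "male"


def flat_utilities(base=0.8, mult=None):
    multipliers = {
        e: UtilityMultiplier(post=mult or 1.0, acute=mult or 1.0)
        for e in ("ischaemic_stroke", "mi", "unstable_angina", "elective_revasc", "pad")
    }
    return UtilityInputs(baseline={MALE: (base,) * N_BANDS}, multipliers=multipliers)


class TestCycleQaly:
    def test_identity_multipliers(self):
        occ = np.zeros(SPACE.n_states)
        occ[SPACE.post_index("mi")] = 1.0
        assert cycle_qaly(occ, 65, MALE, flat_utilities(0.8), SPACE) == pytest.approx(0.8)

    def test_post_stroke_multiplier(self):
        utilities = UtilityInputs(baseline={MALE: (0.8,) * N_BANDS})
        occ = np.zeros(SPACE.n_states)
        occ[SPACE.post_index("ischaemic_stroke")] = 1.0
        assert cycle_qaly(occ, 70, MALE, utilities, SPACE) == pytest.approx(0.8 * 0.816)

    def test_acute_unstable_angina_multiplier(self):
        utilities = UtilityInputs(baseline={MALE: (1.0,) * N_BANDS})
        occ = np.zeros(SPACE.n_states)
        occ[SPACE.acute_index("unstable_angina", "unstable_angina")] = 1.0
        assert cycle_qaly(occ, 60, MALE, utilities, SPACE) == pytest.approx(0.682)

    def test_acute_pad_falls_back_to_post_multiplier(self):
        utilities = UtilityInputs(baseline={MALE: (1.0,) * N_BANDS})
        occ = np.zeros(SPACE.n_states)
        occ[SPACE.acute_index("pad", "pad")] = 1.0
        assert cycle_qaly(occ, 60, MALE, utilities, SPACE) == pytest.approx(0.927)

    def test_dead_contributes_nothing(self):
        occ = np.zeros(SPACE.n_states)
        occ[SPACE.dead_index] = 1.0
        assert cycle_qaly(occ, 80, MALE, flat_utilities(), SPACE) == 0.0


class TestCycleCost:
    def test_acute_stroke_age_sex_cost(self, default_bundle):
        occ = np.zeros(SPACE.n_states)
        occ[SPACE.acute_index("ischaemic_stroke", "ischaemic_stroke")] = 1.0
        cost = cycle_cost(occ, SPACE, 72.0, MALE, default_bundle.costs)
        assert cost == pytest.approx(12545.0)

    def test_tia_event_cost(self, default_bundle):
        occ = np.zeros(SPACE.n_states)
        base = cycle_cost(occ, SPACE, 70.0, MALE, default_bundle.costs, alive_mass=1.0)
        with_tia = cycle_cost(
            occ, SPACE, 70.0, MALE, default_bundle.costs, alive_mass=1.0, tia_incidence=1.0
        )
        assert with_tia - base == pytest.approx(3196.0)

    def test_ezetimibe_annualised_pack_cost(self):
        assert tablet_annual_cost(1.47, 28) == pytest.approx(1.47 / 28 * 365, abs=1e-9)
        assert tablet_annual_cost(1.47, 28) == pytest.approx(19.16, abs=5e-3)

    def test_age_outside_table_clamps(self, default_bundle):
        occ = np.zeros(SPACE.n_states)
        occ[SPACE.acute_index("mi", "mi")] = 1.0
        young = cycle_cost(occ, SPACE, 40.0, MALE, default_bundle.costs)
        old = cycle_cost(occ, SPACE, 104.0, MALE, default_bundle.costs)
        assert young == pytest.approx(7706.0)
        assert old == pytest.approx(11278.0)

    def test_linear_in_unit_costs(self, default_bundle):
        from dataclasses import replace

        c = default_bundle.costs
        doubled = replace(
            c,
            unit_costs={k: 2 * v for k, v in c.unit_costs.items()},
            acute_age_costs={
                e: {s: tuple(2 * x for x in row) for s, row in t.items()}
                for e, t in c.acute_age_costs.items()
            },
            flat_acute_costs={e: 2 * v for e, v in c.flat_acute_costs.items()},
            post_costs={e: 2 * v for e, v in c.post_costs.items()},
            vascular_death_acute=2 * c.vascular_death_acute,
            stroke_social_care_annual=2 * c.stroke_social_care_annual,
        )
        rng = np.random.default_rng(5)
        occ = rng.dirichlet(np.ones(SPACE.n_states))
        kwargs = dict(
            resource_events=[("lipid_test", 1), ("gp_visit", 1)],
            tia_incidence=0.01,
            cvd_deaths=0.005,
        )
        one = cycle_cost(occ, SPACE, 71.0, MALE, c, **kwargs)
        two = cycle_cost(occ, SPACE, 71.0, MALE, doubled, **kwargs)
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestDiscount:
    def test_cycle_zero_is_undiscounted(self):
        assert discount(123.4, 0, 0.035) == 123.4

    def test_one_cycle_at_three_and_a_half_percent(self):
        assert discount(100.0, 1, 0.035) == pytest.approx(96.618, abs=5e-4)

    def test_zero_rate_identity(self):
        assert discount(55.5, 17, 0.0) == 55.5

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            discount(1.0, 1, -0.01)
        with pytest.raises(ConfigurationError):
            discount_factors(5, -0.01)

    def test_discounting_never_inflates(self):
        values = np.full(30, 1.0)
        dfs = discount_factors(30, 0.035)
        assert (values * dfs).sum() <= values.sum()


def test_survival_chain_matches_annuity_closed_form():
    """With unit multipliers and no events, discounted QALYs reduce to a
    geometric annuity on the survival curve."""
    m, u, d, T = 0.05, 0.8, 0.035, 40
    utilities = flat_utilities(u)
    M = build_transition_matrix(SPACE, {}, {"post": m})
    occ = np.zeros(SPACE.n_states)
    occ[SPACE.post_index("mi")] = 1.0
    total = 0.0
    for t in range(T):
        total += discount(cycle_qaly(occ, 65 + t, MALE, utilities, SPACE), t, d)
        occ = occ @ M
    x = math.exp(-m) / (1 + d)
    expected = u * (1 - x**T) / (1 - x)
    assert total == pytest.approx(expected, rel=1e-10)


def test_state_cost_vector_covers_all_alive_states(default_bundle):
    vec = state_cost_vector(SPACE, MALE, 67.0, default_bundle.costs)
    assert vec.shape == (SPACE.n_states,)
    assert vec[SPACE.dead_index] == 0.0
    assert (vec[: SPACE.n_states - 1] >= 0).all()
    # Post-stroke carries the payer share of ongoing social care.
    c = default_bundle.costs
    assert vec[SPACE.post_index("ischaemic_stroke")] == pytest.approx(
        c.post_costs["ischaemic_stroke"]
        + c.stroke_social_care_share * c.stroke_social_care_annual
    )
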