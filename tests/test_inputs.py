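import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lipidcea.bands import AGE_BAND_LABELS
from lipidcea.inputs import (
    FEMALE,
    MALE,
    DriftModel,
    InvalidSpecError,
    LDLDistributionSpec,
    Subgroup,
    apply_drift,
    build_subgroups,
    load_bundle,
    save_bundle,
    synthesize_inputs,
)
from lipidcea.states import EVENTS, TIA, ConfigurationError


def male_spec(location=math.log(2.0), scale=0.3):
    return LDLDistributionSpec(sex=MALE, location=location, scale=scale)


class TestLDLDistributionSpec:
    def test_rejects_bad_scale_and_truncation(self):
        with pytest.raises(InvalidSpecError):
            LDLDistributionSpec(sex=MALE, location=0.6, scale=0.0)
        with pytest.raises(InvalidSpecError):
            LDLDistributionSpec(sex=MALE, location=0.6, scale=0.3, lower_trunc=3.0, upper_trunc=1.0)

    def test_band_means_match_monte_carlo(self):
        """Conditional band means agree with a 10^6-draw sampling oracle."""
        spec = male_spec()
        rng = np.random.default_rng(42)
        draws = rng.lognormal(spec.location, spec.scale, 2_000_000)
        draws = draws[(draws >= spec.lower_trunc) & (draws <= spec.upper_trunc)]
        assert draws.size > 1_000_000
        draws.sort()
        quarters = np.array_split(draws, 4)
        mc_means = np.array([q.mean() for q in quarters])
        np.testing.assert_allclose(spec.band_means(4), mc_means, atol=0.01)

    def test_truncated_mean_matches_monte_carlo(self):
        spec = male_spec()
        rng = np.random.default_rng(7)
        draws = rng.lognormal(spec.location, spec.scale, 2_000_000)
        draws = draws[(draws >= spec.lower_trunc) & (draws <= spec.upper_trunc)]
        assert spec.mean() == pytest.approx(draws.mean(), abs=3 * draws.std() / math.sqrt(draws.size))


class TestBuildSubgroups:
    def test_degenerate_single_band(self):
        spec = male_spec()
        subs = build_subgroups(spec, 1, {MALE: 1.0})
        assert len(subs) == 1
        assert subs[0].weight == pytest.approx(1.0)
        assert subs[0].baseline_ldl == pytest.approx(spec.mean(), abs=1e-9)

    def test_thirty_per_sex_curve(self):
        specs = {MALE: male_spec(), FEMALE: LDLDistributionSpec(sex=FEMALE, location=0.65, scale=0.3)}
        subs = build_subgroups(specs, 30, {MALE: 0.6, FEMALE: 0.4})
        assert len(subs) == 60
        assert sum(1 for s in subs if s.sex == MALE) == 30
        assert sum(1 for s in subs if s.sex == FEMALE) == 30

    @given(
        n=st.integers(1, 40),
        share=st.floats(0.05, 0.95),
        loc=st.floats(0.3, 1.2),
        scale=st.floats(0.05, 0.6),
    )
    def test_weights_sum_to_one_and_mean_is_preserved(self, n, share, loc, scale):
        specs = {
            MALE: LDLDistributionSpec(sex=MALE, location=loc, scale=scale),
            FEMALE: LDLDistributionSpec(sex=FEMALE, location=loc + 0.05, scale=scale),
        }
        subs = build_subgroups(specs, n, {MALE: share, FEMALE: 1 - share})
        assert math.fsum(s.weight for s in subs) == pytest.approx(1.0, abs=1e-12)
        # Equal-probability banding with conditional means preserves each
        # sex's mean LDL-C exactly.
        for sex, spec in specs.items():
            sexsubs = [s for s in subs if s.sex == sex]
            w = sum(s.weight for s in sexsubs)
            mean = sum(s.weight * s.baseline_ldl for s in sexsubs) / w
            assert mean == pytest.approx(spec.mean(), rel=1e-6)

    def test_invalid_spec_raises(self):
        with pytest.raises(InvalidSpecError):
            build_subgroups(male_spec(), 0, {MALE: 1.0})
        with pytest.raises(InvalidSpecError):
            build_subgroups(male_spec(), 3, {MALE: 0.7})  # shares must sum to 1


class TestSynthesizeInputs:
    def test_pure_function_of_config_and_seed(self, tmp_path):
        a = synthesize_inputs({"n_per_sex": 3}, seed=11)
        b = synthesize_inputs({"n_per_sex": 3}, seed=11)
        assert a.event_rates.equals(b.event_rates)
        assert a.mortality.equals(b.mortality)
        assert a.subgroups == b.subgroups
        assert a.config == b.config
        # Byte-identical on disk.
        save_bundle(a, tmp_path / "one")
        save_bundle(b, tmp_path / "two")
        for f in sorted(p.name for p in (tmp_path / "one").iterdir()):
            assert (tmp_path / "one" / f).read_bytes() == (tmp_path / "two" / f).read_bytes()
        c = synthesize_inputs({"n_per_sex": 3}, seed=12)
        assert not a.event_rates.equals(c.event_rates)

    def test_rates_nonnegative_and_age_monotone(self, default_bundle):
        frame = default_bundle.event_rates.frame
        assert (frame["rate"] >= 0).all()
        for event in EVENTS + (TIA,):
            for sex in (MALE, FEMALE):
                rates = default_bundle.event_rates.array(event, sex)
                assert np.all(np.diff(rates) > 0), (event, sex)

    def test_acute_mortality_exceeds_post(self, default_bundle):
        for sex in (MALE, FEMALE):
            post = default_bundle.mortality.array(sex, "post")
            for event in EVENTS:
                acute = default_bundle.mortality.array(sex, f"acute:{event}")
                assert np.all(acute >= post)

    def test_missing_event_type_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            synthesize_inputs({"event_rate_params": {"mi": None}}, seed=0)

    def test_microsample_rate_consistent_with_table(self, default_bundle):
        """A sampled 10^5-person-year cohort reproduces the generating rate."""
        rate = default_bundle.event_rates.rate("mi", MALE, 66.0)
        rng = np.random.default_rng(123)
        n = 100_000
        events = rng.poisson(rate, n)
        se = math.sqrt(rate / n)
        assert abs(events.mean() - rate) < 3 * se


class TestApplyDrift:
    SUB = Subgroup(id=0, sex=MALE, entry_age=65.0, baseline_ldl=2.0, weight=1.0)

    def test_zero_rate_is_identity(self):
        drift = DriftModel(constant_rate={MALE: 0.0, FEMALE: 0.0})
        assert apply_drift(2.0, self.SUB, 1, drift) == 2.0

    def test_constant_rate_adds_each_cycle(self):
        drift = DriftModel(constant_rate={MALE: 0.02, FEMALE: 0.02})
        assert apply_drift(2.00, self.SUB, 1, drift) == pytest.approx(2.02)

    def test_floor_prevents_nonpositive_ldl(self):
        drift = DriftModel(constant_rate={MALE: -5.0, FEMALE: -5.0})
        assert apply_drift(2.0, self.SUB, 1, drift) == drift.ldl_floor

    def test_regression_mode_pulls_toward_the_mean(self):
        drift = DriftModel(mode="three_cycle_regression")
        lo = Subgroup(id=1, sex=MALE, entry_age=65.0, baseline_ldl=1.0, weight=0.5)
        hi = Subgroup(id=2, sex=MALE, entry_age=65.0, baseline_ldl=3.0, weight=0.5)
        assert apply_drift(1.0, lo, 1, drift) > 1.0  # below the mean: rises
        assert apply_drift(3.0, hi, 1, drift) < 3.0  # above the mean: falls
        # Beyond the regression horizon LDL-C is held constant.
        assert apply_drift(2.5, hi, drift.regression_horizon + 1, drift) == 2.5

    def test_preconditions(self):
        drift = DriftModel()
        with pytest.raises(ConfigurationError):
            apply_drift(0.0, self.SUB, 1, drift)
        with pytest.raises(ConfigurationError):
            apply_drift(2.0, self.SUB, 0, drift)


def test_bundle_round_trip(tmp_path, small_bundle):
    save_bundle(small_bundle, tmp_path / "bundle")
    loaded = load_bundle(tmp_path / "bundle")
    assert loaded.event_rates.equals(small_bundle.event_rates)
    assert loaded.mortality.equals(small_bundle.mortality)
    assert loaded.subgroups == small_bundle.subgroups
    assert loaded.config == small_bundle.config
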