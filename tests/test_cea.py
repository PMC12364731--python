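import numpy as np
import pytest

from lipidcea.cea import (
    PsaParameter,
    ThresholdResult,
    apply_psa_realization,
    build_psa_spec,
    draw_psa_parameters,
    incremental_analysis,
    nmb_optimal,
    run_psa,
    sweep_thresholds,
    threshold_grid,
)
from lipidcea.model import prepare_model
from lipidcea.states import ConfigurationError


def make_option(threshold, cost, qaly):
    return ThresholdResult(
        threshold=threshold,
        cost=cost,
        qaly=qaly,
        frac_ezetimibe_1y=0.0,
        frac_injectable_1y=0.0,
        mean_ldl_1y=2.0,
    )


class TestGrid:
    def test_default_ldl_grid_has_41_thresholds(self):
        grid = threshold_grid(0.0, 4.0, 0.1)
        assert len(grid) == 41
        assert grid[0] == 0.0 and grid[-1] == 4.0
        np.testing.assert_allclose(np.diff(grid), 0.1)

    def test_single_threshold_grid(self):
        assert list(threshold_grid(2.0, 2.0, 0.1)) == [2.0]

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            threshold_grid(2.0, 1.0, 0.1)


class TestIncrementalAnalysis:
    def test_icer_below_lambda_selects_more_effective_option(self):
        a = make_option(3.0, 0.0, 1.0)
        b = make_option(2.0, 5000.0, 1.5)  # ICER 10,000/QALY
        ia = incremental_analysis([a, b], 20000.0)
        assert ia.optimal is b
        assert ia.icers[2.0] == pytest.approx(10000.0)

    def test_extended_dominance_flag(self):
        a = make_option(3.0, 0.0, 1.0)
        mid = make_option(2.5, 8000.0, 1.1)  # ICER 80,000 then next step 5,000
        c = make_option(2.0, 10000.0, 1.5)
        ia = incremental_analysis([a, mid, c], 20000.0)
        assert ia.dominated == {2.5: "extended"}
        assert [r.threshold for r in ia.frontier] == [3.0, 2.0]

    def test_strict_dominance_flag(self):
        a = make_option(3.0, 1000.0, 1.2)
        b = make_option(2.0, 2000.0, 1.1)  # costlier and less effective
        ia = incremental_analysis([a, b], 20000.0)
        assert ia.dominated == {2.0: "dominated"}
        assert ia.optimal is a

    def test_needs_two_options(self):
        with pytest.raises(ConfigurationError):
            incremental_analysis([make_option(2.0, 0.0, 1.0)], 20000.0)

    def test_frontier_matches_nmb_argmax_on_random_option_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(3, 12)
            options = [
                make_option(round(t, 2), c, q)
                for t, c, q in zip(
                    np.arange(n) * 0.1 + 1.0,
                    rng.uniform(0, 40000, n),
                    rng.uniform(5.0, 7.0, n),
                )
            ]
            for lam in (15000.0, 20000.0, 30000.0):
                ia = incremental_analysis(options, lam)
                assert ia.optimal is nmb_optimal(options, lam)
                icers = [ia.icers[r.threshold] for r in ia.frontier[1:]]
                assert all(x < y for x, y in zip(icers, icers[1:]))
            # Enumeration oracle: flagged options are never NMB-optimal
            # at any willingness-to-pay.
            ia = incremental_analysis(options, 20000.0)
            for lam in np.linspace(1.0, 100000.0, 60):
                best = nmb_optimal(options, lam)
                assert best.threshold not in ia.dominated

    def test_lower_lambda_never_selects_more_aggressive_threshold(self, small_bundle, small_prepared, small_grid):
        results = sweep_thresholds(small_bundle, grid=small_grid, prepared=small_prepared)
        optima = [
            incremental_analysis(results, lam).optimal.threshold
            for lam in (15000.0, 20000.0, 30000.0)
        ]
        assert optima[0] >= optima[1] >= optima[2]


class TestSweep:
    def test_monotone_patterns_on_synthetic_bundle(self, small_bundle, small_prepared):
        grid = threshold_grid(0.8, 4.0, 0.4)
        results = sweep_thresholds(small_bundle, grid=grid, prepared=small_prepared)
        assert len(results) == len(grid)
        q = [r.qaly for r in results]
        ldl = [r.mean_ldl_1y for r in results]
        treated = [r.frac_ezetimibe_1y for r in results]
        assert all(a >= b - 1e-12 for a, b in zip(q, q[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(ldl, ldl[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(treated, treated[1:]))

    def test_empty_grid_rejected(self, small_bundle, small_prepared):
        with pytest.raises(ConfigurationError):
            sweep_thresholds(small_bundle, grid=[], prepared=small_prepared)


class TestPsaDraws:
    def test_same_seed_same_realization(self, small_bundle):
        a = draw_psa_parameters(small_bundle, 17)
        b = draw_psa_parameters(small_bundle, 17)
        assert a == b
        c = draw_psa_parameters(small_bundle, 18)
        assert a != c

    def test_degenerate_intervals_return_means(self, small_bundle):
        bundle = small_bundle.copy()
        bundle.config["psa"]["degenerate"] = True
        spec = build_psa_spec(bundle)
        realization = draw_psa_parameters(bundle, 3, spec=spec)
        expected = {p.name: p.mean for p in spec}
        assert realization == expected

    def test_lognormal_quantiles_match_printed_interval(self):
        # MACE relative risk 0.78 (0.76, 0.80): the drawn 95% interval
        # must reproduce the printed one.
        p = PsaParameter("rr:mace", "lognormal", 0.78, 0.76, 0.80)
        rng = np.random.default_rng(11)
        draws = np.array([p.draw(rng) for _ in range(100_000)])
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(0.76, abs=0.005)
        assert hi == pytest.approx(0.80, abs=0.005)

    def test_inconsistent_interval_names_the_parameter(self):
        p = PsaParameter("rr:bad", "lognormal", 0.5, 0.6, 0.9)
        with pytest.raises(ConfigurationError, match="rr:bad"):
            p.draw(np.random.default_rng(0))

    def test_realization_changes_the_bundle(self, small_bundle):
        realization = draw_psa_parameters(small_bundle, 5)
        bundle = apply_psa_realization(small_bundle, realization)
        assert bundle.relative_risks.events["mi"].point == pytest.approx(
            realization["rr:mi"]
        )
        assert not bundle.event_rates.equals(small_bundle.event_rates)
        # The base bundle itself is untouched.
        assert small_bundle.relative_risks.events["mi"].point == 0.73


class TestRunPsa:
    def test_degenerate_psa_collapses_to_deterministic(self, small_bundle, small_grid):
        bundle = small_bundle.copy()
        bundle.config["psa"]["degenerate"] = True
        det_prepared = prepare_model(bundle)
        det = sweep_thresholds(bundle, grid=small_grid, prepared=det_prepared)
        res = run_psa(bundle, n_sims=2, lambdas=(20000.0,), seed=4, grid=small_grid)
        np.testing.assert_array_equal(res.mean_cost, [r.cost for r in det])
        np.testing.assert_array_equal(res.mean_qaly, [r.qaly for r in det])

    def test_probabilities_partition_simulations(self, small_bundle, small_grid):
        res = run_psa(small_bundle, n_sims=40, lambdas=(15000.0, 20000.0), seed=9, grid=small_grid)
        for lam, prob in res.prob_optimal.items():
            assert prob.sum() == pytest.approx(1.0, abs=1e-12)
            assert (prob >= 0).all()

    def test_compare_thresholds_subset(self, small_bundle, small_grid):
        subset = [small_grid[1], small_grid[3]]
        res = run_psa(
            small_bundle, n_sims=10, lambdas=(20000.0,), seed=2,
            grid=small_grid, compare_thresholds=subset,
        )
        prob = res.prob_optimal[20000.0]
        mask = np.isin(res.thresholds, subset)
        assert prob[~mask].sum() == 0.0
        assert prob[mask].sum() == pytest.approx(1.0)

    def test_stub_evaluator_receives_every_draw(self, small_bundle, small_grid):
        seen = []
        res = run_psa(
            small_bundle,
            n_sims=25,
            seed=1,
            grid=small_grid,
            evaluator=lambda r, g: (seen.append(dict(r)) or np.zeros(len(g)), np.ones(len(g))),
        )
        assert len(seen) == 25
        assert len({tuple(sorted(r.items())) for r in seen}) == 25  # all distinct draws
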