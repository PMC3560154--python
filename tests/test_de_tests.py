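"""Tests for size factors, dispersion strategies, and the exact NB test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaseqpower import (
    DispersionStrategy,
    ExactNBTest,
    GeneratorConfig,
    build_parameter_population,
    run_de_test,
    simulate_counts,
)
from rnaseqpower.de_tests import (
    _argmax_phi_per_transcript,
    _conditional_ll,
    adjust_pvalues_bh,
    compute_size_factors,
    estimate_dispersions,
    exact_nb_test,
    fold_change_detector,
)
from rnaseqpower.metrics import fpr_null

from conftest import brute_force_exact_pvalue, counts_with_sums


class TestSizeFactors:
    def test_identical_lanes_give_unit_factors(self):
        mat = np.tile(np.array([[10], [20], [5]]), (1, 3))
        for method in ("unit", "median-of-ratios", "tmm"):
            np.testing.assert_allclose(compute_size_factors(mat, method), 1.0)

    def test_doubled_lane_median_of_ratios(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(50, size=500)
        mat = np.column_stack([a, 2 * a])
        f = compute_size_factors(mat, "median-of-ratios")
        assert f[1] / f[0] == pytest.approx(2.0, rel=1e-6)
        assert np.prod(f) == pytest.approx(1.0)  # geometric mean 1

    def test_tmm_agrees_with_median_of_ratios_under_null(self):
        rng = np.random.default_rng(1)
        r = 1 / 0.2
        mu = 10 ** rng.uniform(1, 3, size=2000)
        mat = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 4))
        f1 = compute_size_factors(mat, "tmm")
        f2 = compute_size_factors(mat, "median-of-ratios")
        np.testing.assert_allclose(f1, f2, rtol=0.05)

    def test_all_zero_lane_errors(self):
        with pytest.raises(ValueError):
            compute_size_factors(np.array([[0, 1], [0, 2]]), "unit")


class TestBH:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            adjust_pvalues_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_degenerate(self):
        assert adjust_pvalues_bh([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(adjust_pvalues_bh([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_min_rank_preserved(self, pvals):
        p = np.array(pvals)
        q = adjust_pvalues_bh(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        # the smallest raw p-value attains the smallest adjusted value
        assert q[np.argmin(p)] == q.min()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            adjust_pvalues_bh([0.5, 1.5])


class TestFoldChangeDetector:
    def _cond(self):
        return np.array(["control", "treatment"])

    def test_basic_doubling_called(self):
        mat = np.array([[10, 20]])
        assert fold_change_detector(mat, self._cond(), 2.0, 0.0)[0]

    def test_pseudocount_damping(self):
        mat = np.array([[0, 1]])
        assert fold_change_detector(mat, self._cond(), 2.0, 1.0)[0]  # fc = 2/1
        assert not fold_change_detector(mat, self._cond(), 2.0, 10.0)[0]  # 11/10

    def test_zero_conventions_without_pseudocount(self):
        mat = np.array([[0, 5], [0, 0], [5, 0]])
        calls = fold_change_detector(mat, self._cond(), 2.0, 0.0)
        np.testing.assert_array_equal(calls, [True, False, True])

    def test_halving_called_symmetrically(self):
        mat = np.array([[40, 19]])
        assert fold_change_detector(mat, self._cond(), 2.0, 0.0)[0]


class TestExactTest:
    def test_enumeration_oracle_all_totals_up_to_200(self):
        """Exhaustive agreement with the brute-force conditional oracle for
        every condition-sum total S <= 200."""
        rng = np.random.default_rng(0)
        for S in range(0, 201):
            nA = int(rng.integers(1, 5))
            nB = int(rng.integers(1, 5))
            phi = float(rng.uniform(0, 3))
            SA = int(rng.integers(0, S + 1))
            mat, cond = counts_with_sums(rng, SA, S - SA, nA, nB)
            p = exact_nb_test(mat, cond, np.array([phi]))[0]
            assert p == pytest.approx(
                brute_force_exact_pvalue(SA, S - SA, nA, nB, phi), abs=1e-10
            ), f"S={S} SA={SA} nA={nA} nB={nB} phi={phi}"

    def test_balanced_equal_sums_give_pvalue_one(self):
        # holds whenever the conditional law is unimodal at the centre,
        # i.e. the pooled shape n/phi is at least 1 (always true in the
        # study's designs); phi > n makes the conditional U-shaped instead
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 5))
            SA = int(rng.integers(0, 100))
            mat, cond = counts_with_sums(rng, SA, SA, n, n)
            p = exact_nb_test(mat, cond, np.array([rng.uniform(0, 0.95 * n)]))[0]
            assert p == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_gives_pvalue_one(self):
        mat = np.zeros((1, 4), dtype=int)
        cond = np.array(["control"] * 2 + ["treatment"] * 2)
        assert exact_nb_test(mat, cond, np.array([0.5]))[0] == 1.0

    def test_poisson_limit_matches_conditional_binomial(self):
        """With phi = 0 and one lane per condition the conditional law is
        Binomial(S, 1/2); the two-sided conditional p must match."""
        from scipy.stats import binom

        rng = np.random.default_rng(2)
        cond = np.array(["control", "treatment"])
        for _ in range(40):
            S = int(rng.integers(1, 400))
            SA = int(rng.integers(0, S + 1))
            mat = np.array([[SA, S - SA]])
            p = exact_nb_test(mat, cond, np.array([0.0]))[0]
            pmf = binom.pmf(np.arange(S + 1), S, 0.5)
            expected = pmf[pmf <= pmf[SA] * (1 + 1e-12)].sum()
            assert p == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_large_total_agrees_with_direct_pmf_evaluation(self):
        """Spot-check one large-S transcript against direct nbinom pmfs to
        guard the ratio-recurrence cumsum path."""
        rng = np.random.default_rng(3)
        SA, SB, nA, nB, phi = 52_000, 48_500, 3, 3, 0.05
        mat, cond = counts_with_sums(rng, SA, SB, nA, nB)
        p = exact_nb_test(mat, cond, np.array([phi]))[0]
        assert p == pytest.approx(brute_force_exact_pvalue(SA, SB, nA, nB, phi), rel=1e-6)

    def test_requires_dispersions(self):
        with pytest.raises(ValueError):
            exact_nb_test(np.array([[1, 2]]), np.array(["control", "treatment"]))


class TestDispersionStrategies:
    def test_oracle_passthrough(self, small_population):
        cm = simulate_counts(small_population, 2, seed=0)
        strat = DispersionStrategy("oracle", true_dispersions=small_population.dispersion)
        out = estimate_dispersions(cm, cm.condition, strat)
        np.testing.assert_array_equal(out, small_population.dispersion)

    def test_oracle_requires_dispersions(self):
        with pytest.raises(ValueError):
            DispersionStrategy("oracle")

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            DispersionStrategy("bogus")

    def test_common_dispersion_recovery_constant_phi(self):
        """Tagwise-squeeze with infinite prior df collapses to the common
        conditional-ML dispersion, which should recover a constant truth."""
        pop = build_parameter_population(
            GeneratorConfig(t=5000, library_size=None), seed=4
        )
        pop.dispersion[:] = 0.3
        cm = simulate_counts(pop, 12, seed=5)
        strat = DispersionStrategy("tagwise-squeeze", prior_df=1e12)
        out = estimate_dispersions(cm, cm.condition, strat)
        assert np.ptp(out) < 1e-6  # all squeezed onto the common value
        assert out[0] == pytest.approx(0.3, rel=0.10)

    def test_tagwise_squeeze_blends_towards_common(self, small_population):
        cm = simulate_counts(small_population, 3, seed=6)
        loose = estimate_dispersions(
            cm, cm.condition, DispersionStrategy("tagwise-squeeze", prior_df=1.0)
        )
        tight = estimate_dispersions(
            cm, cm.condition, DispersionStrategy("tagwise-squeeze", prior_df=1e12)
        )
        assert np.ptp(tight) < 1e-6
        assert np.std(loose) > np.std(tight)

    def test_max_parametric_never_below_per_transcript_estimate(self, small_population):
        cm = simulate_counts(small_population, 3, seed=7)
        final = estimate_dispersions(cm, cm.condition, DispersionStrategy("max-parametric"))
        masks = [cm.condition == "control", cm.condition == "treatment"]
        per = _argmax_phi_per_transcript(
            lambda p: _conditional_ll(cm.counts, masks, p), cm.n_transcripts
        )
        assert np.all(final >= per - 1e-9)
        # where the per-transcript estimate exceeds the trend it is kept
        raised = final > per + 1e-9
        assert 0 < raised.sum() < len(final)
        assert np.any(np.isclose(final, per, rtol=1e-9) & (per > 1e-6))

    def test_powerlaw_forces_all_onto_curve(self, small_population):
        cm = simulate_counts(small_population, 3, seed=8)
        out = estimate_dispersions(cm, cm.condition, DispersionStrategy("powerlaw"))
        mu = cm.counts.mean(axis=1)
        ok = mu > 0
        slope = np.polyfit(np.log(mu[ok]), np.log(out[ok]), 1)
        # perfectly collinear in log-log space
        resid = np.log(out[ok]) - np.polyval(slope, np.log(mu[ok]))
        assert np.max(np.abs(resid)) < 1e-8


class TestRunDeTest:
    def test_duplicate_lanes_as_both_conditions_give_p_one(self):
        rng = np.random.default_rng(9)
        lane = rng.poisson(20, size=300)
        mat = np.column_stack([lane, lane, lane, lane])
        cond = np.array(["control", "treatment", "control", "treatment"])
        frame = run_de_test(mat, cond, strategy="max-parametric")
        np.testing.assert_allclose(frame["p_value"], 1.0)

    def test_output_shape_and_monotone_adjustment(self, small_population):
        cm = simulate_counts(small_population, 2, seed=10)
        frame = run_de_test(cm, strategy="tagwise-squeeze")
        assert len(frame) == cm.n_transcripts
        assert np.all(frame["p_adj"] >= frame["p_value"] - 1e-12)
        assert set(frame.columns) >= {
            "transcript_id",
            "p_value",
            "p_adj",
            "fold_change",
            "dispersion_used",
            "mean_control",
            "mean_treatment",
        }

    def test_null_fpr_ordering_of_strategies(self, small_population):
        """On shared null datasets at small n the strategies reproduce the
        conservative-to-liberal ordering: max-parametric <= tagwise-squeeze
        <= powerlaw."""
        for n, seed in ((2, 21), (3, 22)):
            cm = simulate_counts(small_population, n, seed=seed)
            vals = {}
            for s in ("max-parametric", "tagwise-squeeze", "powerlaw"):
                d = estimate_dispersions(cm, cm.condition, DispersionStrategy(s))
                vals[s] = fpr_null(exact_nb_test(cm, cm.condition, d), 1.0)
            assert vals["max-parametric"] <= vals["tagwise-squeeze"] <= vals["powerlaw"]

    def test_model_results_summary(self, small_population):
        cm = simulate_counts(small_population, 2, seed=11)
        res = ExactNBTest(cm, strategy="deseq").fit()
        text = res.summary()
        assert "max-parametric" in text
        assert str(cm.n_transcripts) in text
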