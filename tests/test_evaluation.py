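"""Reliability, FEVE, correlation and sparseness estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pointreadout.evaluation import (explainable_variance_ratio, feve,
                                     filter_reliable, mean_test_correlation,
                                     noise_variance, population_selectivity,
                                     score_model,
                                     selectivity_index, total_variance)


def poisson_test_counts(rates, repeats, seed=0):
    rng = np.random.default_rng(seed)
    lam = np.broadcast_to(rates[:, None, :],
                          (rates.shape[0], repeats, rates.shape[1]))
    return rng.poisson(lam)


class TestNoiseVariance:
    def test_identical_repeats_give_zero(self):
        counts = np.tile(np.arange(5)[:, None, None], (1, 4, 2))
        np.testing.assert_array_equal(noise_variance(counts), 0.0)

    def test_hand_arithmetic_two_repeats(self):
        # one image, repeats {0, 2}: unbiased variance 2
        counts = np.array([[[0], [2]]])
        assert noise_variance(counts)[0] == pytest.approx(2.0)

    def test_poisson_noise_variance_near_rate(self, rng):
        rates = np.full((75, 3), 5.0)
        counts = poisson_test_counts(rates, 45, seed=1)
        np.testing.assert_allclose(noise_variance(counts), 5.0, atol=0.35)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            noise_variance(np.zeros((5, 1, 2)))


class TestExplainableVariance:
    def test_noiseless_responses_have_ev_one(self):
        counts = np.tile(np.arange(6)[:, None, None], (1, 3, 2))
        np.testing.assert_allclose(explainable_variance_ratio(counts), 1.0)

    def test_no_signal_gives_ev_near_zero(self, rng):
        rates = np.full((75, 20), 4.0)   # identical mean across images
        counts = poisson_test_counts(rates, 45, seed=2)
        ev = explainable_variance_ratio(counts)
        assert abs(np.mean(ev)) < 0.02

    def test_known_signal_noise_ratio(self, rng):
        # Gaussian responses: signal variance 1, noise variance 3 -> EV 0.25
        signal = rng.normal(0, 1.0, size=(400, 10))
        noise = rng.normal(0, np.sqrt(3.0), size=(400, 50, 10))
        counts = signal[:, None, :] + noise
        ev = explainable_variance_ratio(counts)
        assert np.mean(ev) == pytest.approx(0.25, abs=0.03)

    def test_zero_total_variance_flagged(self):
        with pytest.warns(UserWarning):
            ev = explainable_variance_ratio(np.zeros((4, 3, 1)))
        assert np.isnan(ev[0])


class TestFilterReliable:
    def test_threshold_is_strict_below(self):
        # "below 0.15 removed": exactly 0.15 is retained
        kept = filter_reliable(np.array([0.10, 0.15, 0.20]))
        np.testing.assert_array_equal(kept, [1, 2])

    def test_all_below_gives_empty(self):
        assert filter_reliable(np.array([0.0, 0.1])).size == 0

    def test_matches_brute_force_recount(self, rng):
        ev = rng.uniform(-0.5, 1.0, 1000)
        kept = filter_reliable(ev)
        brute = [i for i, v in enumerate(ev) if not v < 0.15]
        np.testing.assert_array_equal(kept, brute)


class TestFeve:
    def test_perfect_predictions_on_noiseless_data(self):
        counts = np.tile(np.arange(1, 7, dtype=float)[:, None, None], (1, 3, 2))
        preds = counts[:, 0, :]
        np.testing.assert_allclose(feve(preds, counts), 1.0)

    def test_grand_mean_prediction_scores_zero(self, rng):
        rates = rng.uniform(1, 9, size=(75, 10))
        counts = poisson_test_counts(rates, 200, seed=3)
        preds = np.full_like(rates, counts.mean())
        assert np.mean(feve(preds, counts)) == pytest.approx(0.0, abs=0.03)

    def test_oracle_predictor_approaches_one(self, rng):
        rates = rng.uniform(1, 9, size=(75, 10))
        counts = poisson_test_counts(rates, 45, seed=4)
        assert np.mean(feve(rates, counts)) == pytest.approx(1.0, abs=0.03)

    def test_undefined_when_no_explainable_variance(self, rng):
        rates = np.full((20, 3), 4.0)
        counts = poisson_test_counts(rates, 10, seed=5)
        with pytest.warns(UserWarning):
            out = feve(rates.copy(), counts)
        assert np.isnan(out).any()


class TestCorrelation:
    def test_affine_predictions_score_one(self, rng):
        counts = poisson_test_counts(rng.uniform(1, 9, (30, 4)), 20, seed=6)
        target = counts.mean(axis=1)
        np.testing.assert_allclose(
            mean_test_correlation(2.0 * target + 3.0, counts), 1.0)

    def test_negated_predictions_score_minus_one(self, rng):
        counts = poisson_test_counts(rng.uniform(1, 9, (30, 4)), 20, seed=6)
        target = counts.mean(axis=1)
        np.testing.assert_allclose(
            mean_test_correlation(-target, counts), -1.0)

    def test_random_predictions_score_near_zero(self, rng):
        counts = poisson_test_counts(rng.uniform(1, 9, (75, 200)), 10, seed=7)
        preds = rng.normal(size=(75, 200))
        r = mean_test_correlation(preds, counts)
        assert abs(np.mean(r)) < 0.02
        assert np.percentile(np.abs(r), 95) < 0.3

    def test_zero_variance_prediction_is_missing(self, rng):
        counts = poisson_test_counts(rng.uniform(1, 9, (30, 2)), 5, seed=8)
        preds = np.ones((30, 2))
        assert np.isnan(mean_test_correlation(preds, counts)).all()


class TestSelectivityIndex:
    def test_uniform_grid_gives_si_near_zero(self):
        res = selectivity_index(np.linspace(0, 1, 100_000))
        assert res.area == pytest.approx(0.5, abs=1e-3)
        assert res.si == pytest.approx(0.0, abs=2e-3)

    def test_single_responsive_image_is_sparse(self):
        r = np.zeros(200)
        r[17] = 5.0
        assert selectivity_index(r).si > 0.95

    def test_matches_brute_force_threshold_oracle(self, rng):
        r = rng.gamma(2.0, 2.0, size=500)
        res = selectivity_index(r)
        ts = np.linspace(r.min(), r.max(), 100)
        fracs = [np.sum(r > t) / r.size for t in ts]
        assert res.area == pytest.approx(float(np.mean(fracs)), abs=1e-12)
        assert res.si == pytest.approx(1 - 2 * float(np.mean(fracs)), abs=1e-12)

    def test_constant_responses_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index(np.full(10, 3.0))

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.1, 50), shift=st.floats(-10, 10),
           seed=st.integers(0, 100))
    def test_invariant_to_positive_affine_rescaling(self, scale, shift, seed):
        r = np.random.default_rng(seed).gamma(1.5, 1.0, size=80)
        if r.max() <= r.min():
            return
        a = selectivity_index(r).si
        b = selectivity_index(scale * r + shift).si
        assert a == pytest.approx(b, abs=1e-9)


def test_score_model_bundles_consistent_summaries(rng):
    rates = rng.uniform(1, 9, size=(40, 6))
    counts = poisson_test_counts(rates, 30, seed=9)
    score = score_model(rates, counts)
    assert score.mean_correlation == pytest.approx(np.nanmean(score.correlation))
    # the noise-corrected estimator can exceed 1 only by sampling error
    assert (score.feve <= 1.0 + 0.05).all()


def test_population_selectivity_handles_constant_neurons(rng):
    responses = rng.uniform(0, 5, size=(50, 3))
    responses[:, 1] = 2.0
    si = population_selectivity(responses)
    assert np.isnan(si[1]) and np.isfinite(si[[0, 2]]).all()
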