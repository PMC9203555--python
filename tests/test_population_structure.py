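"""Tests for log-log slope fits and the variational Gaussian mixture."""

import numpy as np
import pandas as pd
import pytest

from dnakflow.errors import ValidationError
from dnakflow.kinetics import KineticParams
from dnakflow.population_structure import (MixtureConfig, effective_components,
                                           fit_mixture, loglog_slope,
                                           subpopulation_report)
from dnakflow.synthetic_data import TimepointSample, simulate_population
from dnakflow.variants import VariantSpec


def make_sample(red, green):
    n = len(red)
    return TimepointSample("v", 1, 0.0, pd.DataFrame(
        {"fsc": np.ones(n), "ssc": np.ones(n), "red": red, "green": green}))


class TestLoglogSlope:
    def test_constant_ratio_gives_slope_one(self):
        red = np.array([10.0, 100.0, 1000.0, 50.0])
        fit = loglog_slope(make_sample(red, 3.0 * red))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(np.log10(3.0))

    def test_constant_green_gives_slope_zero(self):
        red = np.array([10.0, 100.0, 1000.0])
        fit = loglog_slope(make_sample(red, np.full(3, 42.0)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_normal_equations(self):
        red = np.array([100.0, 200.0, 400.0, 800.0])
        green = np.array([300.0, 500.0, 1000.0, 1500.0])
        fit = loglog_slope(make_sample(red, green))
        # frozen values from an independent normal-equations evaluation
        assert fit.slope == pytest.approx(0.7965784284662041, rel=1e-12)
        assert fit.intercept == pytest.approx(0.8851977712946288, rel=1e-12)

    def test_requires_three_positive_events(self):
        with pytest.raises(ValidationError):
            loglog_slope(make_sample(np.array([1.0, 2.0]), np.array([1.0, 2.0])))

    def test_slope_one_iff_constant_ratio(self):
        rng = np.random.default_rng(3)
        red = rng.lognormal(5, 0.5, 200)
        fit = loglog_slope(make_sample(red, 2.5 * red))
        resid = np.log10(2.5 * red) - (fit.slope * np.log10(red) + fit.intercept)
        assert fit.slope == pytest.approx(1.0) and np.allclose(resid, 0.0)


def two_blob_data(seed, n=2000, sep_sd=8.0, sd=0.1):
    rng = np.random.default_rng(seed)
    half = n // 2
    a = rng.normal([2.0, 2.0], sd, size=(half, 2))
    b = rng.normal([2.0 + sep_sd * sd, 2.0 + sep_sd * sd], sd, size=(n - half, 2))
    return np.vstack([a, b])


class TestFitMixture:
    def test_single_cluster_prunes_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal([2.5, 3.0], 0.05, size=(2000, 2))
        fit = fit_mixture(x, seed=1)
        assert effective_components(fit) == 1
        assert fit.weights.max() > 0.99

    def test_two_separated_clusters_recovered(self):
        x = two_blob_data(seed=5)
        fit = fit_mixture(x, seed=5)
        assert effective_components(fit) == 2
        top = np.sort(fit.weights)[::-1][:2]
        assert np.all(np.abs(top - 0.5) < 0.05)
        idx = np.argsort(fit.weights)[::-1][:2]
        means = fit.means[idx][np.argsort(fit.means[idx][:, 0])]
        assert np.all(np.abs(means[0] - [2.0, 2.0]) < 0.5 * 0.1)
        assert np.all(np.abs(means[1] - [2.8, 2.8]) < 0.5 * 0.1)

    def test_seeded_determinism(self):
        x = two_blob_data(seed=9)
        f1 = fit_mixture(x, seed=3)
        f2 = fit_mixture(x, seed=3)
        assert f1.elbo == f2.elbo
        assert np.array_equal(f1.responsibilities, f2.responsibilities)

    def test_elbo_monotone_nondecreasing(self):
        x = two_blob_data(seed=11, n=1000)
        fit = fit_mixture(x, seed=11)
        gains = np.diff(fit.elbo_trace)
        assert gains.min() >= -1e-8 * max(1.0, abs(fit.elbo))

    def test_invariants_of_fit(self):
        x = two_blob_data(seed=13, n=500)
        fit = fit_mixture(x, seed=13)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fit.variances > 0)
        assert fit.responsibilities.sum(axis=1) == pytest.approx(
            np.ones(500), abs=1e-9)

    def test_dataframe_input_log_transforms(self):
        rng = np.random.default_rng(17)
        red = rng.lognormal(6, 0.2, 600)
        green = rng.lognormal(6.5, 0.2, 600)
        sample = make_sample(red, green)
        fit = fit_mixture(sample.events, MixtureConfig(n_init=2), seed=2)
        assert effective_components(fit) == 1
        k = int(np.argmax(fit.weights))
        assert fit.means[k][0] == pytest.approx(np.log10(red).mean(), abs=0.05)
        assert fit.means[k][1] == pytest.approx(np.log10(green).mean(), abs=0.05)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValidationError):
            fit_mixture(np.zeros((5, 2)), seed=0)

    def test_agreement_with_sklearn_reference(self):
        """Independent cross-check: scikit-learn's variational mixture on
        the same data finds the same structure (weights and means)."""
        from sklearn.mixture import BayesianGaussianMixture
        x = two_blob_data(seed=21)
        fit = fit_mixture(x, seed=21)
        ref = BayesianGaussianMixture(
            n_components=7, covariance_type="diag",
            weight_concentration_prior_type="dirichlet_distribution",
            weight_concentration_prior=1e-6, max_iter=500, n_init=3,
            random_state=0).fit(x)
        ours = np.sort(fit.weights)[::-1][:2]
        theirs = np.sort(ref.weights_)[::-1][:2]
        assert np.all(np.abs(ours - theirs) < 0.05)
        our_means = fit.means[np.argsort(fit.weights)[::-1][:2]]
        their_means = ref.means_[np.argsort(ref.weights_)[::-1][:2]]
        assert np.allclose(np.sort(our_means[:, 0]),
                           np.sort(their_means[:, 0]), atol=0.05)


class TestEffectiveComponents:
    def _fit_with_weights(self, w):
        fit = fit_mixture(two_blob_data(seed=1, n=200), MixtureConfig(n_init=1),
                          seed=1)
        fit.weights = np.asarray(w, dtype=float)
        return fit

    def test_dominant_plus_trace(self):
        assert effective_components(self._fit_with_weights(
            [0.99, 0.009, 0, 0, 0, 0, 0.001])) == 1

    def test_uniform_seven(self):
        assert effective_components(self._fit_with_weights([1 / 7] * 7)) == 7

    def test_floor_four(self):
        w = [0.6, 0.3, 0.05, 0.05, 1e-6, 1e-6, 1e-6]
        assert effective_components(self._fit_with_weights(w),
                                    weight_floor=0.04) == 4

    def test_label_permutation_invariance(self):
        fit = fit_mixture(two_blob_data(seed=2, n=400), seed=2)
        perm = np.random.default_rng(0).permutation(len(fit.weights))
        permuted = fit_mixture(two_blob_data(seed=2, n=400), seed=2)
        permuted.weights = fit.weights[perm]
        assert effective_components(permuted) == effective_components(fit)


class TestSubpopulationReport:
    def test_single_component_all_flags_false(self):
        fits = {t: fit_mixture(two_blob_data(seed=1, n=400, sep_sd=0.0),
                               seed=1) for t in (0.0, 90.0)}
        report = subpopulation_report(fits)
        assert not report["low_red"].any()
        assert (report["n_effective"] == 1).all()

    def test_toxicity_switch_creates_late_low_red_component(self):
        """With the toxicity switch on, high-load cells stop synthesising
        and fall behind in red: a low-red component must appear late."""
        variant = VariantSpec("wt", 55.0, is_wild_type=True)
        params = KineticParams(toxicity_enabled=True, toxicity_threshold=2500.0,
                               noise_cv=0.05)
        schedule = np.array([0.0, 120.0, 240.0])
        samples, _ = simulate_population(variant, params, n_cells=400,
                                         replicate_seed=4, schedule=schedule)
        fits = {s.time_min: fit_mixture(s.events, MixtureConfig(n_init=3),
                                        seed=8)
                for s in samples}
        report = subpopulation_report(fits)
        late = report[(report["time_min"] == 240.0) & ~report["is_main"]]
        assert late["low_red"].any()

    def test_deterministic_repeat(self):
        fits = {0.0: fit_mixture(two_blob_data(seed=3, n=300), seed=3)}
        r1 = subpopulation_report(fits)
        r2 = subpopulation_report(fits)
        pd.testing.assert_frame_equal(r1, r2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            subpopulation_report({})
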