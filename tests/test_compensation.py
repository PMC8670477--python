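import numpy as np
import pytest
from scipy.stats import ks_2samp, pearsonr, skew

from mbmodel.compensation import (
    ConvergenceError,
    FittingError,
    HomeostasisConfig,
    apply_activity_independent,
    fit_conditional_weight_components,
    homeostatic_tune,
    negative_alpha_fraction,
    tune_threshold_response_prob,
)
from mbmodel.network import (
    ModelSpec,
    ParamDistributions,
    calibrate,
    coding_level,
    kc_response,
    sample_population,
)


@pytest.fixture(scope="module")
def sampler(dists):
    return fit_conditional_weight_components(dists, rng_seed=0)


@pytest.fixture(scope="module")
def tuning_x(small_panel, noisy_trials):
    return noisy_trials.reshape(24, -1)


def mean_activity(pop, x, inhibition_on=True):
    return kc_response(pop, x, inhibition_on=inhibition_on).flat().mean(axis=1)


class TestConditionalWeightSampler:
    def test_degenerate_single_component_equals_target(self):
        # N and theta effectively fixed -> the one component IS target P(w)
        dists = ParamDistributions(n_sd=0.0, theta_cv=1e-9)
        s = fit_conditional_weight_components(dists, rng_seed=1)
        med = s.component_median(np.array([6]), np.array([dists.theta_mean]))
        assert med[0] == pytest.approx(np.exp(dists.w_mu_log), rel=0.01)
        assert s.sigma_log == pytest.approx(dists.w_sigma_log, rel=0.01)

    def test_high_n_component_below_low_n(self, sampler, dists):
        theta = dists.theta_mean
        m7 = sampler.component_median(np.array([7]), np.array([theta]))
        m2 = sampler.component_median(np.array([2]), np.array([theta]))
        assert m7[0] < m2[0]

    def test_component_median_increases_with_theta(self, sampler):
        lo = sampler.component_median(np.array([6]), np.array([7.0]))
        hi = sampler.component_median(np.array([6]), np.array([13.0]))
        assert lo[0] < hi[0]

    def test_pooled_mixture_matches_target(self, sampler, dists):
        """10^5 draws over the joint (N, theta) population vs the target
        log-normal: two-sample KS below 0.02."""
        rng = np.random.default_rng(2)
        n = 100_000
        N = dists.sample_n(n, rng)
        theta = dists.sample_theta(n, rng)
        pooled = sampler.component_median(N, theta) * rng.lognormal(
            0.0, sampler.sigma_log, n
        )
        target = rng.lognormal(dists.w_mu_log, dists.w_sigma_log, n)
        assert ks_2samp(pooled, target).statistic < 0.02

    def test_too_narrow_target_fails(self):
        with pytest.raises(FittingError):
            fit_conditional_weight_components(
                ParamDistributions(w_sigma_log=0.05), rng_seed=3
            )


class TestActivityIndependent:
    def test_planted_correlations(self, sampler, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=2000
        )
        pop = sample_population(spec, dists, 24, rng_seed=4)
        out = apply_activity_independent(pop, sampler, rng_seed=5)
        r_n = pearsonr(out.mean_w, out.claw_counts).statistic
        r_t = pearsonr(out.mean_w, out.theta).statistic
        assert r_n < -0.2
        assert r_t > 0.1

    def test_topology_and_other_params_untouched(self, sampler, dists, small_random_spec):
        pop = sample_population(small_random_spec, dists, 24, rng_seed=6)
        out = apply_activity_independent(pop, sampler, rng_seed=7)
        assert np.array_equal(out.pn_index, pop.pn_index)
        assert np.array_equal(out.theta, pop.theta)
        assert np.array_equal(out.alpha, pop.alpha)
        assert not np.allclose(out.weights, pop.weights)

    def test_fixed_n_theta_population_recovers_unconditional(self, dists):
        dfix = ParamDistributions(n_sd=0.0, theta_cv=1e-9)
        s = fit_conditional_weight_components(dfix, rng_seed=8)
        spec = ModelSpec(variable_w=True, n_kc=3000)
        pop = sample_population(spec, dfix, 24, rng_seed=9)
        out = apply_activity_independent(pop, s, rng_seed=10)
        w = out.weights[out.pn_index >= 0]
        target = np.random.default_rng(11).lognormal(
            dfix.w_mu_log, dfix.w_sigma_log, w.size
        )
        assert ks_2samp(w, target).statistic < 0.03


class TestHomeostaticTune:
    @pytest.mark.parametrize("target", ["w", "theta", "alpha"])
    def test_every_kc_within_tolerance(self, target, small_panel, tuning_x, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=400
        )
        pop = sample_population(spec, dists, 24, rng_seed=12)
        pop = calibrate(pop, small_panel.rates, spec)
        cfg = HomeostasisConfig(target=target)
        tuned = homeostatic_tune(pop, tuning_x, cfg, spec=spec)
        a = mean_activity(tuned, tuning_x)
        A0 = tuned.meta["A0"]
        assert np.all(np.abs(a - A0) <= cfg.tolerance * A0 + 1e-9)
        # cross-KC variation of mean activity within the tolerance
        assert a.std() / a.mean() <= cfg.tolerance

    @pytest.mark.parametrize("target", ["w", "theta", "alpha"])
    def test_untargeted_parameters_untouched(self, target, small_panel, tuning_x, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=300
        )
        pop = sample_population(spec, dists, 24, rng_seed=13)
        pop = calibrate(pop, small_panel.rates, spec)
        tuned = homeostatic_tune(
            pop, tuning_x, HomeostasisConfig(target=target), spec=spec
        )
        assert np.array_equal(tuned.pn_index, pop.pn_index)
        if target != "w":
            assert np.array_equal(tuned.weights, pop.weights)
        if target != "theta":
            assert np.array_equal(tuned.theta, pop.theta)
        if target != "alpha":
            assert np.array_equal(tuned.alpha, pop.alpha)

    def test_weight_tuning_preserves_topology_scales_magnitudes(
        self, small_panel, tuning_x, dists
    ):
        spec = ModelSpec(variable_w=True, variable_N=True, n_kc=300)
        pop = sample_population(spec, dists, 24, rng_seed=14)
        pop = calibrate(pop, small_panel.rates, spec)
        tuned = homeostatic_tune(pop, tuning_x, HomeostasisConfig(target="w"), spec=spec)
        # per-KC weights are a common positive rescaling of the originals
        mask = pop.pn_index >= 0
        ratio = np.where(mask, tuned.weights / np.where(mask, pop.weights, 1.0), np.nan)
        spread = np.nanmax(ratio, axis=1) - np.nanmin(ratio, axis=1)
        assert np.nanmax(spread) < 1e-9

    def test_already_equalized_is_fixed_point(self, small_panel, tuning_x, dists):
        spec = ModelSpec(n_kc=300, variable_theta=True, variable_w=True, variable_N=True)
        pop = sample_population(spec, dists, 24, rng_seed=15)
        pop = calibrate(pop, small_panel.rates, spec)
        cfg = HomeostasisConfig(target="theta")
        once = homeostatic_tune(pop, tuning_x, cfg, spec=spec)
        again = homeostatic_tune(
            once, tuning_x,
            HomeostasisConfig(target="theta", A0=once.meta["A0"]),
            spec=spec,
        )
        assert np.allclose(again.theta, once.theta, atol=1e-6 * np.abs(once.theta).max())

    def test_coding_level_held_near_target(self, small_panel, tuning_x, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=400
        )
        pop = sample_population(spec, dists, 24, rng_seed=16)
        pop = calibrate(pop, small_panel.rates, spec)
        tuned = homeostatic_tune(pop, tuning_x, HomeostasisConfig(target="w"), spec=spec)
        cl = coding_level(kc_response(tuned, tuning_x))
        assert cl == pytest.approx(spec.coding_level, abs=0.01)

    def test_emergent_tuned_w_right_skewed_unimodal(self, small_panel, tuning_x, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=500
        )
        pop = sample_population(spec, dists, 24, rng_seed=17)
        pop = calibrate(pop, small_panel.rates, spec)
        tuned = homeostatic_tune(pop, tuning_x, HomeostasisConfig(target="w"), spec=spec)
        w = tuned.weights[tuned.pn_index >= 0]
        assert skew(w) > 0.5
        hist, _ = np.histogram(np.log(w), bins=12)
        peak = np.argmax(hist)
        assert 0 < peak < 11  # interior mode

    def test_emergent_tuned_theta_wider_than_input(self, small_panel, tuning_x, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=500
        )
        pop = sample_population(spec, dists, 24, rng_seed=18)
        pop = calibrate(pop, small_panel.rates, spec)
        tuned = homeostatic_tune(
            pop, tuning_x, HomeostasisConfig(target="theta"), spec=spec
        )
        assert tuned.theta.std() > pop.theta.std()


class TestResponseProbabilityTuning:
    def test_all_probabilities_near_target(self, small_panel, tuning_x, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=400
        )
        pop = sample_population(spec, dists, 24, rng_seed=19)
        pop = calibrate(pop, small_panel.rates, spec)
        tuned = tune_threshold_response_prob(pop, tuning_x, spec=spec)
        prob = (kc_response(tuned, tuning_x).flat() > 0).mean(axis=1)
        n_samples = tuning_x.shape[1]
        assert np.all(np.abs(prob - spec.coding_level) <= 1.0 / n_samples + 1e-9)

    def test_silent_kc_brought_to_respond(self, small_panel, tuning_x, dists):
        spec = ModelSpec(n_kc=300, variable_theta=True)
        pop = sample_population(spec, dists, 24, rng_seed=20)
        pop = calibrate(pop, small_panel.rates, spec)
        pop.theta[0] = 1e9  # force one silent KC
        tuned = tune_threshold_response_prob(pop, tuning_x, spec=spec)
        prob0 = (kc_response(tuned, tuning_x).flat()[0] > 0).mean()
        assert prob0 > 0


class TestNegativeAlpha:
    def test_all_nonnegative_gives_zero(self, calibrated_homog):
        assert negative_alpha_fraction(calibrated_homog) == 0.0

    def test_alpha_tuning_under_threshold_sparseness_needs_negatives(
        self, small_panel, tuning_x, dists
    ):
        """With coding level 0.2 without inhibition (high thresholds), equalizing
        activity through inhibition alone forces many alpha below zero."""
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=400
        )
        pop = sample_population(spec, dists, 24, rng_seed=21)
        pop = calibrate(pop, small_panel.rates, spec)
        tuned = homeostatic_tune(
            pop, tuning_x,
            HomeostasisConfig(target="alpha", allow_negative_alpha=True),
            spec=spec,
        )
        assert negative_alpha_fraction(tuned) > 0.2

    def test_inhibition_only_sparseness_avoids_negatives(self, small_panel, tuning_x, dists):
        """With thresholds at zero (sparseness from inhibition alone), the
        non-negativity constraint is nearly free and the no-inhibition coding
        level approaches one."""
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=400
        )
        pop = sample_population(spec, dists, 24, rng_seed=22)
        pop.theta = np.zeros_like(pop.theta)
        pop = calibrate(pop, small_panel.rates, spec, stages=("alpha",))
        tuned = homeostatic_tune(
            pop, tuning_x,
            HomeostasisConfig(
                target="alpha", allow_negative_alpha=False, raise_on_failure=False
            ),
            spec=spec,
        )
        assert tuned.meta["tuning_fraction_out"] < 0.05
        cl_no_inh = coding_level(kc_response(tuned, small_panel.rates, inhibition_on=False))
        assert cl_no_inh > 0.9

    def test_clamped_tuning_reports_failure(self, small_panel, tuning_x, dists):
        spec = ModelSpec(
            variable_w=True, variable_N=True, variable_theta=True, n_kc=300
        )
        pop = sample_population(spec, dists, 24, rng_seed=23)
        pop = calibrate(pop, small_panel.rates, spec)
        with pytest.raises(ConvergenceError) as exc:
            homeostatic_tune(
                pop, tuning_x,
                HomeostasisConfig(target="alpha", allow_negative_alpha=False),
                spec=spec,
            )
        assert exc.value.fraction_out > 0
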