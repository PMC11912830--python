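"""Unit tests for penalties, the penalized fit, alpha selection and bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transectne import (ChromosomeMap, IBDHistogram, LengthGrid, NeTrajectory,
                        PenaltyConfig, SampleSet, SamplingScheme, bootstrap_ci,
                        constant_ne_density, decay_weights, fit_constant_ne,
                        fit_trajectory, haplotype_pair_count,
                        initialize_trajectory, objective, penalty_curvature,
                        penalty_decayed_diff, sample_ibd_from_model,
                        select_alpha)
from transectne.likelihood import PoissonIBDModel
from transectne.optimize import _penalty_value_grad


class TestPenalties:
    def test_affine_sequences_have_zero_curvature(self):
        t = np.arange(20)
        assert penalty_curvature(3.5 - 0.2 * t) == pytest.approx(0.0, abs=1e-24)

    def test_hat_sequence(self):
        assert penalty_curvature([0.0, 1.0, 0.0]) == pytest.approx(4.0)

    def test_matches_convolution_oracle(self, rng):
        x = rng.normal(size=50)
        expect = np.sum(np.convolve(x, [1.0, -2.0, 1.0], mode="valid") ** 2)
        assert penalty_curvature(x) == pytest.approx(expect, rel=1e-12)

    def test_curvature_needs_three_points(self):
        with pytest.raises(ValueError):
            penalty_curvature([1.0, 2.0])

    def test_decay_weight_values(self):
        w = decay_weights(30)
        assert w[30] == pytest.approx(1.0)
        assert w[20] == pytest.approx(np.exp(-0.5))
        assert w[0] == pytest.approx(np.exp(-4.5))
        assert np.all(np.diff(w) > 0)
        # w_0 is independent of the horizon
        assert decay_weights(173)[0] == pytest.approx(np.exp(-4.5))

    def test_decayed_diff_examples(self):
        assert penalty_decayed_diff([5.0, 5.0, 5.0], np.ones(3)) == 0.0
        assert penalty_decayed_diff([0.0, 1.0], np.array([0.3, 1.0])) == 1.0

    @settings(derandomize=True, max_examples=20)
    @given(st.floats(min_value=-5, max_value=5))
    def test_penalties_scale_quadratically(self, c):
        x = np.array([0.1, -0.4, 0.7, 0.2, -0.9])
        w = decay_weights(4)
        assert penalty_decayed_diff(c * x, w) == pytest.approx(
            c**2 * penalty_decayed_diff(x, w), abs=1e-9)
        assert penalty_curvature(c * x) == pytest.approx(
            c**2 * penalty_curvature(x), abs=1e-9)

    def test_invariant_to_constant_shift(self, rng):
        # adding a constant to log Ne changes neither penalty
        x = rng.normal(size=30)
        w = decay_weights(29)
        assert penalty_curvature(x + 3.7) == pytest.approx(penalty_curvature(x))
        assert penalty_decayed_diff(x + 3.7, w) == pytest.approx(
            penalty_decayed_diff(x, w))

    def test_penalty_gradient_matches_finite_differences(self, rng):
        x = rng.normal(size=25)
        w = decay_weights(24)
        alpha, beta = 3.0, 7.0
        p1, p2, g = _penalty_value_grad(x, alpha, beta, w)

        def f(y):
            a, b, _ = _penalty_value_grad(y, alpha, beta, w)
            return a + b

        eps = 1e-7
        for i in range(0, 25, 3):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            assert g[i] == pytest.approx((f(xp) - f(xm)) / (2 * eps), rel=1e-4,
                                         abs=1e-8)


def _sampled_setup(seed=9, ne_val=10000.0, G=60, sizes=(20, 20), times=(0, 15)):
    grid = LengthGrid.from_cm(8, 20, 0.25)
    chroms = ChromosomeMap.default_autosomes()
    scheme = SamplingScheme([SampleSet(t, n) for t, n in zip(times, sizes)])
    ne = NeTrajectory.constant(ne_val, scheme.tmax(G))
    hist = sample_ibd_from_model(ne, scheme, grid, chroms, G, seed=seed)
    return hist, scheme, grid, chroms, ne, G


class TestObjective:
    def test_zero_penalties_reduce_to_neg_loglik(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        from transectne import composite_loglik
        val = objective(ne, hist, scheme, grid, chroms, G, PenaltyConfig(0.0, 0.0))
        assert val == pytest.approx(
            -composite_loglik(hist, ne, scheme, grid, chroms, G), rel=1e-12)

    def test_constant_trajectory_has_zero_penalty(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        a = objective(ne, hist, scheme, grid, chroms, G, PenaltyConfig(0.0, 0.0))
        b = objective(ne, hist, scheme, grid, chroms, G, PenaltyConfig(1e6, 1e6))
        assert a == pytest.approx(b)

    def test_breakdown_terms_sum_to_objective(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        fit = fit_trajectory(hist, scheme, grid, chroms, PenaltyConfig(50.0),
                             G=G, seed=0, maxiter=60)
        assert fit.objective == pytest.approx(
            fit.neg_loglik + fit.curvature_penalty + fit.diff_penalty, abs=1e-8)


class TestFitConstantNe:
    def test_recovers_truth_from_closed_form_sampling(self):
        # Poisson data at the closed-form constant-Ne rates, large nhap
        rng = np.random.default_rng(77)
        scheme = SamplingScheme([SampleSet(0, 80), SampleSet(10, 60)])
        grid = LengthGrid.from_cm(8, 20, 0.25)
        chroms = ChromosomeMap.default_autosomes()
        Ne = 25000.0
        hist = IBDHistogram.empty(scheme, grid, chroms)
        for p, (i, j) in enumerate(scheme.pair_indices()):
            ctx = scheme.context(i, j)
            nhap = haplotype_pair_count(scheme.sets[i],
                                        scheme.sets[j] if i != j else None)
            for c, lab in enumerate(chroms.labels):
                lam = nhap * grid.dl * constant_ne_density(
                    grid.midpoints, ctx.dt, Ne, chroms[lab])
                hist.counts[p, c] = rng.poisson(lam)
        est = fit_constant_ne(hist, scheme, grid, chroms)
        assert est == pytest.approx(Ne, rel=0.05)

    def test_more_sharing_means_smaller_estimate(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        est = fit_constant_ne(hist, scheme, grid, chroms)
        doubled = IBDHistogram(hist.counts * 2, hist.pairs, hist.chromosomes,
                               grid)
        assert fit_constant_ne(doubled, scheme, grid, chroms) < est

    def test_invariant_to_bin_order(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        est = fit_constant_ne(hist, scheme, grid, chroms)
        assert est == pytest.approx(fit_constant_ne(hist, scheme, grid, chroms))

    def test_empty_histogram_raises_with_guidance(self):
        grid = LengthGrid.from_cm(8, 20, 0.25)
        chroms = ChromosomeMap.default_autosomes()
        scheme = SamplingScheme([SampleSet(0, 5)])
        hist = IBDHistogram.empty(scheme, grid, chroms)
        with pytest.raises(ValueError, match="no segments"):
            fit_constant_ne(hist, scheme, grid, chroms)


class TestInitializeTrajectory:
    def test_deterministic_given_seed(self):
        a = initialize_trajectory(5000.0, 100, seed=3)
        b = initialize_trajectory(5000.0, 100, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_scale_is_one_twentieth(self):
        vals = initialize_trajectory(5000.0, 10**5, seed=0).values
        eps = vals - 5000.0
        se = (5000.0 / 20) / np.sqrt(eps.size)
        assert abs(eps.mean()) < 3 * se
        assert eps.std() == pytest.approx(250.0, rel=0.02)

    def test_all_entries_positive(self):
        vals = initialize_trajectory(30.0, 10**4, seed=1).values
        assert np.all(vals > 0)


class TestFitTrajectory:
    def test_constant_truth_recovered_within_30pct(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        fit = fit_trajectory(hist, scheme, grid, chroms, PenaltyConfig(100.0),
                             G=G, seed=2)
        ratio = fit.trajectory.values[:51] / 10000.0
        assert ratio.min() > 0.7 and ratio.max() < 1.3
        assert fit.converged

    def test_final_objective_not_above_initial(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        cfg = PenaltyConfig(50.0)
        init = initialize_trajectory(8000.0, scheme.tmax(G), seed=5)
        fit = fit_trajectory(hist, scheme, grid, chroms, cfg, G=G, seed=5,
                             init_trajectory=init)
        assert fit.objective <= objective(init, hist, scheme, grid, chroms, G,
                                          cfg) + 1e-9

    def test_huge_alpha_flattens_log_trajectory(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        fit = fit_trajectory(hist, scheme, grid, chroms, PenaltyConfig(1e8),
                             G=G, seed=2)
        assert np.abs(np.diff(np.log(fit.trajectory.values), 2)).max() < 1e-3

    def test_engine_gradient_matches_finite_differences(self, rng):
        # analytic gradient of the Poisson term vs central differences
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        model = PoissonIBDModel(hist, scheme, grid, chroms, G)
        x = np.log(ne.values) + 0.2 * rng.normal(size=len(ne))
        _, g = model.neg_loglik_grad(x)
        eps = 1e-6
        for i in range(0, x.size, 11):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num = (model.neg_loglik_grad(xp)[0] -
                   model.neg_loglik_grad(xm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_single_bin_matches_moment_inversion(self):
        # alpha = beta = 0 and a single bin: the fitted constant Ne solves
        # nhap * f(mid) * dl = mean observed count, checked via the
        # closed-form rate evaluated at the fitted value
        rng = np.random.default_rng(4)
        scheme = SamplingScheme([SampleSet(0, 50)])
        grid = LengthGrid(0.08, 0.085, 0.005)  # one bin
        chroms = ChromosomeMap({"1": 2.0})
        nhap = haplotype_pair_count(scheme.sets[0])
        Ne = 8000.0
        lam = nhap * grid.dl * constant_ne_density(grid.midpoints[0], 0, Ne, 2.0)
        hist = IBDHistogram.empty(scheme, grid, chroms)
        hist.counts[0, 0, 0] = rng.poisson(lam * 50)  # plenty of mass
        # scale counts back: treat as 50 pooled replicates by inflating nhap
        est = fit_constant_ne(hist, scheme, grid, chroms)
        fitted_rate = nhap * grid.dl * constant_ne_density(
            grid.midpoints[0], 0, est, 2.0)
        assert fitted_rate == pytest.approx(hist.counts[0, 0, 0], rel=1e-4)


class TestSelectAlpha:
    def test_constant_data_prefers_heaviest_smoothing(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup(
            seed=5, ne_val=8000.0, sizes=(15, 15), times=(0, 10))
        alpha = select_alpha(hist, scheme, grid, chroms, G=G,
                             alphas=[1e-2, 1.0, 1e2, 1e4], n_folds=3, seed=0,
                             maxiter=300)
        assert alpha == 1e4

    def test_bottleneck_data_prefers_lighter_smoothing(self):
        from transectne import bottleneck_scenario, build_scenario
        grid = LengthGrid.from_cm(8, 20, 0.25)
        chroms = ChromosomeMap.default_autosomes()
        G = 60
        scheme = SamplingScheme([SampleSet(0, 60), SampleSet(25, 60),
                                 SampleSet(35, 60)])
        truth = build_scenario(bottleneck_scenario(), scheme.tmax(G))
        hist = sample_ibd_from_model(truth, scheme, grid, chroms, G, seed=6)
        alpha = select_alpha(hist, scheme, grid, chroms, G=G,
                             alphas=[1e-2, 1.0, 1e2, 1e4], n_folds=3, seed=0,
                             maxiter=300)
        assert alpha < 1e4

    def test_same_seed_same_alpha(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup(
            seed=5, ne_val=8000.0, sizes=(15, 15), times=(0, 10))
        kwargs = dict(G=G, alphas=[1.0, 1e2], n_folds=2, seed=11, maxiter=150)
        assert select_alpha(hist, scheme, grid, chroms, **kwargs) == \
            select_alpha(hist, scheme, grid, chroms, **kwargs)

    def test_single_chromosome_is_rejected(self):
        grid = LengthGrid.from_cm(8, 20, 0.25)
        chroms = ChromosomeMap({"1": 2.0})
        scheme = SamplingScheme([SampleSet(0, 5)])
        hist = IBDHistogram.empty(scheme, grid, chroms)
        with pytest.raises(ValueError, match="manual"):
            select_alpha(hist, scheme, grid, chroms, G=20)


class TestBootstrap:
    def test_identity_resampling_reproduces_point_estimate(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        cfg = PenaltyConfig(100.0)
        base = fit_trajectory(hist, scheme, grid, chroms, cfg, G=G, seed=2)
        same = fit_trajectory(hist, scheme, grid, chroms, cfg, G=G, seed=2,
                              chrom_mult=np.ones(len(chroms)))
        np.testing.assert_array_equal(base.trajectory.values,
                                      same.trajectory.values)

    def test_envelope_is_deterministic_and_covers_truth(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        cfg = PenaltyConfig(100.0)
        bs1 = bootstrap_ci(hist, scheme, grid, chroms, cfg, G=G, reps=20, seed=4)
        bs2 = bootstrap_ci(hist, scheme, grid, chroms, cfg, G=G, reps=20, seed=4)
        np.testing.assert_array_equal(bs1.lower, bs2.lower)
        np.testing.assert_array_equal(bs1.upper, bs2.upper)
        cover = np.mean((bs1.lower[:51] <= 10000.0) & (10000.0 <= bs1.upper[:51]))
        assert cover >= 0.9
        assert bs1.trajectories.shape == (20, scheme.tmax(G))

    def test_too_few_replicates_rejected(self):
        hist, scheme, grid, chroms, ne, G = _sampled_setup()
        with pytest.raises(ValueError):
            bootstrap_ci(hist, scheme, grid, chroms, PenaltyConfig(1.0), G=G,
                         reps=1, seed=0)
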