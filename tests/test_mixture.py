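"""EM engine for trajectory mixtures: E/M steps, fitting, label handling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trajmix.data import DesignSpec, LongitudinalDataset, ValidationError
from trajmix.mixed import MEMParameters, fit_mem
from trajmix.mixture import (
    MixtureParameters,
    MixtureSpec,
    TrajectoryMixture,
    align_labels,
    class_conditional_loglik,
    e_step,
    fit_mixture,
    m_step,
    modal_assignment,
    predicted_trajectories,
)

from conftest import make_continuous


class TestEStep:
    @pytest.mark.parametrize("llmat,probs,expected", [
        (np.zeros((3, 2)), [0.5, 0.5], [0.5, 0.5]),
        (np.zeros((3, 2)), [0.9, 0.1], [0.9, 0.1]),
        (np.log([[0.2, 0.1]]), [0.5, 0.5], [2 / 3, 1 / 3]),
    ])
    def test_bayes_arithmetic(self, llmat, probs, expected):
        post = e_step(np.atleast_2d(llmat), np.asarray(probs))
        assert np.allclose(post, np.asarray(expected)[None, :], atol=1e-12)

    def test_rows_sum_to_one_under_extreme_logliks(self):
        llmat = np.array([[-1000.0, -1005.0], [-2000.0, -1990.0]])
        post = e_step(llmat, np.array([0.3, 0.7]))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestMStep:
    def test_wls_matches_normal_equations_oracle(self):
        # 3 subjects x 2 times, fixed fractional posterior
        ds = LongitudinalDataset(pd.DataFrame({
            "id": [1, 1, 2, 2, 3, 3],
            "time": [0.0, 1.0] * 3,
            "value": [0.1, 0.9, 2.0, 3.1, 4.2, 5.0]}))
        spec = MixtureSpec(2, DesignSpec(degree=1))
        post = np.array([[0.8, 0.2], [0.5, 0.5], [0.1, 0.9]])
        current = MixtureParameters(
            [0.5, 0.5],
            [MEMParameters(fixed=[0.0, 0.0], resid_var=1.0)] * 2)
        params = m_step(ds, spec, post, current)
        X = np.column_stack([np.ones(6), ds.times])
        for c in range(2):
            w = np.repeat(post[:, c], 2)
            W = np.diag(w)
            beta_oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ ds.values)
            assert np.allclose(params.class_params[c].fixed, beta_oracle,
                               atol=1e-8)

    def test_degenerate_posterior_reduces_to_single_class_fit(self):
        ds, _ = make_continuous(30, np.arange(3.0), [[2.0, 0.3]], seed=5)
        spec = MixtureSpec(2, DesignSpec(degree=1),
                           residual_mode="class_specific")
        post = np.column_stack([np.ones(30), np.zeros(30)])
        current = MixtureParameters(
            [0.5, 0.5],
            [MEMParameters(fixed=[0.0, 0.0], resid_var=1.0)] * 2)
        with pytest.raises(Exception):  # empty class 2 must be refused
            m_step(ds, spec, post, current)

    def test_class_specific_residual_variances_estimated_per_class(self):
        # two flat classes with very different noise levels
        rng = np.random.default_rng(77)
        rows = []
        for i in range(300):
            mu, sd = (0.0, 0.5) if i < 150 else (8.0, 2.0)
            for t in np.arange(3.0):
                rows.append((i, t, mu + rng.normal(0, sd)))
        ds = LongitudinalDataset(
            pd.DataFrame(rows, columns=["id", "time", "value"]))
        fit = fit_mixture(
            ds, MixtureSpec(2, DesignSpec(degree=0),
                            residual_mode="class_specific"),
            n_starts=4, seed=0)
        fit = fit.align_to(np.r_[np.ones(150, int), np.full(150, 2)])
        sds = [np.sqrt(p.resid_var) for p in fit.params.class_params]
        assert abs(sds[0] - 0.5) < 0.15
        assert abs(sds[1] - 2.0) < 0.3

    def test_time_specific_shared_variances_in_m_step(self):
        rng = np.random.default_rng(78)
        sds = np.array([0.5, 1.5])
        rows = [(i, t, rng.normal(0, sds[int(t)]))
                for i in range(200) for t in (0.0, 1.0)]
        ds = LongitudinalDataset(
            pd.DataFrame(rows, columns=["id", "time", "value"]))
        spec = MixtureSpec(
            1, DesignSpec(degree=0, residual_variance_mode="time_specific"))
        fit = fit_mixture(ds, spec, n_starts=1, seed=0)
        rv = np.asarray(fit.params.class_params[0].resid_var)
        assert np.all(np.abs(np.sqrt(rv) - sds) < 0.2)

    def test_uniform_posterior_gives_identical_classes(self):
        ds, _ = make_continuous(40, np.arange(3.0), [[1.0, 0.1]], seed=6)
        spec = MixtureSpec(2, DesignSpec(degree=1))
        post = np.full((40, 2), 0.5)
        current = MixtureParameters(
            [0.5, 0.5],
            [MEMParameters(fixed=[0.0, 0.0], resid_var=1.0)] * 2)
        params = m_step(ds, spec, post, current)
        assert np.allclose(params.class_params[0].fixed,
                           params.class_params[1].fixed)
        assert np.allclose(params.class_probs, [0.5, 0.5])


class TestModalAssignment:
    def test_argmax_and_tie_break(self):
        post = np.array([[0.1, 0.9], [0.5, 0.5], [0.7, 0.3]])
        assert modal_assignment(post).tolist() == [2, 1, 1]

    def test_identity_posterior_labels_in_order(self):
        assert modal_assignment(np.eye(4)).tolist() == [1, 2, 3, 4]


class TestAlignLabels:
    def test_identity_and_transposition(self):
        ref = np.array([1, 1, 2, 2, 3])
        assert align_labels(ref, ref) == (0, 1, 2)
        swapped = np.array([2, 2, 1, 1, 3])
        assert align_labels(ref, swapped) == (1, 0, 2)

    def test_recovers_planted_permutation_vs_brute_force(self):
        rng = np.random.default_rng(12)
        true_perm = (2, 0, 1)
        ref = rng.integers(1, 4, size=200)
        noisy = np.where(rng.random(200) < 0.85,
                         np.asarray(true_perm)[ref - 1] + 1,
                         rng.integers(1, 4, size=200))
        perm = align_labels(ref, noisy)
        conf = np.zeros((3, 3))
        for r, l in zip(ref, noisy):
            conf[r - 1, l - 1] += 1
        best = max(itertools.permutations(range(3)),
                   key=lambda p: sum(conf[k, p[k]] for k in range(3)))
        assert perm == tuple(best)


class TestFitMixture:
    def test_one_class_reduction_equals_fit_mem(self, mem_dataset):
        spec = MixtureSpec(1, DesignSpec(degree=1, random_terms=(0,)),
                           covariance_mode="shared")
        mix = fit_mixture(mem_dataset, spec, n_starts=1, seed=0)
        mem = fit_mem(mem_dataset, DesignSpec(degree=1, random_terms=(0,)),
                      compute_se=False)
        assert abs(mix.loglik - mem.loglik) < 1e-6
        assert np.allclose(mix.posterior, 1.0)

    def test_two_class_lcga_proportions_recovered(self, two_class_lcga):
        ds, labels = two_class_lcga
        fit = fit_mixture(ds, MixtureSpec(2, DesignSpec(degree=0)),
                          n_starts=10, seed=1)
        fit = fit.align_to(labels + 1)
        true_props = np.bincount(labels) / len(labels)
        assert np.all(np.abs(fit.class_proportions - true_props) < 0.03)

    def test_em_dominates_brute_force_grid_oracle(self):
        # N=12, J=2, 2-class intercept-only LCGA; the EM optimum (sigma free)
        # must dominate a grid search over (m1, m2, p) with sigma at truth
        rng = np.random.default_rng(21)
        rows = []
        for i in range(12):
            mu = 0.0 if i < 7 else 2.5
            for t in (0.0, 1.0):
                rows.append((i, t, mu + rng.normal()))
        ds = LongitudinalDataset(
            pd.DataFrame(rows, columns=["id", "time", "value"]))
        fit = fit_mixture(ds, MixtureSpec(2, DesignSpec(degree=0)),
                          n_starts=6, seed=2)

        from scipy.stats import norm as norm_dist
        from scipy.special import logsumexp
        vals = ds.values.reshape(12, 2)
        grid = np.arange(-1.5, 4.0 + 1e-9, 0.05)
        pgrid = np.arange(0.05, 0.951, 0.05)
        best = -np.inf
        for m1 in grid:
            lp1 = norm_dist.logpdf(vals, m1, 1.0).sum(axis=1)
            for m2 in grid:
                lp2 = norm_dist.logpdf(vals, m2, 1.0).sum(axis=1)
                both = np.stack([lp1, lp2], axis=1)
                for p in pgrid:
                    ll = logsumexp(both + np.log([p, 1 - p]), axis=1).sum()
                    best = max(best, ll)
        assert fit.loglik >= best - 1e-8

    def test_loglik_trace_nondecreasing(self, two_class_lcga):
        ds, _ = two_class_lcga
        fit = fit_mixture(ds, MixtureSpec(2, DesignSpec(degree=0)),
                          n_starts=3, seed=3)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8 * (1 + np.abs(fit.loglik_trace[:-1])))

    def test_label_permutation_leaves_loglik_unchanged(self, two_class_lcga):
        ds, _ = two_class_lcga
        spec = MixtureSpec(2, DesignSpec(degree=0))
        model = TrajectoryMixture(ds, spec)
        fit = model.fit(n_starts=3, seed=4)
        flipped = MixtureParameters(
            fit.params.class_probs[::-1].copy(),
            fit.params.class_params[::-1])
        assert np.isclose(model.observed_loglik(fit.params),
                          model.observed_loglik(flipped), atol=1e-10)

    def test_permute_classes_consistency(self, two_class_lcga):
        ds, _ = two_class_lcga
        fit = fit_mixture(ds, MixtureSpec(2, DesignSpec(degree=0)),
                          n_starts=3, seed=5)
        out = fit.permute_classes((1, 0))
        assert np.allclose(out.posterior, fit.posterior[:, ::-1])
        assert np.all(out.assignments == 3 - fit.assignments)
        assert np.allclose(out.params.class_probs,
                           fit.params.class_probs[::-1])

    def test_posterior_rows_sum_to_one(self, two_class_lcga):
        ds, _ = two_class_lcga
        fit = fit_mixture(ds, MixtureSpec(2, DesignSpec(degree=0)),
                          n_starts=2, seed=6)
        assert np.allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-12)

    def test_family_mismatch_rejected(self, ordinal_dataset):
        with pytest.raises(ValidationError, match="family"):
            TrajectoryMixture(ordinal_dataset,
                              MixtureSpec(2, DesignSpec(degree=1)))

    def test_ordinal_two_class_fit_separates_trends(self):
        # 2 ordinal classes with opposite latent trends
        rng = np.random.default_rng(31)
        rows, labels = [], []
        for i in range(150):
            c = int(rng.random() < 0.5)
            slope = 0.9 if c else -0.9
            labels.append(c)
            for t in np.arange(4.0):
                latent = slope * t + rng.logistic()
                rows.append((i, t, 1 + (latent > -1.0) + (latent > 1.0)))
        ds = LongitudinalDataset(
            pd.DataFrame(rows, columns=["id", "time", "value"]),
            outcome_family="ordinal", n_categories=3)
        spec = MixtureSpec(2, DesignSpec(degree=1), outcome_family="ordinal")
        fit = fit_mixture(ds, spec, n_starts=2, seed=7, tol=1e-6,
                          polish=False)
        fit = fit.align_to(np.asarray(labels) + 1)
        agreement = np.mean(fit.assignments == np.asarray(labels) + 1)
        assert agreement > 0.85
        slopes = [p.fixed[1] for p in fit.params.class_params]
        assert slopes[0] < 0 < slopes[1] or slopes[1] < 0 < slopes[0]


class TestPredictedTrajectories:
    def test_flat_and_linear_curves(self):
        spec = MixtureSpec(2, DesignSpec(degree=1))
        params = MixtureParameters(
            [0.5, 0.5],
            [MEMParameters(fixed=[3.0, 0.0], resid_var=1.0),
             MEMParameters(fixed=[20.0, 0.5], resid_var=1.0)])
        curves, extrap = predicted_trajectories(
            spec, params, np.array([0.0, 10.0]))
        assert np.allclose(curves[0], [3.0, 3.0])
        assert np.isclose(curves[1][1], 25.0)

    def test_extrapolation_flagged(self):
        spec = MixtureSpec(1, DesignSpec(degree=1))
        params = MixtureParameters(
            [1.0], [MEMParameters(fixed=[0.0, 1.0], resid_var=1.0)])
        _, extrap = predicted_trajectories(
            spec, params, np.array([12.0]), observed_range=(0.0, 10.0))
        assert extrap

    def test_ordinal_stacked_probabilities_sum_to_one(self):
        spec = MixtureSpec(1, DesignSpec(degree=1),
                           outcome_family="ordinal")
        params = MixtureParameters(
            [1.0], [MEMParameters(fixed=[0.0, 0.4],
                                  thresholds=[-1.0, 1.0])])
        curves, _ = predicted_trajectories(spec, params,
                                           np.array([0.0, 1.0, 2.0]))
        assert np.allclose(curves.sum(axis=2), 1.0, atol=1e-12)

    def test_back_transform_exponentiates(self):
        spec = MixtureSpec(1, DesignSpec(degree=0))
        params = MixtureParameters(
            [1.0], [MEMParameters(fixed=[1.0], resid_var=1.0)])
        curves, _ = predicted_trajectories(spec, params, np.array([0.0]),
                                           back_transform=True)
        assert np.isclose(curves[0, 0], np.e)


class TestSpecInvariants:
    def test_covariance_none_requires_no_random_terms(self):
        with pytest.raises(ValidationError):
            MixtureSpec(2, DesignSpec(degree=1, random_terms=(0,)),
                        covariance_mode="none")
        with pytest.raises(ValidationError):
            MixtureSpec(2, DesignSpec(degree=1), covariance_mode="shared")

    def test_llca_flag(self):
        spec = MixtureSpec(2, DesignSpec(basis="time_dummies"))
        assert spec.is_llca

    def test_class_conditional_duplicated_params_give_identical_columns(
            self, two_class_lcga):
        ds, _ = two_class_lcga
        spec = MixtureSpec(2, DesignSpec(degree=0))
        p = MEMParameters(fixed=[1.0], resid_var=2.0)
        llmat = class_conditional_loglik(ds, spec, [p, p])
        assert np.allclose(llmat[:, 0], llmat[:, 1])
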