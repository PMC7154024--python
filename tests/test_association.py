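"""Misclassification correction and class-covariate/distal association."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from trajmix.association import (
    ClassificationErrorMatrix,
    misclassification_matrix,
    onestep_fit,
    threestep_covariate,
    threestep_covariate_from_assignments,
    threestep_distal_from_assignments,
)
from trajmix.data import DesignSpec, LongitudinalDataset, ValidationError
from trajmix.mixture import MixtureSpec, TrajectoryMixture

from conftest import make_continuous


def _simulate_classification(rng, n, gamma1, error_matrix, base_logit=0.0):
    """Draw (true class, assignment, covariate) for a 2-class setting."""
    x = rng.standard_normal(n)
    p2 = expit(base_logit + gamma1 * x)
    true = (rng.random(n) < p2).astype(int)  # 0/1
    u = rng.random(n)
    a = np.where(u < error_matrix[true, 0], 1, 2)
    return true, a, x


M9 = np.array([[0.93, 0.07], [0.08, 0.92]])  # entropy around 0.9


class TestMisclassificationMatrix:
    def test_degenerate_posterior_gives_identity(self):
        post = np.eye(3)[np.array([0, 1, 2, 1, 0])]
        em = misclassification_matrix(post, np.array([1, 2, 3, 2, 1]))
        assert np.allclose(em.matrix, np.eye(3))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        post = rng.dirichlet(np.ones(3), size=50)
        a = np.argmax(post, axis=1) + 1
        if len(np.unique(a)) == 3:
            em = misclassification_matrix(post, a)
            assert np.allclose(em.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_hand_arithmetic_two_subjects(self):
        post = np.array([[0.9, 0.1], [0.4, 0.6]])
        em = misclassification_matrix(post, np.array([1, 2]))
        expected = np.array([[0.9 / 1.3, 0.4 / 1.3],
                             [0.1 / 0.7, 0.6 / 0.7]])
        assert np.allclose(em.matrix, expected, atol=1e-12)

    def test_empty_assigned_class_rejected(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        with pytest.raises(ValidationError, match="empty"):
            misclassification_matrix(post, np.array([1, 1]))


class TestThreestepCovariate:
    def test_identity_matrix_equals_plain_multinomial_logit(self):
        rng = np.random.default_rng(2)
        true, a, x = _simulate_classification(rng, 500, 0.5, np.eye(2))
        em = ClassificationErrorMatrix(np.eye(2), np.bincount(a - 1) / 500)
        res = threestep_covariate_from_assignments(a, em, x,
                                                   reference_class=1)
        ref = sm.MNLogit(a - 1, sm.add_constant(x)).fit(disp=0)
        assert np.isclose(res.table["log_rrr"].iloc[0],
                          np.asarray(ref.params)[1, 0], atol=1e-6)

    def test_naive_method_is_identity_correction(self):
        rng = np.random.default_rng(3)
        true, a, x = _simulate_classification(rng, 400, 0.4, M9)
        em = ClassificationErrorMatrix(M9, np.bincount(a - 1) / 400)
        res_naive = threestep_covariate_from_assignments(
            a, em, x, reference_class=1, method="naive")
        em_id = ClassificationErrorMatrix(np.eye(2), np.bincount(a - 1) / 400)
        res_id = threestep_covariate_from_assignments(
            a, em_id, x, reference_class=1, method="3step")
        assert np.isclose(res_naive.table["log_rrr"].iloc[0],
                          res_id.table["log_rrr"].iloc[0], atol=1e-8)

    def test_null_covariate_ci_coverage(self):
        covered = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            _, a, x = _simulate_classification(rng, 2000, 0.0, M9,
                                               base_logit=np.log(0.4 / 0.6))
            em = ClassificationErrorMatrix(M9, np.bincount(a - 1) / 2000)
            res = threestep_covariate_from_assignments(a, em, x,
                                                       reference_class=1)
            row = res.table.iloc[0]
            covered += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert covered >= 17

    def test_rrr_recovery_with_misclassification(self):
        ests = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            _, a, x = _simulate_classification(
                rng, 2000, np.log(1.5), M9, base_logit=np.log(0.4 / 0.6))
            em = ClassificationErrorMatrix(M9, np.bincount(a - 1) / 2000)
            res = threestep_covariate_from_assignments(a, em, x,
                                                       reference_class=1)
            ests.append(res.table["rrr"].iloc[0])
        assert abs(np.mean(ests) - 1.5) < 0.15

    def test_location_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(4)
        _, a, x = _simulate_classification(rng, 800, 0.5, M9)
        em = ClassificationErrorMatrix(M9, np.bincount(a - 1) / 800)
        base = threestep_covariate_from_assignments(a, em, x,
                                                    reference_class=1)
        shifted = threestep_covariate_from_assignments(a, em, x + 10.0,
                                                       reference_class=1)
        scaled = threestep_covariate_from_assignments(a, em, 2.0 * x,
                                                      reference_class=1)
        b = base.table["log_rrr"].iloc[0]
        assert np.isclose(shifted.table["log_rrr"].iloc[0], b, atol=1e-5)
        assert np.isclose(scaled.table["log_rrr"].iloc[0], b / 2.0,
                          atol=1e-5)

    def test_reference_defaults_to_most_frequent(self):
        rng = np.random.default_rng(5)
        _, a, x = _simulate_classification(rng, 600, 0.3, M9,
                                           base_logit=np.log(0.25 / 0.75))
        em = ClassificationErrorMatrix(M9, np.bincount(a - 1) / 600)
        res = threestep_covariate_from_assignments(a, em, x)
        assert res.reference_class == int(np.argmax(np.bincount(a - 1))) + 1


class TestThreestepDistal:
    def test_identity_matrix_equals_naive_class_means(self):
        rng = np.random.default_rng(6)
        a = rng.integers(1, 3, size=300)
        y = np.where(a == 1, 0.0, 0.5) + rng.normal(0, 0.2, 300)
        em = ClassificationErrorMatrix(np.eye(2), np.bincount(a - 1) / 300)
        res = threestep_distal_from_assignments(a, em, y, reference_class=1)
        naive = y[a == 2].mean() - y[a == 1].mean()
        assert np.isclose(res.table["mean_difference"].iloc[0], naive,
                          atol=1e-12)

    def test_null_distal_ci_coverage(self):
        covered = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            true = (rng.random(2000) < 0.4).astype(int)
            a = np.where(rng.random(2000) < M9[true, 0], 1, 2)
            y = rng.normal(0, 1, 2000)  # independent of class
            em = ClassificationErrorMatrix(M9, np.bincount(a - 1) / 2000)
            res = threestep_distal_from_assignments(a, em, y,
                                                    reference_class=1)
            row = res.table.iloc[0]
            covered += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert covered >= 17

    def test_recovery_of_three_class_means(self):
        M3 = np.array([[0.92, 0.05, 0.03],
                       [0.05, 0.90, 0.05],
                       [0.04, 0.06, 0.90]])
        mus = np.array([0.0, 0.3, 0.5])
        diffs = []
        for rep in range(20):
            rng = np.random.default_rng(400 + rep)
            true = rng.choice(3, size=2000, p=[0.5, 0.3, 0.2])
            a = np.array([1 + rng.choice(3, p=M3[t]) for t in true])
            y = mus[true] + rng.normal(0, 0.4, 2000)
            em = ClassificationErrorMatrix(M3, np.bincount(a - 1) / 2000)
            res = threestep_distal_from_assignments(a, em, y,
                                                    reference_class=1)
            diffs.append(res.table["mean_difference"].to_numpy())
        mean_diffs = np.mean(diffs, axis=0)
        assert np.all(np.abs(mean_diffs - [0.3, 0.5]) < 0.05)

    def test_log_scale_applied_first(self):
        rng = np.random.default_rng(7)
        a = rng.integers(1, 3, size=200)
        y = np.exp(np.where(a == 1, 1.0, 1.4) + rng.normal(0, 0.1, 200))
        em = ClassificationErrorMatrix(np.eye(2), np.bincount(a - 1) / 200)
        res = threestep_distal_from_assignments(
            a, em, y, reference_class=1, log_scale=True)
        naive = np.log(y[a == 2]).mean() - np.log(y[a == 1]).mean()
        assert np.isclose(res.table["mean_difference"].iloc[0], naive,
                          atol=1e-12)

    def test_missing_distal_dropped_and_counted(self):
        rng = np.random.default_rng(8)
        a = np.array([1, 2] * 100)
        y = rng.normal(size=200)
        y[:10] = np.nan
        em = ClassificationErrorMatrix(np.eye(2), np.bincount(a - 1) / 200)
        res = threestep_distal_from_assignments(a, em, y)
        assert res.n_dropped_missing == 10
        assert res.n_used == 190


class TestRelabelInvariance:
    def test_association_values_survive_class_relabelling(self, two_class_lcga):
        ds, labels = two_class_lcga
        rng = np.random.default_rng(9)
        x = rng.standard_normal(ds.n_subjects)
        fit = TrajectoryMixture(ds, MixtureSpec(2, DesignSpec(degree=0))).fit(
            n_starts=4, seed=1)
        res = threestep_covariate(fit, x, reference_class=1)
        flipped = fit.permute_classes((1, 0))
        res_f = threestep_covariate(flipped, x, reference_class=2)
        assert np.isclose(res.table["log_rrr"].iloc[0],
                          res_f.table["log_rrr"].iloc[0], atol=1e-6)


class TestOnestep:
    def test_zero_covariate_reduces_to_plain_mixture(self, two_class_lcga):
        ds, _ = two_class_lcga
        spec = MixtureSpec(2, DesignSpec(degree=0))
        plain = TrajectoryMixture(ds, spec).fit(n_starts=4, seed=2)
        fit0, _ = onestep_fit(ds, spec, np.zeros(ds.n_subjects),
                              n_starts=4, seed=2, compute_se=False)
        assert abs(plain.loglik - fit0.loglik) < 1e-6

    def test_missing_membership_covariates_rejected(self, two_class_lcga):
        ds, _ = two_class_lcga
        x = np.zeros(ds.n_subjects)
        x[0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            onestep_fit(ds, MixtureSpec(2, DesignSpec(degree=0)), x)

    def test_agrees_with_threestep_at_high_entropy(self):
        # classes 4 sigma apart -> entropy near 1; covariate effect log(2)
        rng = np.random.default_rng(10)
        rows, xs = [], []
        for i in range(600):
            x = rng.standard_normal()
            xs.append(x)
            p2 = expit(np.log(0.6) + np.log(2.0) * x)
            mu = 4.0 if rng.random() < p2 else 0.0
            for t in np.arange(3.0):
                rows.append((i, t, mu + rng.normal()))
        ds = LongitudinalDataset(
            pd.DataFrame(rows, columns=["id", "time", "value"]))
        spec = MixtureSpec(2, DesignSpec(degree=0))
        xs = np.asarray(xs)
        fit1, assoc1 = onestep_fit(ds, spec, xs, n_starts=4, seed=3)
        fit3 = TrajectoryMixture(ds, spec).fit(n_starts=4, seed=3)
        ref = int(np.argmax(fit3.class_proportions)) + 1
        assoc3 = threestep_covariate(fit3, xs, reference_class=ref)
        from trajmix.selection import relative_entropy
        assert relative_entropy(fit3.posterior) > 0.8
        r1 = assoc1.table["rrr"].iloc[0]
        r3 = assoc3.table["rrr"].iloc[0]
        r1 = r1 if r1 >= 1 else 1 / r1
        r3 = r3 if r3 >= 1 else 1 / r3
        assert abs(r1 - r3) / r3 < 0.10
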