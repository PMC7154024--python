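"""Relating latent classes to antecedent covariates and distal outcomes.

Modal class assignment is an error-prone measurement of the true latent
class; regressing assignments on external variables without correction
attenuates associations. This module implements:

* the **classification-error matrix** ``D[t, a] = P(assigned a | true t)``
  estimated from the posterior class probabilities;
* the **maximum-likelihood 3-step estimator** for antecedent covariates — a
  multinomial logistic regression of the *true* class on the covariate in
  which the observed variable is the modal assignment, linked to the true
  class through the fixed classification-error matrix — reported as relative
  risk ratios (RRRs) per unit of the (standardized) covariate;
* an **inverse-error-weighting 3-step estimator** for distal outcomes —
  per-true-class outcome means from weights built from the inverse of the
  classification-error matrix, with influence-function (sandwich-type)
  standard errors — reported as mean differences against a reference class;
* the **1-step** joint model, where class membership probabilities are
  subject-specific multinomial-logistic functions of the covariate and all
  parameters are estimated together;
* uncorrected "naive" versions of both 3-step estimators for comparison.

The reference class defaults to the most frequent assigned class.
Confidence intervals are Wald-type at 95%; no multiplicity adjustment is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess1

from .data import LongitudinalDataset, ValidationError
from .mixture import MixtureResults, MixtureSpec, TrajectoryMixture

__all__ = [
    "AssociationResult",
    "ClassificationErrorMatrix",
    "misclassification_matrix",
    "onestep_fit",
    "threestep_covariate",
    "threestep_covariate_from_assignments",
    "threestep_distal",
    "threestep_distal_from_assignments",
]

_Z95 = float(norm.ppf(0.975))


@dataclass
class ClassificationErrorMatrix:
    """``matrix[t, a] = P(assigned class a | true class t)`` (rows sum to 1)."""

    matrix: np.ndarray
    assigned_proportions: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("classification-error matrix must be square")
        if np.any(m < -1e-9) or np.any(np.abs(m.sum(axis=1) - 1) > 1e-6):
            raise ValidationError("rows must be probabilities summing to 1")
        self.matrix = m

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]


def misclassification_matrix(posterior: np.ndarray,
                             assignments: np.ndarray) -> ClassificationErrorMatrix:
    """Posterior-mass estimator of P(assigned | true).

    Entry (t, a) is ``sum_{i: a_i = a} pi_it / sum_i pi_it`` — the posterior
    mass of true class t landing in assigned class a, row-normalized to the
    true -> assigned orientation.
    """
    post = np.asarray(posterior, dtype=float)
    a = np.asarray(assignments, dtype=int) - 1
    N, C = post.shape
    counts = np.bincount(a, minlength=C)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0]) + 1
        raise ValidationError(f"assigned class {empty} is empty")
    ind = np.zeros((N, C))
    ind[np.arange(N), a] = 1.0
    M = post.T @ ind  # (true t, assigned a) mass
    M /= M.sum(axis=1, keepdims=True)
    return ClassificationErrorMatrix(M, counts / N)


@dataclass
class AssociationResult:
    """Per-class association estimates relative to a reference class.

    ``table`` has one row per non-reference class with the estimate on the
    link scale (log-RRR for covariates, mean difference for distal
    outcomes), its standard error and Wald 95% CI; for covariate
    associations the exponentiated RRR columns are included.
    """

    table: pd.DataFrame
    reference_class: int
    method: str
    kind: str                      # "covariate" | "distal"
    n_used: int
    n_dropped_missing: int = 0
    notes: tuple[str, ...] = ()

    def summary(self) -> str:
        head = (f"{self.kind} association ({self.method}), reference class "
                f"{self.reference_class}, N={self.n_used}"
                + (f" ({self.n_dropped_missing} dropped for missingness)"
                   if self.n_dropped_missing else ""))
        return head + "\n" + self.table.to_string(index=False)


def _default_reference(assigned_props: np.ndarray) -> int:
    return int(np.argmax(assigned_props)) + 1


def _mlogit_neg_loglik(gamma_free: np.ndarray, Xm: np.ndarray,
                       a_idx: np.ndarray, M: np.ndarray,
                       ref_idx: int) -> float:
    """Negative loglik of the assignment given covariates and error matrix."""
    N, k = Xm.shape
    C = M.shape[0]
    G = np.zeros((C, k))
    free = [c for c in range(C) if c != ref_idx]
    G[free] = gamma_free.reshape(C - 1, k)
    eta = Xm @ G.T
    lp = eta - logsumexp(eta, axis=1, keepdims=True)
    # P(a_i | x_i) = sum_t p_t(x_i) M[t, a_i]
    lmass = lp + np.log(np.maximum(M[:, a_idx].T, 1e-300))
    return -float(logsumexp(lmass, axis=1).sum())


def threestep_covariate_from_assignments(
        assignments: np.ndarray, error_matrix: ClassificationErrorMatrix,
        covariate: np.ndarray, reference_class: int | None = None,
        method: str = "3step") -> AssociationResult:
    """ML 3-step multinomial regression of true class on a covariate.

    ``method="naive"`` replaces the classification-error matrix with the
    identity, i.e. an ordinary multinomial logit on the modal assignments.
    """
    a = np.asarray(assignments, dtype=int)
    x = np.asarray(covariate, dtype=float)
    keep = np.isfinite(x)
    n_dropped = int((~keep).sum())
    a, x = a[keep], x[keep]
    C = error_matrix.n_classes
    M = (np.eye(C) if method == "naive" else error_matrix.matrix)
    props = np.bincount(a - 1, minlength=C) / a.size
    ref = (reference_class if reference_class is not None
           else _default_reference(props))
    ref_idx = ref - 1
    Xm = np.column_stack([np.ones(a.size), x])
    k = Xm.shape[1]
    x0 = np.zeros((C - 1) * k)
    a_idx = a - 1
    res = optimize.minimize(
        _mlogit_neg_loglik, x0, args=(Xm, a_idx, M, ref_idx),
        method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-13})
    if not np.isfinite(res.fun):
        raise ValidationError("3-step multinomial likelihood is degenerate")
    H = approx_hess1(res.x, _mlogit_neg_loglik,
                     args=(Xm, a_idx, M, ref_idx))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        raise ValidationError(
            "singular information in the 3-step membership model "
            "(a class may be perfectly predicted by the covariate)") from err
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(C - 1, k)
    G = res.x.reshape(C - 1, k)
    free = [c for c in range(C) if c != ref_idx]
    rows = []
    for pos, c in enumerate(free):
        est, s = G[pos, 1], se[pos, 1]
        rows.append({
            "class": c + 1, "class_pct": 100.0 * props[c],
            "log_rrr": est, "se": s,
            "ci_low": est - _Z95 * s, "ci_high": est + _Z95 * s,
            "rrr": np.exp(est),
            "rrr_ci_low": np.exp(est - _Z95 * s),
            "rrr_ci_high": np.exp(est + _Z95 * s),
        })
    notes = ()
    if not res.success:
        notes = (f"optimizer: {res.message}",)
    return AssociationResult(
        table=pd.DataFrame(rows), reference_class=ref, method=method,
        kind="covariate", n_used=int(a.size),
        n_dropped_missing=n_dropped, notes=notes)


def threestep_covariate(fitted: MixtureResults, covariate: np.ndarray,
                        reference_class: int | None = None,
                        method: str = "3step") -> AssociationResult:
    """3-step (or naive) covariate association for a fitted mixture."""
    if fitted.n_classes < 2:
        raise ValidationError("association needs at least two classes")
    em = misclassification_matrix(fitted.posterior, fitted.assignments)
    return threestep_covariate_from_assignments(
        fitted.assignments, em, covariate, reference_class, method)


def threestep_distal_from_assignments(
        assignments: np.ndarray, error_matrix: ClassificationErrorMatrix,
        distal: np.ndarray, reference_class: int | None = None,
        method: str = "3step", log_scale: bool = False) -> AssociationResult:
    """Classification-error-weighted distal-outcome mean differences.

    Each subject contributes to true class t with weight
    ``(D^-1)[a_i, t]`` where D is the classification-error matrix; the
    weights have expectation 1{t = true class}, so weighted means are
    unbiased for the per-true-class outcome means. Standard errors come from
    the influence functions of the weighted means (sandwich-type).
    """
    a = np.asarray(assignments, dtype=int)
    y = np.asarray(distal, dtype=float)
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    a, y = a[keep], y[keep]
    if log_scale:
        if np.any(y <= 0):
            raise ValidationError("log scale requires positive distal values")
        y = np.log(y)
    C = error_matrix.n_classes
    counts = np.bincount(a - 1, minlength=C)
    if np.any(counts == 0):
        empty = int(np.flatnonzero(counts == 0)[0]) + 1
        raise ValidationError(f"class {empty} has no distal data")
    props = counts / a.size
    ref = (reference_class if reference_class is not None
           else _default_reference(props))
    notes = []
    if method == "naive":
        W = np.eye(C)[a - 1]
    else:
        D = error_matrix.matrix
        cond = np.linalg.cond(D)
        if cond > 1e3:
            notes.append(
                f"classification-error matrix poorly conditioned "
                f"(cond={cond:.3g}); weights are unstable at low entropy")
        Dinv = np.linalg.inv(D)
        W = Dinv[a - 1]  # row a_i of D^{-1}: weight for each true class
    sw = W.sum(axis=0)
    if np.any(np.abs(sw) < 1e-8):
        raise ValidationError("a true class receives no effective weight")
    mu = (W * y[:, None]).sum(axis=0) / sw
    # influence-function covariance of the weighted means
    resid = y[:, None] - mu[None, :]
    infl = W * resid / sw[None, :]
    cov_mu = infl.T @ infl
    rows = []
    ref_idx = ref - 1
    for c in range(C):
        if c == ref_idx:
            continue
        d = mu[c] - mu[ref_idx]
        var = cov_mu[c, c] + cov_mu[ref_idx, ref_idx] - 2 * cov_mu[c, ref_idx]
        s = float(np.sqrt(max(var, 0.0)))
        rows.append({
            "class": c + 1, "class_pct": 100.0 * props[c],
            "mean_difference": d, "se": s,
            "ci_low": d - _Z95 * s, "ci_high": d + _Z95 * s,
        })
    return AssociationResult(
        table=pd.DataFrame(rows), reference_class=ref, method=method,
        kind="distal", n_used=int(a.size), n_dropped_missing=n_dropped,
        notes=tuple(notes))


def threestep_distal(fitted: MixtureResults, distal: np.ndarray | None = None,
                     reference_class: int | None = None,
                     method: str = "3step",
                     log_scale: bool = False) -> AssociationResult:
    """3-step (or naive) distal-outcome association for a fitted mixture."""
    if fitted.n_classes < 2:
        raise ValidationError("association needs at least two classes")
    if distal is None:
        ds = fitted.model.dataset
        if ds.distal is None:
            raise ValidationError("dataset has no distal outcome")
        distal = ds.distal.to_numpy(dtype=float)
    em = misclassification_matrix(fitted.posterior, fitted.assignments)
    return threestep_distal_from_assignments(
        fitted.assignments, em, distal, reference_class, method, log_scale)


def onestep_fit(dataset: LongitudinalDataset, spec: MixtureSpec,
                membership_covariates: np.ndarray,
                n_starts: int = 10, seed: int = 0,
                reference_class: int | None = None,
                compute_se: bool = True,
                **fit_kw) -> tuple[MixtureResults, AssociationResult]:
    """Joint (1-step) estimation of classes and their covariate association.

    Class probabilities become subject-specific,
    ``p_c(x_i) = softmax(gamma_0c + gamma_1c' x_i)`` with the first class's
    coefficients fixed at zero, and the EM engine alternates the usual class
    updates with a weighted multinomial-logistic step for gamma. Returns the
    fitted mixture and the membership association re-expressed against the
    requested reference class, with standard errors from the observed
    information of the membership block.
    """
    x = np.asarray(membership_covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    keep = np.all(np.isfinite(x), axis=1)
    if not keep.all():
        raise ValidationError(
            f"{int((~keep).sum())} subjects have missing membership "
            "covariates; drop them before fitting")
    model = TrajectoryMixture(dataset, spec, membership_covariates=x)
    fit = model.fit(n_starts=n_starts, seed=seed, **fit_kw)
    C = spec.n_classes
    k = 1 + x.shape[1]
    props = fit.class_proportions
    ref = (reference_class if reference_class is not None
           else int(np.argmax(props)) + 1)
    # re-anchor gamma on the chosen reference class
    G = fit.gamma - fit.gamma[ref - 1][None, :]
    cov_g = None
    if compute_se:
        cov_g = _gamma_covariance(model, fit)
    rows = []
    for c in range(C):
        if c == ref - 1:
            continue
        for m in range(1, k):
            est = G[c, m]
            if cov_g is not None:
                s = _contrast_se(cov_g, C, k, c, ref - 1, m)
            else:
                s = np.nan
            rows.append({
                "class": c + 1, "class_pct": 100.0 * props[c],
                "covariate": m - 1,
                "log_rrr": est, "se": s,
                "ci_low": est - _Z95 * s, "ci_high": est + _Z95 * s,
                "rrr": np.exp(est),
                "rrr_ci_low": np.exp(est - _Z95 * s),
                "rrr_ci_high": np.exp(est + _Z95 * s),
            })
    assoc = AssociationResult(
        table=pd.DataFrame(rows), reference_class=ref, method="1step",
        kind="covariate", n_used=dataset.n_subjects)
    return fit, assoc


def _gamma_covariance(model: TrajectoryMixture,
                      fit: MixtureResults) -> np.ndarray | None:
    """Observed-information covariance of the free membership coefficients.

    Profiles over the membership block only, holding the class trajectory
    parameters at their ML values — a curvature approximation that is cheap
    and adequate for Wald summaries of the membership model.
    """
    C = fit.n_classes
    k = fit.gamma.shape[1]
    llmat = model.conditional_logliks(fit.params.class_params)
    Xm = np.column_stack([np.ones(model.dataset.n_subjects),
                          model.membership_covariates])

    def neg(v):
        G = np.vstack([np.zeros(k), v.reshape(C - 1, k)])
        eta = Xm @ G.T
        lp = eta - logsumexp(eta, axis=1, keepdims=True)
        return -float(logsumexp(lp + llmat, axis=1).sum())

    v0 = fit.gamma[1:].ravel()
    try:
        H = approx_hess1(v0, neg)
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


def _contrast_se(cov_g: np.ndarray, C: int, k: int, c: int, ref: int,
                 m: int) -> float:
    """SE of gamma[c, m] - gamma[ref, m] (free block excludes class 0)."""
    vec = np.zeros((C - 1) * k)
    if c != 0:
        vec[(c - 1) * k + m] = 1.0
    if ref != 0:
        vec[(ref - 1) * k + m] -= 1.0
    return float(np.sqrt(max(vec @ cov_g @ vec, 0.0)))
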