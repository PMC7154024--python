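"""Finite mixtures over longitudinal trajectories, estimated by EM.

One engine covers the three latent-class families:

* **Growth mixture model (GMM)** — a mixture of mixed effects models: each
  class has its own mean trajectory and within-class random coefficients
  (``covariance_mode`` ``"shared"`` or ``"class_specific"``).
* **Latent class growth analysis (LCGA)** — ``covariance_mode="none"``:
  fixed class trajectories, residuals independent given class.
* **Longitudinal latent class analysis (LLCA)** — LCGA with the
  ``time_dummies`` basis: unconstrained class means per grid time.

Estimation is maximum likelihood via EM with multiple randomized starts. The
M-step is closed-form weighted least squares for continuous LCGA/LLCA and a
numerical ascent on the posterior-weighted marginal likelihood otherwise (a
generalized EM step: any increase is accepted, which preserves the EM
monotonicity guarantee). The observed-data log-likelihood is asserted
nondecreasing at every iteration. An optional final "polish" maximizes the
observed-data likelihood directly from the EM solution, warm-started, to
sharpen the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .data import DesignSpec, LongitudinalDataset, ValidationError, build_design
from .mixed import (
    MEMParameters,
    MixedEffectsModel,
    SingleClassLayout,
    layout_for,
    ordinal_category_probs,
    predict_random_effects,
    subject_logliks,
)

__all__ = [
    "DegenerateClassError",
    "MonotonicityError",
    "MixtureParameters",
    "MixtureResults",
    "MixtureSpec",
    "TrajectoryMixture",
    "align_labels",
    "class_conditional_loglik",
    "e_step",
    "fit_mixture",
    "m_step",
    "modal_assignment",
    "predicted_trajectories",
]


class DegenerateClassError(RuntimeError):
    """A class's mixing proportion collapsed below 1/(2N)."""


class MonotonicityError(RuntimeError):
    """The observed-data log-likelihood decreased during EM (should never)."""


@dataclass(frozen=True)
class MixtureSpec:
    """Structure of a latent-class trajectory model.

    ``covariance_mode="none"`` (no random terms) gives LCGA, or LLCA when
    combined with the time-dummy basis; ``"shared"`` / ``"class_specific"``
    give growth mixture models with one common or per-class random-effect
    covariance. ``constrain_re_zero`` keeps the random-effect structure in
    the model but pins its covariance at exactly zero (useful to compare a
    GMM against LCGA on identical footing). ``residual_mode`` makes the
    residual variance(s) shared across classes or class-specific.
    """

    n_classes: int
    design: DesignSpec
    outcome_family: str = "continuous"
    covariance_mode: str = "none"
    residual_mode: str = "shared"
    constrain_re_zero: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValidationError("need at least one class")
        if self.covariance_mode not in ("none", "shared", "class_specific"):
            raise ValidationError(
                f"unknown covariance_mode {self.covariance_mode!r}")
        if self.residual_mode not in ("shared", "class_specific"):
            raise ValidationError(
                f"unknown residual_mode {self.residual_mode!r}")
        if self.outcome_family not in ("continuous", "ordinal"):
            raise ValidationError(
                f"unknown outcome family {self.outcome_family!r}")
        has_random = bool(self.design.random_terms)
        if (self.covariance_mode == "none") == has_random:
            raise ValidationError(
                "covariance_mode='none' requires empty random_terms and "
                "vice versa")

    @property
    def is_llca(self) -> bool:
        return (self.design.basis == "time_dummies"
                and self.covariance_mode == "none")


@dataclass
class MixtureParameters:
    """Class probabilities plus per-class mixed-model parameters."""

    class_probs: np.ndarray
    class_params: list[MEMParameters]

    def __post_init__(self) -> None:
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        if np.any(self.class_probs < -1e-12) or \
                abs(self.class_probs.sum() - 1) > 1e-8:
            raise ValidationError("class probabilities must lie on the simplex")

    @property
    def n_classes(self) -> int:
        return len(self.class_params)


# ---------------------------------------------------------------------------
# packing of the full per-class parameter block (class probs excluded)


class MixtureLayout:
    """Unconstrained vector <-> per-class parameters, honouring shared blocks."""

    def __init__(self, dataset: LongitudinalDataset, spec: MixtureSpec) -> None:
        self.spec = spec
        self.C = spec.n_classes
        base = layout_for(dataset, spec.design,
                          constrain_re_zero=spec.constrain_re_zero)
        self.base = base
        self.n_beta = base.n_beta
        self.n_tau = base.n_tau
        self.n_chol = base.n_chol if spec.covariance_mode != "none" else 0
        self.n_chol_blocks = (
            0 if self.n_chol == 0
            else (self.C if spec.covariance_mode == "class_specific" else 1))
        self.n_resid = base.n_resid
        self.n_resid_blocks = (
            0 if self.n_resid == 0
            else (self.C if spec.residual_mode == "class_specific" else 1))
        self.size = (self.C * (self.n_beta + self.n_tau)
                     + self.n_chol_blocks * self.n_chol
                     + self.n_resid_blocks * self.n_resid)

    def pack(self, class_params: list[MEMParameters]) -> np.ndarray:
        xs = []
        for p in class_params:
            v = self.base.pack(p)
            xs.append(v[:self.n_beta])
            if self.n_tau:
                xs.append(v[self.n_beta + self.base.n_chol + self.base.n_resid:])
        for b in range(self.n_chol_blocks):
            v = self.base.pack(class_params[b])
            xs.append(v[self.n_beta:self.n_beta + self.n_chol])
        for b in range(self.n_resid_blocks):
            v = self.base.pack(class_params[b])
            off = self.n_beta + self.base.n_chol
            xs.append(v[off:off + self.n_resid])
        return np.concatenate(xs) if xs else np.empty(0)

    def unpack(self, x: np.ndarray) -> list[MEMParameters]:
        i = 0
        betas, taus = [], []
        for _ in range(self.C):
            betas.append(x[i:i + self.n_beta]); i += self.n_beta
            if self.n_tau:
                taus.append(x[i:i + self.n_tau]); i += self.n_tau
        chols = []
        for _ in range(self.n_chol_blocks):
            chols.append(x[i:i + self.n_chol]); i += self.n_chol
        resids = []
        for _ in range(self.n_resid_blocks):
            resids.append(x[i:i + self.n_resid]); i += self.n_resid
        out = []
        for c in range(self.C):
            parts = [betas[c]]
            if self.n_chol_blocks:
                parts.append(chols[min(c, self.n_chol_blocks - 1)])
            elif self.base.q and self.spec.constrain_re_zero:
                pass
            if self.n_resid_blocks:
                parts.append(resids[min(c, self.n_resid_blocks - 1)])
            if self.n_tau:
                parts.append(taus[c])
            out.append(self.base.unpack(np.concatenate(parts)))
        return out

    def bounds(self) -> list[tuple]:
        base_b = self.base.bounds()
        beta_b = base_b[:self.n_beta]
        chol_b = base_b[self.n_beta:self.n_beta + self.n_chol]
        off = self.n_beta + self.base.n_chol
        resid_b = base_b[off:off + self.n_resid]
        tau_b = base_b[off + self.n_resid:]
        b: list[tuple] = []
        for _ in range(self.C):
            b += beta_b
            b += tau_b
        for _ in range(self.n_chol_blocks):
            b += chol_b
        for _ in range(self.n_resid_blocks):
            b += resid_b
        return b


# ---------------------------------------------------------------------------
# spec-level operations


def class_conditional_loglik(dataset: LongitudinalDataset, spec: MixtureSpec,
                             class_params: list[MEMParameters],
                             n_quad_nodes: int = 15) -> np.ndarray:
    """N x C matrix of per-subject log-likelihoods under each class model."""
    cols = [subject_logliks(dataset, spec.design, p, n_quad_nodes)
            for p in class_params]
    return np.column_stack(cols)


def e_step(log_lik_matrix: np.ndarray,
           class_probs: np.ndarray) -> np.ndarray:
    """Posterior class probabilities, computed stably on the log scale."""
    post, _ = _posterior_and_loglik(
        log_lik_matrix, np.log(np.asarray(class_probs, dtype=float))[None, :])
    return post


def _posterior_and_loglik(llmat: np.ndarray,
                          log_prior: np.ndarray) -> tuple[np.ndarray, float]:
    logpost = log_prior + llmat
    norm = logsumexp(logpost, axis=1)
    if not np.all(np.isfinite(norm)):
        raise ValidationError(
            "posterior mass underflowed for some subjects despite "
            "log-scale stabilization")
    post = np.exp(logpost - norm[:, None])
    return post, float(norm.sum())


def modal_assignment(posterior: np.ndarray) -> np.ndarray:
    """1-based class labels; ties break toward the lowest class index."""
    return np.argmax(posterior, axis=1) + 1


def predicted_trajectories(spec: MixtureSpec, params: MixtureParameters,
                           times: np.ndarray,
                           grid=None, back_transform: bool = False,
                           observed_range: tuple[float, float] | None = None):
    """Per-class predicted curves at the requested times.

    Continuous family: returns ``(curves, extrapolated)`` with ``curves`` of
    shape C x T (optionally exp-back-transformed from the log scale, a
    median-scale prediction). Ordinal family: ``curves`` has shape
    C x T x (K+1), the stacked category probabilities at the class-mean
    linear predictor (random effects at zero).
    """
    times = np.asarray(times, dtype=float)
    X, _ = build_design(times, spec.design, grid)
    extrapolated = False
    if observed_range is not None:
        extrapolated = bool(times.min() < observed_range[0] - 1e-9
                            or times.max() > observed_range[1] + 1e-9)
    if spec.outcome_family == "continuous":
        curves = np.vstack([X @ p.fixed for p in params.class_params])
        if back_transform:
            curves = np.exp(curves)
        return curves, extrapolated
    curves = np.stack([
        ordinal_category_probs(X @ p.fixed, p.thresholds)
        for p in params.class_params])
    return curves, extrapolated


def align_labels(reference_labels: np.ndarray, labels: np.ndarray,
                 n_classes: int | None = None) -> tuple[int, ...]:
    """Permutation ``perm`` (new class k <- old class perm[k]) maximizing the
    overlap between ``labels`` (after permutation) and ``reference_labels``.

    Labels are 1-based. Solved exactly as an assignment problem on the
    confusion matrix.
    """
    ref = np.asarray(reference_labels, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if ref.shape != lab.shape:
        raise ValidationError("labelings must cover the same subjects")
    C = n_classes or max(ref.max(), lab.max())
    if ref.max() > C or lab.max() > C:
        raise ValidationError("label exceeds the declared number of classes")
    conf = np.zeros((C, C))
    for r, l in zip(ref, lab):
        conf[r - 1, l - 1] += 1
    row, col = linear_sum_assignment(-conf)
    # row k (reference class) matched with old class col[k]
    perm = tuple(int(col[k]) for k in np.argsort(row))
    return perm


# ---------------------------------------------------------------------------
# the model


class TrajectoryMixture:
    """Latent-class trajectory model (GMM / LCGA / LLCA) fitted by ML + EM.

    Parameters
    ----------
    dataset
        Longitudinal data; its outcome family must match ``spec``.
    spec
        The :class:`MixtureSpec` describing classes, design and covariance
        structure.
    membership_covariates
        Optional N x k array of subject-level covariates entering a
        multinomial-logistic model for class membership (the joint "1-step"
        model); ``None`` gives the plain mixture with free class
        probabilities.
    """

    def __init__(self, dataset: LongitudinalDataset, spec: MixtureSpec,
                 membership_covariates: np.ndarray | None = None,
                 n_quad_nodes: int = 15) -> None:
        if dataset.outcome_family != spec.outcome_family:
            raise ValidationError(
                "dataset and spec disagree on the outcome family")
        self.dataset = dataset
        self.spec = spec
        self.n_quad_nodes = n_quad_nodes
        self.layout = MixtureLayout(dataset, spec)
        if membership_covariates is not None:
            membership_covariates = np.atleast_2d(
                np.asarray(membership_covariates, dtype=float))
            if membership_covariates.shape[0] != dataset.n_subjects:
                membership_covariates = membership_covariates.T
            if membership_covariates.shape[0] != dataset.n_subjects:
                raise ValidationError(
                    "membership covariates must have one row per subject")
            if np.isnan(membership_covariates).any():
                raise ValidationError("membership covariates must be complete")
        self.membership_covariates = membership_covariates
        # record-level design, cached
        self._X_rec, _ = build_design(
            dataset.times, spec.design, dataset.grid, dataset.grid_tol)
        self._rec_sub = dataset._sub_codes
        self._single_fit_cache = None

    # -- bookkeeping -----------------------------------------------------------

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    @property
    def n_free_params(self) -> int:
        C = self.n_classes
        if self.membership_covariates is None:
            n_member = C - 1
        else:
            n_member = (C - 1) * (1 + self.membership_covariates.shape[1])
        return n_member + self.layout.size

    def _log_prior(self, params: MixtureParameters,
                   gamma: np.ndarray | None) -> np.ndarray:
        if self.membership_covariates is None or gamma is None:
            return np.log(np.maximum(params.class_probs, 1e-300))[None, :]
        Xm = np.column_stack(
            [np.ones(self.dataset.n_subjects), self.membership_covariates])
        eta = Xm @ gamma.T  # N x C  (gamma row for class 0 is all zeros)
        return eta - logsumexp(eta, axis=1, keepdims=True)

    # -- likelihood pieces -----------------------------------------------------

    def conditional_logliks(self, class_params: list[MEMParameters]) -> np.ndarray:
        return class_conditional_loglik(
            self.dataset, self.spec, class_params, self.n_quad_nodes)

    def observed_loglik(self, params: MixtureParameters,
                        gamma: np.ndarray | None = None) -> float:
        llmat = self.conditional_logliks(params.class_params)
        _, ll = _posterior_and_loglik(llmat, self._log_prior(params, gamma))
        return ll

    # -- M-step ---------------------------------------------------------------

    def m_step(self, posterior: np.ndarray,
               current: MixtureParameters,
               gamma: np.ndarray | None = None,
               inner_maxiter: int = 40):
        """Posterior-weighted parameter update (closed form where available).

        Returns ``(MixtureParameters, gamma)``. Raises
        :class:`DegenerateClassError` when a class's posterior mass falls
        below one subject-equivalent over 2.
        """
        N, C = posterior.shape
        mass = posterior.sum(axis=0)
        if mass.min() < 0.5:
            raise DegenerateClassError(
                f"class mass {mass.min():.3g} below half a subject")
        probs = mass / N
        if probs.min() < 1.0 / (2 * N):
            raise DegenerateClassError(
                f"mixing proportion {probs.min():.3g} below 1/(2N)")
        if self.membership_covariates is not None:
            gamma = self._update_gamma(posterior, gamma)
        if (self.spec.outcome_family == "continuous"
                and self.spec.covariance_mode == "none"):
            class_params = self._mstep_wls(posterior)
        else:
            class_params = self._mstep_numeric(
                posterior, current.class_params, inner_maxiter)
        return MixtureParameters(probs, class_params), gamma

    def _mstep_wls(self, posterior: np.ndarray) -> list[MEMParameters]:
        """Exact weighted-least-squares M-step for continuous LCGA/LLCA."""
        X = self._X_rec
        y = self.dataset.values
        C = self.n_classes
        w_rec = posterior[self._rec_sub]  # n_records x C
        betas, resid2 = [], []
        for c in range(C):
            w = w_rec[:, c]
            Xw = X * w[:, None]
            beta = np.linalg.solve(X.T @ Xw + 1e-12 * np.eye(X.shape[1]),
                                   Xw.T @ y)
            betas.append(beta)
            resid2.append((y - X @ beta) ** 2)
        resid2 = np.column_stack(resid2)  # n_records x C
        time_specific = (self.spec.design.residual_variance_mode
                         == "time_specific")
        gidx = self.dataset.grid_idx
        params = []
        if self.spec.residual_mode == "shared":
            wr2 = (w_rec * resid2).sum(axis=1)
            if time_specific:
                num = np.bincount(gidx, weights=wr2,
                                  minlength=self.dataset.grid.size)
                den = np.bincount(gidx, minlength=self.dataset.grid.size)
                rv = np.maximum(num / np.maximum(den, 1), 1e-10)
            else:
                rv = max(wr2.sum() / len(y), 1e-10)
            for c in range(C):
                params.append(MEMParameters(fixed=betas[c], resid_var=rv))
        else:
            for c in range(C):
                w = w_rec[:, c]
                if time_specific:
                    num = np.bincount(gidx, weights=w * resid2[:, c],
                                      minlength=self.dataset.grid.size)
                    den = np.bincount(gidx, weights=w,
                                      minlength=self.dataset.grid.size)
                    rv = np.maximum(num / np.maximum(den, 1e-12), 1e-10)
                else:
                    rv = max((w * resid2[:, c]).sum() / w.sum(), 1e-10)
                params.append(MEMParameters(fixed=betas[c], resid_var=rv))
        return params

    def _mstep_numeric(self, posterior: np.ndarray,
                       current: list[MEMParameters],
                       inner_maxiter: int) -> list[MEMParameters]:
        """Generalized-EM M-step: numerically increase the weighted loglik."""
        x0 = self.layout.pack(current)

        def negQ(x):
            try:
                cp = self.layout.unpack(x)
                llmat = self.conditional_logliks(cp)
            except (ValidationError, np.linalg.LinAlgError):
                return 1e12
            val = float((posterior * llmat).sum())
            return 1e12 if not np.isfinite(val) else -val

        q0 = negQ(x0)
        res = optimize.minimize(
            negQ, x0, method="L-BFGS-B", bounds=self.layout.bounds(),
            options={"maxiter": inner_maxiter, "ftol": 1e-12})
        if res.fun < q0 - 1e-12:
            return self.layout.unpack(res.x)
        return current

    def _update_gamma(self, posterior: np.ndarray,
                      gamma: np.ndarray | None) -> np.ndarray:
        """Weighted multinomial-logistic update of membership coefficients."""
        N, C = posterior.shape
        Xm = np.column_stack([np.ones(N), self.membership_covariates])
        k = Xm.shape[1]
        x0 = (np.zeros((C - 1) * k) if gamma is None
              else gamma[1:].ravel())

        def neg(v):
            G = np.vstack([np.zeros(k), v.reshape(C - 1, k)])
            eta = Xm @ G.T
            lp = eta - logsumexp(eta, axis=1, keepdims=True)
            return -float((posterior * lp).sum())

        res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                options={"maxiter": 200, "ftol": 1e-12})
        best = res.x if res.fun <= neg(x0) else x0
        return np.vstack([np.zeros(k), best.reshape(C - 1, k)])

    # -- initialization --------------------------------------------------------

    def _subject_features(self) -> np.ndarray:
        feats = np.zeros((self.dataset.n_subjects, 2))
        for i, sl in enumerate(self.dataset.subject_slices()):
            t = self.dataset.times[sl]
            v = self.dataset.values[sl]
            feats[i, 0] = v.mean()
            if np.unique(t).size >= 2:
                feats[i, 1] = np.polyfit(t, v, 1)[0]
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        return feats / sd

    def _single_class_fit(self):
        if self._single_fit_cache is None:
            spec1 = self.spec.design
            self._single_fit_cache = MixedEffectsModel(
                self.dataset, spec1, self.n_quad_nodes).fit(compute_se=False)
        return self._single_fit_cache

    def _init_from_labels(self, labels0: np.ndarray,
                          rng: np.random.Generator) -> MixtureParameters:
        """Build coherent starting parameters from a hard partition."""
        C = self.n_classes
        N = self.dataset.n_subjects
        if C == 1:
            post = np.ones((N, 1))
        else:
            post = np.full((N, C), 0.05 / (C - 1))
            post[np.arange(N), labels0] = 0.95
        probs = post.mean(axis=0)
        X = self._X_rec
        y = self.dataset.values
        w_rec = post[self._rec_sub]
        class_params = []
        base_fit = None
        if (self.spec.covariance_mode != "none"
                or self.spec.outcome_family == "ordinal"):
            base_fit = self._single_class_fit()
        if self.spec.outcome_family == "continuous":
            betas, r2s = [], []
            for c in range(C):
                w = w_rec[:, c]
                Xw = X * w[:, None]
                beta = np.linalg.solve(
                    X.T @ Xw + 1e-8 * np.eye(X.shape[1]), Xw.T @ y)
                betas.append(beta)
                r2s.append(((y - X @ beta) ** 2 * w).sum() / w.sum())
            pooled = max(float(np.mean(r2s)), 1e-6)
            for c in range(C):
                # shared modes must start inside the constrained space,
                # else the first M-step could lower the observed loglik
                r2 = (pooled if self.spec.residual_mode == "shared"
                      else max(r2s[c], 1e-6))
                rv = (r2
                      if self.spec.design.residual_variance_mode == "constant"
                      else np.full(self.dataset.grid.size, r2))
                re_cov = None
                if self.spec.covariance_mode != "none":
                    re_cov = base_fit.params.re_cov.copy()
                    rv = base_fit.params.resid_var
                class_params.append(MEMParameters(
                    fixed=betas[c], re_cov=re_cov, resid_var=rv))
        else:
            for c in range(C):
                vals = y[post[self._rec_sub, c] > 0.5]
                if vals.size < 5:
                    vals = y
                K = self.dataset.n_categories - 1
                freq = np.bincount(vals.astype(int),
                                   minlength=self.dataset.n_categories + 1)[1:]
                cum = np.clip(np.cumsum(freq / freq.sum())[:-1],
                              1e-3, 1 - 1e-3)
                tau = np.log(cum / (1 - cum))
                tau = np.maximum.accumulate(tau) + 1e-4 * np.arange(K)
                p0 = base_fit.params
                fixed = np.zeros(self.layout.base.p)
                fixed[1:] = p0.fixed[1:] + 0.1 * rng.standard_normal(
                    self.layout.base.p - 1)
                re_cov = (p0.re_cov.copy()
                          if self.spec.covariance_mode != "none" else None)
                class_params.append(MEMParameters(
                    fixed=fixed, re_cov=re_cov, thresholds=tau))
        return MixtureParameters(probs, class_params)

    def _start_labels(self, start: int, rng: np.random.Generator) -> np.ndarray:
        feats = self._subject_features()
        C = self.n_classes
        if start == 1 and C > 1:
            # quantile split on the subject mean, a deliberately different cut
            qs = np.quantile(feats[:, 0], np.linspace(0, 1, C + 1)[1:-1])
            return np.searchsorted(qs, feats[:, 0])
        if start >= 2:
            feats = feats + 0.5 * rng.standard_normal(feats.shape)
        km = KMeans(n_clusters=C, n_init=3,
                    random_state=int(rng.integers(2 ** 31)))
        return km.fit_predict(feats)

    # -- EM --------------------------------------------------------------------

    def _run_em(self, params: MixtureParameters, gamma, tol, max_iter,
                inner_maxiter):
        trace = []
        ll_prev = -np.inf
        post = None
        for it in range(max_iter):
            llmat = self.conditional_logliks(params.class_params)
            post, ll = _posterior_and_loglik(
                llmat, self._log_prior(params, gamma))
            if ll < ll_prev - 1e-8 * (1.0 + abs(ll_prev)):
                raise MonotonicityError(
                    f"log-likelihood decreased {ll_prev:.10f} -> {ll:.10f} "
                    f"at EM iteration {it}")
            trace.append(ll)
            if it > 0 and abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
                break
            ll_prev = ll
            params, gamma = self.m_step(post, params, gamma, inner_maxiter)
        return params, gamma, post, trace

    def fit(self, n_starts: int = 10, seed: int = 0, tol: float = 1e-8,
            max_iter: int = 1000, polish: bool = True,
            init: MixtureParameters | None = None,
            inner_maxiter: int = 40) -> "MixtureResults":
        """Run EM from several randomized starts and keep the best solution.

        ``tol`` is the (relative-scaled) change in observed log-likelihood
        declaring EM converged. ``polish`` runs a final direct quasi-Newton
        maximization of the observed-data likelihood from the best EM
        solution.
        """
        rng = np.random.default_rng(seed)
        C = self.n_classes
        if C == 1:
            n_starts = 1
        k_member = (0 if self.membership_covariates is None
                    else 1 + self.membership_covariates.shape[1])
        best = None
        reports = []
        for s in range(n_starts):
            start_seed = int(rng.integers(2 ** 31))
            srng = np.random.default_rng(start_seed)
            try:
                if init is not None and s == 0:
                    params0 = init
                else:
                    labels0 = (np.zeros(self.dataset.n_subjects, dtype=int)
                               if C == 1 else self._start_labels(s, srng))
                    params0 = self._init_from_labels(labels0, srng)
                gamma0 = (np.zeros((C, k_member)) if k_member else None)
                params, gamma, post, trace = self._run_em(
                    params0, gamma0, tol, max_iter, inner_maxiter)
                ok = len(trace) < max_iter
                reports.append({"start": s, "seed": start_seed,
                                "loglik": trace[-1], "n_iter": len(trace),
                                "converged": ok, "error": None})
                cand = (trace[-1], ok, params, gamma, post, trace, s,
                        start_seed)
                if best is None or cand[0] > best[0]:
                    best = cand
            except (DegenerateClassError, ValidationError,
                    np.linalg.LinAlgError) as err:
                reports.append({"start": s, "seed": start_seed,
                                "loglik": np.nan, "n_iter": 0,
                                "converged": False, "error": str(err)})
        if best is None:
            raise DegenerateClassError(
                "all EM starts degenerated or failed; per-start reports: "
                + "; ".join(str(r["error"]) for r in reports))
        ll, ok, params, gamma, post, trace, s_best, seed_best = best
        if polish:
            params, gamma, ll2 = self._polish(params, gamma)
            if ll2 > ll:
                ll = ll2
                llmat = self.conditional_logliks(params.class_params)
                post, ll = _posterior_and_loglik(
                    llmat, self._log_prior(params, gamma))
                trace = trace + [ll]
        return MixtureResults(
            model=self, spec=self.spec, params=params, gamma=gamma,
            loglik=float(ll), posterior=post,
            assignments=modal_assignment(post),
            loglik_trace=np.asarray(trace), n_em_iterations=len(trace),
            n_starts_used=n_starts, best_start_seed=seed_best,
            converged=bool(ok), start_reports=reports)

    def _polish(self, params: MixtureParameters, gamma):
        """Direct observed-likelihood maximization, warm-started from EM."""
        C = self.n_classes
        k_member = (0 if self.membership_covariates is None
                    else 1 + self.membership_covariates.shape[1])
        if k_member:
            head = gamma[1:].ravel()
            n_head = head.size
        else:
            lp = np.log(np.maximum(params.class_probs, 1e-12))
            head = (lp[1:] - lp[0])
            n_head = C - 1
        x0 = np.concatenate([head, self.layout.pack(params.class_params)])

        def unpack_all(x):
            if k_member:
                g = np.vstack([np.zeros(k_member),
                               x[:n_head].reshape(C - 1, k_member)])
                probs = np.full(C, 1.0 / C)
            else:
                g = None
                logits = np.r_[0.0, x[:n_head]]
                probs = np.exp(logits - logsumexp(logits))
            cp = self.layout.unpack(x[n_head:])
            return MixtureParameters(probs, cp), g

        def neg(x):
            try:
                p, g = unpack_all(x)
                return -self.observed_loglik(p, g)
            except (ValidationError, np.linalg.LinAlgError):
                return 1e12

        bounds = [(-30.0, 30.0)] * n_head + self.layout.bounds()
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 300, "ftol": 1e-13})
        if -res.fun <= -neg(x0):
            p, g = unpack_all(x0)
            return p, g, -neg(x0)
        p, g = unpack_all(res.x)
        return p, g, -res.fun


# ---------------------------------------------------------------------------
# results


@dataclass
class MixtureResults:
    """Converged latent-class fit: parameters, posteriors, fit indices."""

    model: TrajectoryMixture
    spec: MixtureSpec
    params: MixtureParameters
    gamma: np.ndarray | None
    loglik: float
    posterior: np.ndarray
    assignments: np.ndarray
    loglik_trace: np.ndarray
    n_em_iterations: int
    n_starts_used: int
    best_start_seed: int
    converged: bool
    start_reports: list = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    @property
    def n_free_params(self) -> int:
        return self.model.n_free_params

    @property
    def n_subjects(self) -> int:
        return self.posterior.shape[0]

    @property
    def class_proportions(self) -> np.ndarray:
        """Posterior-weighted (expected) class frequencies."""
        return self.posterior.mean(axis=0)

    # -- fit indices (delegated to selection, imported lazily to avoid cycle)

    @property
    def aic(self) -> float:
        from .selection import information_criteria
        return information_criteria(self.loglik, self.n_free_params,
                                    self.n_subjects)[0]

    @property
    def bic(self) -> float:
        from .selection import information_criteria
        return information_criteria(self.loglik, self.n_free_params,
                                    self.n_subjects)[1]

    @property
    def cbic(self) -> float:
        from .selection import information_criteria
        return information_criteria(self.loglik, self.n_free_params,
                                    self.n_subjects)[2]

    @property
    def entropy(self) -> float:
        from .selection import relative_entropy
        return relative_entropy(self.posterior)

    def predicted_trajectories(self, times=None, back_transform=None):
        ds = self.model.dataset
        if times is None:
            times = ds.grid if ds.grid is not None else np.unique(ds.times)
        if back_transform is None:
            back_transform = ds.log_transformed
        return predicted_trajectories(
            self.spec, self.params, times, grid=ds.grid,
            back_transform=back_transform,
            observed_range=(ds.times.min(), ds.times.max()))

    def predict_random_effects(self) -> np.ndarray:
        """Per-subject empirical-Bayes random effects within the modal class."""
        ds = self.model.dataset
        q = self.spec.design.n_random
        out = np.zeros((ds.n_subjects, q))
        if q == 0:
            return out
        for c in range(self.n_classes):
            mask = self.assignments == c + 1
            if not mask.any():
                continue
            u = predict_random_effects(ds, self.spec.design,
                                       self.params.class_params[c],
                                       self.model.n_quad_nodes)
            out[mask] = u[mask]
        return out

    def standard_errors(self) -> dict:
        """Wald standard errors from the inverse observed information.

        The Hessian of the observed-data negative log-likelihood is taken
        numerically over all free parameters (class-probability logits or
        membership coefficients, then the per-class blocks). Returns a dict
        with ``"fixed"`` (C x p array of fixed-effect SEs; NaN where a
        coefficient is fixed by convention) and ``"all"`` (SE per packed
        free parameter).
        """
        from statsmodels.tools.numdiff import approx_hess1

        model = self.model
        C = self.n_classes
        layout = model.layout
        if model.membership_covariates is not None:
            k = self.gamma.shape[1]
            head = self.gamma[1:].ravel()
        else:
            k = 0
            lp = np.log(np.maximum(self.params.class_probs, 1e-12))
            head = lp[1:] - lp[0]
        n_head = head.size
        x0 = np.concatenate([head, layout.pack(self.params.class_params)])

        def neg(x):
            if k:
                g = np.vstack([np.zeros(k), x[:n_head].reshape(C - 1, k)])
                probs = np.full(C, 1.0 / C)
            else:
                logits = np.r_[0.0, x[:n_head]]
                probs = np.exp(logits - logsumexp(logits))
                g = None
            p = MixtureParameters(probs, layout.unpack(x[n_head:]))
            return -model.observed_loglik(p, g)

        H = approx_hess1(x0, neg)
        cov = np.linalg.pinv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        se_all = np.sqrt(d)
        p = layout.base.p
        fixed = np.full((C, p), np.nan)
        block = layout.n_beta + layout.n_tau
        for c in range(C):
            off = n_head + c * block
            if self.spec.outcome_family == "continuous":
                fixed[c, :] = se_all[off:off + layout.n_beta]
            else:
                fixed[c, 1:] = se_all[off:off + layout.n_beta]
        return {"fixed": fixed, "all": se_all, "cov": cov}

    def permute_classes(self, perm) -> "MixtureResults":
        """Reorder classes so that new class k is old class perm[k]."""
        perm = tuple(perm)
        if sorted(perm) != list(range(self.n_classes)):
            raise ValidationError(f"{perm} is not a permutation of the classes")
        params = MixtureParameters(
            self.params.class_probs[list(perm)],
            [self.params.class_params[p] for p in perm])
        inv = np.empty(self.n_classes, dtype=int)
        for new, old in enumerate(perm):
            inv[old] = new
        gamma = self.gamma[list(perm)] if self.gamma is not None else None
        return replace(
            self, params=params, gamma=gamma,
            posterior=self.posterior[:, list(perm)],
            assignments=inv[self.assignments - 1] + 1)

    def align_to(self, reference_labels: np.ndarray) -> "MixtureResults":
        perm = align_labels(reference_labels, self.assignments,
                            self.n_classes)
        return self.permute_classes(perm)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "family": self.spec.outcome_family,
            "covariance_mode": self.spec.covariance_mode,
            "residual_mode": self.spec.residual_mode,
            "constrain_re_zero": self.spec.constrain_re_zero,
            "n_categories": self.model.dataset.n_categories,
            "basis": self.spec.design.basis,
            "design": {
                "basis": self.spec.design.basis,
                "degree": self.spec.design.degree,
                "random_terms": list(self.spec.design.random_terms),
                "residual_variance_mode":
                    self.spec.design.residual_variance_mode,
                "centre": self.spec.design.centre,
            },
            "class_probs": self.params.class_probs.tolist(),
            "class_params": [
                {"fixed": p.fixed.tolist(),
                 "re_cov": None if p.re_cov is None else p.re_cov.tolist(),
                 "resid_var": None if p.resid_var is None
                 else np.atleast_1d(p.resid_var).tolist(),
                 "thresholds": None if p.thresholds is None
                 else p.thresholds.tolist()}
                for p in self.params.class_params],
            "membership_coefficients": (
                None if self.gamma is None else self.gamma.tolist()),
            "loglik": self.loglik,
            "n_free_params": self.n_free_params,
            "aic": self.aic, "bic": self.bic, "cbic": self.cbic,
            "entropy": None if self.n_classes == 1 else self.entropy,
            "converged": self.converged,
            "n_em_iterations": self.n_em_iterations,
            "n_starts_used": self.n_starts_used,
            "best_start_seed": self.best_start_seed,
        }

    def posterior_frame(self):
        import pandas as pd
        cols = {f"class_{c + 1}": self.posterior[:, c]
                for c in range(self.n_classes)}
        return pd.DataFrame({"id": self.model.dataset.subjects, **cols,
                             "assigned": self.assignments})

    def summary(self) -> str:
        d = self.to_dict()
        name = {"none": "LCGA" if self.spec.design.basis == "polynomial"
                else "LLCA"}.get(self.spec.covariance_mode, "GMM")
        lines = [
            f"{name} with {self.n_classes} class(es) "
            f"({d['family']} outcome)",
            f"  log-likelihood {self.loglik:.4f}  "
            f"k={self.n_free_params}  N={self.n_subjects}",
            f"  AIC {d['aic']:.3f}  BIC {d['bic']:.3f}  "
            f"c-BIC {d['cbic']:.3f}"
            + ("" if d["entropy"] is None
               else f"  entropy {d['entropy']:.3f}"),
            "  class probabilities: "
            + ", ".join(f"{p:.3f}" for p in d["class_probs"]),
        ]
        for c, p in enumerate(self.params.class_params):
            lines.append(f"  class {c + 1} fixed effects: "
                         + ", ".join(f"{b:.4f}" for b in p.fixed))
        if not self.converged:
            lines.append("  WARNING: EM did not converge on the best start")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers matching the operation-level interface


def m_step(dataset: LongitudinalDataset, spec: MixtureSpec,
           posterior: np.ndarray, current_params: MixtureParameters,
           n_quad_nodes: int = 15) -> MixtureParameters:
    model = TrajectoryMixture(dataset, spec, n_quad_nodes=n_quad_nodes)
    params, _ = model.m_step(posterior, current_params)
    return params


def fit_mixture(dataset: LongitudinalDataset, spec: MixtureSpec,
                n_starts: int = 10, seed: int = 0, tol: float = 1e-8,
                max_iter: int = 1000, **kw) -> MixtureResults:
    """Convenience wrapper: build a :class:`TrajectoryMixture` and fit it."""
    return TrajectoryMixture(dataset, spec).fit(
        n_starts=n_starts, seed=seed, tol=tol, max_iter=max_iter, **kw)
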