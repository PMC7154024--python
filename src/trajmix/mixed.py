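"""Single-class mixed effects models for continuous and ordinal outcomes.

Continuous outcomes follow the linear mixed model

    Z_ij = x_ij' beta + z_ij' u_i + eps_ij,   u_i ~ N(0, Omega_u),
    eps_ij ~ N(0, sigma2) (or sigma2_j per grid time),

whose marginal likelihood is multivariate normal per subject and is evaluated
in closed form. Ordinal outcomes with K+1 ordered categories follow a
cumulative-logit latent-variable model: a latent Z'_ij = x_ij' beta + z_ij' u_i
+ eps_ij with standard-logistic eps (variance pi^2/3) is cut at thresholds
tau_1 < ... < tau_K; the marginal likelihood integrates the random effects out
by Gauss-Hermite quadrature. The fixed-effect intercept of the ordinal model
is fixed at 0 and all K thresholds are estimated (the usual cumulative-logit
identification, removing the location aliasing between intercept and
thresholds).

Estimation is by maximum likelihood over an unconstrained parameterization:
log-Cholesky for Omega_u, log variances, and tau_1 plus log-increments for the
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1

from .data import DesignSpec, LongitudinalDataset, ValidationError, build_design

__all__ = [
    "MEMParameters",
    "MixedEffectsModel",
    "MixedEffectsResults",
    "fit_mem",
    "gaussian_marginal_loglik",
    "gaussian_subject_logliks",
    "ordinal_category_probs",
    "ordinal_marginal_loglik",
    "ordinal_subject_logliks",
    "predict_random_effects",
]

MAX_RANDOM_DIM = 3
_LOGVAR_BOUND = 23.0
_TINY = 1e-300


@dataclass
class MEMParameters:
    """Parameters of one (class-specific or single-class) mixed effects model.

    ``fixed`` has one entry per fixed-effect design column (for ordinal models
    the first entry is the intercept, fixed at 0). ``re_cov`` is the q x q
    random-effect covariance (``None`` or empty when there are no random
    terms). ``resid_var`` is a scalar or a per-grid-time vector (continuous
    only). ``thresholds`` holds the K strictly increasing cut-points (ordinal
    only).
    """

    fixed: np.ndarray
    re_cov: np.ndarray | None = None
    resid_var: float | np.ndarray | None = None
    thresholds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fixed = np.atleast_1d(np.asarray(self.fixed, dtype=float))
        if self.re_cov is not None:
            self.re_cov = np.atleast_2d(np.asarray(self.re_cov, dtype=float))
            if self.re_cov.size == 0:
                self.re_cov = None
        if self.thresholds is not None:
            self.thresholds = np.atleast_1d(
                np.asarray(self.thresholds, dtype=float))
            if np.any(np.diff(self.thresholds) <= 0):
                raise ValidationError("thresholds must be strictly increasing")
        if self.resid_var is not None:
            rv = np.asarray(self.resid_var, dtype=float)
            if np.any(rv <= 0):
                raise ValidationError("residual variances must be positive")

    @property
    def n_random(self) -> int:
        return 0 if self.re_cov is None else self.re_cov.shape[0]


# ---------------------------------------------------------------------------
# parameter packing


class SingleClassLayout:
    """Maps a MEMParameters to/from an unconstrained vector.

    Blocks (in order): free fixed effects (all of beta for continuous, beta
    without intercept for ordinal); log-Cholesky of Omega_u (row-wise lower
    triangle, log on the diagonal); log residual variance(s) (continuous);
    tau_1 and log threshold increments (ordinal).
    """

    def __init__(self, family: str, p: int, q: int, resid_mode: str,
                 n_grid: int | None, n_categories: int | None,
                 constrain_re_zero: bool = False) -> None:
        self.family = family
        self.p = p
        self.q = q
        self.resid_mode = resid_mode
        self.constrain_re_zero = constrain_re_zero
        self.n_beta = p if family == "continuous" else p - 1
        self.n_chol = 0 if constrain_re_zero else q * (q + 1) // 2
        if family == "continuous":
            self.n_resid = 1 if resid_mode == "constant" else int(n_grid)
            self.n_tau = 0
        else:
            self.n_resid = 0
            self.n_tau = int(n_categories) - 1
        self.size = self.n_beta + self.n_chol + self.n_resid + self.n_tau

    def pack(self, params: MEMParameters) -> np.ndarray:
        x = np.empty(self.size)
        i = 0
        beta = params.fixed if self.family == "continuous" else params.fixed[1:]
        x[i:i + self.n_beta] = beta
        i += self.n_beta
        if self.n_chol:
            L = np.linalg.cholesky(
                params.re_cov + 1e-10 * np.eye(self.q))
            for r in range(self.q):
                for c in range(r + 1):
                    x[i] = np.log(max(L[r, r], 1e-8)) if r == c else L[r, c]
                    i += 1
        if self.n_resid:
            rv = np.atleast_1d(np.asarray(params.resid_var, dtype=float))
            if rv.size == 1 and self.n_resid > 1:
                rv = np.full(self.n_resid, rv[0])
            x[i:i + self.n_resid] = np.log(rv)
            i += self.n_resid
        if self.n_tau:
            tau = params.thresholds
            x[i] = tau[0]
            x[i + 1:i + self.n_tau] = np.log(np.diff(tau))
        return x

    def unpack(self, x: np.ndarray) -> MEMParameters:
        i = 0
        if self.family == "continuous":
            fixed = np.asarray(x[i:i + self.n_beta], dtype=float).copy()
        else:
            fixed = np.r_[0.0, x[i:i + self.n_beta]]
        i += self.n_beta
        re_cov = None
        if self.q:
            if self.constrain_re_zero:
                re_cov = np.zeros((self.q, self.q))
            else:
                L = np.zeros((self.q, self.q))
                for r in range(self.q):
                    for c in range(r + 1):
                        L[r, c] = np.exp(x[i]) if r == c else x[i]
                        i += 1
                re_cov = L @ L.T
        resid_var = None
        if self.n_resid:
            rv = np.exp(x[i:i + self.n_resid])
            resid_var = float(rv[0]) if self.n_resid == 1 else rv
            i += self.n_resid
        thresholds = None
        if self.n_tau:
            thresholds = np.cumsum(
                np.r_[x[i], np.exp(x[i + 1:i + self.n_tau])])
        return MEMParameters(fixed=fixed, re_cov=re_cov,
                             resid_var=resid_var, thresholds=thresholds)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = [(None, None)] * self.n_beta
        k = 0
        for r in range(self.q if self.n_chol else 0):
            for c in range(r + 1):
                b.append((-_LOGVAR_BOUND, _LOGVAR_BOUND) if r == c
                         else (-1e3, 1e3))
                k += 1
        b += [(-_LOGVAR_BOUND, _LOGVAR_BOUND)] * self.n_resid
        if self.n_tau:
            b.append((None, None))
            b += [(-_LOGVAR_BOUND, _LOGVAR_BOUND)] * (self.n_tau - 1)
        return b


def layout_for(dataset: LongitudinalDataset, spec: DesignSpec,
               constrain_re_zero: bool = False) -> SingleClassLayout:
    n_grid = None if dataset.grid is None else dataset.grid.size
    p = spec.n_fixed(dataset.grid)
    return SingleClassLayout(
        dataset.outcome_family, p, spec.n_random, spec.residual_variance_mode,
        n_grid, dataset.n_categories, constrain_re_zero=constrain_re_zero)


# ---------------------------------------------------------------------------
# Gaussian marginal likelihood


def _resid_vars_at(params: MEMParameters, grid_idx: np.ndarray | None,
                   n_times: int) -> np.ndarray:
    rv = np.atleast_1d(np.asarray(params.resid_var, dtype=float))
    if rv.size == 1:
        return np.full(n_times, rv[0])
    if grid_idx is None:
        raise ValidationError("time-specific residual variances need a grid")
    return rv[grid_idx]


def gaussian_subject_logliks(dataset: LongitudinalDataset, spec: DesignSpec,
                             params: MEMParameters) -> np.ndarray:
    """Per-subject marginal normal log-likelihood (vector of length N)."""
    if dataset.outcome_family != "continuous":
        raise ValidationError("gaussian likelihood needs a continuous outcome")
    out = np.empty(dataset.n_subjects)
    q = params.n_random
    if q:
        w = np.linalg.eigvalsh(params.re_cov)
        if w.min() < -1e-8:
            raise ValidationError("random-effect covariance is not PSD")
    for g in dataset.pattern_groups():
        X, Z = build_design(g.times, spec, dataset.grid, dataset.grid_tol)
        rv = _resid_vars_at(params, g.grid_idx, g.times.size)
        J = g.times.size
        R = g.values - X @ params.fixed  # n_g x J
        if q:
            V = Z @ params.re_cov @ Z.T + np.diag(rv)
            L = np.linalg.cholesky(V)
            sol = solve_triangular(L, R.T, lower=True)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            quad = np.einsum("ji,ji->i", sol, sol)
        else:
            logdet = np.log(rv).sum()
            quad = (R * R / rv).sum(axis=1)
        out[g.subject_rows] = -0.5 * (J * np.log(2 * np.pi) + logdet + quad)
    return out


def gaussian_marginal_loglik(dataset: LongitudinalDataset, spec: DesignSpec,
                             params: MEMParameters) -> float:
    """Total marginal log-likelihood of the linear mixed model."""
    return float(gaussian_subject_logliks(dataset, spec, params).sum())


# ---------------------------------------------------------------------------
# ordinal cumulative-logit likelihood


def ordinal_category_probs(linear_predictor, thresholds) -> np.ndarray:
    """Cumulative-logit category probabilities.

    ``P(Z=1) = F(tau_1 - eta)``, ``P(Z=k) = F(tau_k - eta) - F(tau_{k-1} -
    eta)``, ``P(Z=K+1) = 1 - F(tau_K - eta)`` with F the standard logistic
    CDF. The trailing axis of the result indexes the K+1 categories.
    """
    tau = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if np.any(np.diff(tau) <= 0):
        raise ValidationError("thresholds must be strictly increasing")
    eta = np.asarray(linear_predictor, dtype=float)
    cum = expit(tau - eta[..., None])  # ..., K
    ones = np.ones(eta.shape + (1,))
    zeros = np.zeros(eta.shape + (1,))
    return np.diff(np.concatenate([zeros, cum, ones], axis=-1), axis=-1)


@lru_cache(maxsize=32)
def _gh_nodes(q: int, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Hermite rule for a q-dim standard normal.

    Returns standardized nodes (Q x q, already scaled by sqrt 2) and log
    weights such that ``E[f(U)] ~= sum_k exp(logw_k) f(nodes_k)`` for
    U ~ N(0, I_q).
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.meshgrid(*([x] * q), indexing="ij")
    nodes = np.sqrt(2.0) * np.stack([g.ravel() for g in grids], axis=1)
    wg = np.meshgrid(*([np.log(w)] * q), indexing="ij")
    logw = sum(g.ravel() for g in wg) - 0.5 * q * np.log(np.pi)
    return nodes, logw


def ordinal_subject_logliks(dataset: LongitudinalDataset, spec: DesignSpec,
                            params: MEMParameters,
                            n_quad_nodes: int = 15) -> np.ndarray:
    """Per-subject ordinal log-likelihood, random effects integrated out."""
    if dataset.outcome_family != "ordinal":
        raise ValidationError("ordinal likelihood needs an ordinal outcome")
    if n_quad_nodes < 1:
        raise ValidationError("need at least one quadrature node")
    q = params.n_random
    if q > MAX_RANDOM_DIM:
        raise ValidationError(f"random-effect dimension capped at {MAX_RANDOM_DIM}")
    out = np.empty(dataset.n_subjects)
    degenerate = q == 0 or np.allclose(params.re_cov, 0.0)
    if not degenerate:
        Lr = np.linalg.cholesky(params.re_cov + 1e-12 * np.eye(q))
        nodes, logw = _gh_nodes(q, n_quad_nodes)
        U = nodes @ Lr.T  # Q x q draws from N(0, Omega)
    for g in dataset.pattern_groups():
        X, Z = build_design(g.times, spec, dataset.grid, dataset.grid_tol)
        eta0 = X @ params.fixed  # J
        idx = g.values.astype(int) - 1  # n_g x J
        if degenerate:
            probs = ordinal_category_probs(eta0, params.thresholds)  # J x K+1
            lp = np.log(np.maximum(probs, _TINY))
            out[g.subject_rows] = np.take_along_axis(
                lp[None, :, :].repeat(idx.shape[0], axis=0),
                idx[:, :, None], axis=2)[:, :, 0].sum(axis=1)
        else:
            eta = eta0[:, None] + Z @ U.T  # J x Q
            probs = ordinal_category_probs(eta, params.thresholds)  # J x Q x K+1
            lp = np.log(np.maximum(probs, _TINY))
            # S[n, k] = sum_j lp[j, k, z_nj]
            S = np.zeros((idx.shape[0], U.shape[0]))
            for j in range(g.times.size):
                S += lp[j, :, :].T[idx[:, j], :]
            out[g.subject_rows] = logsumexp(S + logw[None, :], axis=1)
    return out


def ordinal_marginal_loglik(dataset: LongitudinalDataset, spec: DesignSpec,
                            params: MEMParameters,
                            n_quad_nodes: int = 15) -> float:
    """Total ordinal marginal log-likelihood (Gauss-Hermite quadrature)."""
    return float(
        ordinal_subject_logliks(dataset, spec, params, n_quad_nodes).sum())


def subject_logliks(dataset: LongitudinalDataset, spec: DesignSpec,
                    params: MEMParameters, n_quad_nodes: int = 15) -> np.ndarray:
    """Family-dispatching per-subject log-likelihood."""
    if dataset.outcome_family == "continuous":
        return gaussian_subject_logliks(dataset, spec, params)
    return ordinal_subject_logliks(dataset, spec, params, n_quad_nodes)


# ---------------------------------------------------------------------------
# empirical-Bayes random-effect prediction


def predict_random_effects(dataset: LongitudinalDataset, spec: DesignSpec,
                           params: MEMParameters,
                           n_quad_nodes: int = 15) -> np.ndarray:
    """Posterior means of the subject-level random effects (N x q).

    Continuous family: closed form ``Omega Z' V^{-1} (z - X beta)``; ordinal
    family: quadrature posterior mean with the same rule as the likelihood.
    """
    q = params.n_random
    if q == 0:
        return np.empty((dataset.n_subjects, 0))
    out = np.empty((dataset.n_subjects, q))
    if dataset.outcome_family == "continuous":
        for g in dataset.pattern_groups():
            X, Z = build_design(g.times, spec, dataset.grid, dataset.grid_tol)
            rv = _resid_vars_at(params, g.grid_idx, g.times.size)
            V = Z @ params.re_cov @ Z.T + np.diag(rv)
            R = g.values - X @ params.fixed
            M = cho_solve(cho_factor(V, lower=True), Z @ params.re_cov)
            out[g.subject_rows] = R @ M
        return out
    if np.allclose(params.re_cov, 0.0):
        return np.zeros((dataset.n_subjects, q))
    Lr = np.linalg.cholesky(params.re_cov + 1e-12 * np.eye(q))
    nodes, logw = _gh_nodes(q, n_quad_nodes)
    U = nodes @ Lr.T
    for g in dataset.pattern_groups():
        X, Z = build_design(g.times, spec, dataset.grid, dataset.grid_tol)
        eta = (X @ params.fixed)[:, None] + Z @ U.T
        lp = np.log(np.maximum(
            ordinal_category_probs(eta, params.thresholds), _TINY))
        idx = g.values.astype(int) - 1
        S = np.zeros((idx.shape[0], U.shape[0]))
        for j in range(g.times.size):
            S += lp[j, :, :].T[idx[:, j], :]
        logpost = S + logw[None, :]
        logpost -= logsumexp(logpost, axis=1, keepdims=True)
        out[g.subject_rows] = np.exp(logpost) @ U
    return out


# ---------------------------------------------------------------------------
# fitting


class MixedEffectsModel:
    """Single-class mixed effects model (continuous or ordinal outcome).

    Parameters
    ----------
    dataset
        A :class:`~trajmix.data.LongitudinalDataset`.
    spec
        The :class:`~trajmix.data.DesignSpec` for the fixed and random parts.
    n_quad_nodes
        Gauss-Hermite nodes per random-effect dimension (ordinal family).
    """

    def __init__(self, dataset: LongitudinalDataset, spec: DesignSpec,
                 n_quad_nodes: int = 15) -> None:
        self.dataset = dataset
        self.spec = spec
        self.n_quad_nodes = n_quad_nodes
        self._check_identifiable()
        self.layout = layout_for(dataset, spec)

    def _check_identifiable(self) -> None:
        n_distinct = np.unique(self.dataset.times).size
        if self.spec.basis == "polynomial" and n_distinct <= self.spec.degree:
            raise ValidationError(
                f"polynomial degree {self.spec.degree} needs more than "
                f"{self.spec.degree} distinct observation times "
                f"(found {n_distinct})")
        q = self.spec.n_random
        if q > MAX_RANDOM_DIM:
            raise ValidationError(
                f"random-effect dimension capped at {MAX_RANDOM_DIM}")
        if q:
            max_obs = max((s.stop - s.start)
                          for s in self.dataset.subject_slices())
            if max_obs < q + 1:
                raise ValidationError(
                    f"no subject has the >= {q + 1} observations needed to "
                    f"identify a {q}-dimensional random effect")

    # -- likelihood ----------------------------------------------------------

    def loglik(self, params: MEMParameters) -> float:
        return float(subject_logliks(
            self.dataset, self.spec, params, self.n_quad_nodes).sum())

    def _negloglik_packed(self, x: np.ndarray) -> float:
        try:
            ll = self.loglik(self.layout.unpack(x))
        except (np.linalg.LinAlgError, ValidationError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    # -- starting values -----------------------------------------------------

    def start_params(self) -> MEMParameters:
        ds, spec = self.dataset, self.spec
        X, Z = build_design(ds.times, spec, ds.grid, ds.grid_tol)
        q = spec.n_random
        if ds.outcome_family == "continuous":
            beta, *_ = np.linalg.lstsq(X, ds.values, rcond=None)
            resid = ds.values - X @ beta
            s2 = max(float(np.var(resid)), 1e-6)
            re_cov = None
            if q:
                scale = np.maximum(np.mean(Z * Z, axis=0), 1e-8)
                re_cov = np.diag(0.5 * s2 / scale)
                s2 = 0.5 * s2
            rv = s2 if spec.residual_variance_mode == "constant" else \
                np.full(ds.grid.size, s2)
            return MEMParameters(fixed=beta, re_cov=re_cov, resid_var=rv)
        K = ds.n_categories - 1
        freq = np.bincount(ds.values.astype(int),
                           minlength=ds.n_categories + 1)[1:] / ds.n_records
        cum = np.clip(np.cumsum(freq)[:-1], 1e-3, 1 - 1e-3)
        tau = np.log(cum / (1 - cum))
        tau = np.maximum.accumulate(tau + 1e-6 * np.arange(K))
        tau += 1e-6 * np.arange(K)  # enforce strict increase on ties
        fixed = np.zeros(self.layout.p)
        re_cov = np.eye(q) if q else None
        return MEMParameters(fixed=fixed, re_cov=re_cov, thresholds=tau)

    # -- fit -------------------------------------------------------------------

    def fit(self, start: MEMParameters | None = None, maxiter: int = 500,
            gtol: float = 1e-7, compute_se: bool = True) -> "MixedEffectsResults":
        start = start if start is not None else self.start_params()
        x0 = self.layout.pack(start)
        ll0 = -self._negloglik_packed(x0)
        res = optimize.minimize(
            self._negloglik_packed, x0, method="L-BFGS-B",
            bounds=self.layout.bounds(),
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol,
                     "maxfun": 200000})
        x, ll = res.x, -res.fun
        if ll < ll0:  # never return worse than the initialization
            x, ll = x0, ll0
        params = self.layout.unpack(x)
        cov = bse = None
        if compute_se:
            cov, bse = self._covariance(x)
        degenerate = bool(
            self.layout.n_resid
            and np.any(np.atleast_1d(np.log(
                np.atleast_1d(params.resid_var))) <= -_LOGVAR_BOUND + 1))
        report = {
            "converged": bool(res.success),
            "message": str(res.message),
            "n_iter": int(res.nit),
            "grad_norm": float(np.max(np.abs(res.jac)))
            if res.jac is not None else np.nan,
            "degenerate_variance": degenerate,
        }
        return MixedEffectsResults(
            model=self, params=params, packed=x, loglik=float(ll),
            cov_params=cov, bse_packed=bse, convergence=report)

    def _covariance(self, x: np.ndarray) -> tuple[np.ndarray | None, np.ndarray | None]:
        try:
            H = approx_hess1(x, self._negloglik_packed)
            cov = np.linalg.pinv(H)
            d = np.diag(cov).copy()
            d[d < 0] = np.nan
            return cov, np.sqrt(d)
        except Exception:
            return None, None


@dataclass
class MixedEffectsResults:
    """Maximum-likelihood fit of a :class:`MixedEffectsModel`."""

    model: MixedEffectsModel
    params: MEMParameters
    packed: np.ndarray
    loglik: float
    cov_params: np.ndarray | None
    bse_packed: np.ndarray | None
    convergence: dict

    @property
    def converged(self) -> bool:
        return self.convergence["converged"]

    @property
    def n_free_params(self) -> int:
        return self.model.layout.size

    @property
    def se_fixed(self) -> np.ndarray:
        """Standard errors of the fixed effects (NaN where unavailable)."""
        p = self.model.layout.p
        out = np.full(p, np.nan)
        if self.bse_packed is None:
            return out
        nb = self.model.layout.n_beta
        if self.model.dataset.outcome_family == "continuous":
            out[:nb] = self.bse_packed[:nb]
        else:
            out[0] = 0.0
            out[1:nb + 1] = self.bse_packed[:nb]
        return out

    def predict_random_effects(self) -> np.ndarray:
        return predict_random_effects(
            self.model.dataset, self.model.spec, self.params,
            self.model.n_quad_nodes)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "family": self.model.dataset.outcome_family,
            "fixed": p.fixed.tolist(),
            "se_fixed": self.se_fixed.tolist(),
            "re_cov": None if p.re_cov is None else p.re_cov.tolist(),
            "resid_var": None if p.resid_var is None
            else np.atleast_1d(p.resid_var).tolist(),
            "thresholds": None if p.thresholds is None
            else p.thresholds.tolist(),
            "loglik": self.loglik,
            "n_free_params": self.n_free_params,
            "convergence": self.convergence,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Mixed effects model ({} outcome)".format(d["family"]),
            f"  log-likelihood: {self.loglik:.4f}   "
            f"free parameters: {self.n_free_params}",
            "  fixed effects: "
            + ", ".join(f"{b:.4f} (se {s:.4f})"
                        for b, s in zip(d["fixed"], d["se_fixed"])),
        ]
        if d["re_cov"] is not None:
            lines.append("  random-effect covariance: "
                         + np.array_str(np.asarray(d["re_cov"]), precision=4))
        if d["resid_var"] is not None:
            lines.append("  residual variance: "
                         + ", ".join(f"{v:.4f}" for v in d["resid_var"]))
        if d["thresholds"] is not None:
            lines.append("  thresholds: "
                         + ", ".join(f"{t:.4f}" for t in d["thresholds"]))
        if not self.converged:
            lines.append("  WARNING: optimizer did not report convergence")
        return "\n".join(lines)


def fit_mem(dataset: LongitudinalDataset, spec: DesignSpec,
            init: MEMParameters | None = None, n_quad_nodes: int = 15,
            **fit_kw) -> MixedEffectsResults:
    """Convenience wrapper: build a :class:`MixedEffectsModel` and fit it."""
    return MixedEffectsModel(dataset, spec, n_quad_nodes).fit(
        start=init, **fit_kw)
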