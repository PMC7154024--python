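"""Seeded generative module for latent-class longitudinal data.

A :class:`SimulationScenario` fully specifies a generative model from any of
the supported families — class membership (fixed probabilities or linked to a
standard-normal covariate through a multinomial-logistic model), per-class
trajectories, within-class random effects, residual noise (Gaussian for
continuous outcomes, standard-logistic latent noise cut at thresholds for
ordinal ones), a class-linked distal outcome, and monotone missing-at-random
dropout. Two presets emulate the structure of a typical birth-cohort
application: a right-skewed continuous outcome at six ages (a BMI-like
measure) and a three-category ordinal outcome at eight ages (a parental-report
fussy-eating-like item). The preset trajectory shapes and covariances are
illustrative choices of this package, not calibrated to any restricted
cohort data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from .data import DesignSpec, LongitudinalDataset, ValidationError, build_design
from .mixture import MixtureResults

__all__ = [
    "MARDropout",
    "SimulationScenario",
    "apply_mar_dropout",
    "preset_bmi_like",
    "preset_fussy_like",
    "scenario_from_results",
    "simulate",
]


@dataclass(frozen=True)
class MARDropout:
    """Monotone dropout whose hazard depends only on observed information.

    At each wave after the first, a still-in-study subject drops out with
    probability ``expit(intercept + coef_prev * previous_observed_value +
    coef_cov * covariate)``; once dropped, all later waves are missing. The
    mechanism may depend only on the previous observed outcome and the
    baseline covariate (``depends_on``); referencing the current, unobserved
    value would make the missingness not-at-random and is rejected.
    """

    intercept: float
    coef_prev: float = 0.0
    coef_cov: float = 0.0
    depends_on: tuple[str, ...] = ("previous", "covariate")

    def __post_init__(self) -> None:
        allowed = {"previous", "covariate"}
        bad = set(self.depends_on) - allowed
        if bad:
            raise ValidationError(
                f"dropout may depend only on {sorted(allowed)}; "
                f"{sorted(bad)} would violate the MAR construction")


@dataclass
class SimulationScenario:
    """Complete generative specification for :func:`simulate`."""

    n_subjects: int
    design: DesignSpec
    class_fixed: np.ndarray              # C x p fixed effects per class
    outcome_family: str = "continuous"
    grid: tuple[float, ...] = ()
    class_probs: np.ndarray | None = None
    membership_gamma: np.ndarray | None = None  # C x 2, row 0 all zeros
    covariance_mode: str = "none"
    re_cov: np.ndarray | list | None = None
    resid_var: float | np.ndarray | list = 1.0
    thresholds: np.ndarray | list | None = None  # K, or C x K (ordinal)
    n_categories: int | None = None
    with_covariate: bool = False
    distal_means: np.ndarray | None = None
    distal_sd: float = 0.3
    distal_log: bool = True
    exponentiate: bool = False           # generate on log scale, report exp
    missing: MARDropout | None = None

    def __post_init__(self) -> None:
        self.class_fixed = np.atleast_2d(
            np.asarray(self.class_fixed, dtype=float))
        self.grid = tuple(float(t) for t in self.grid)
        if len(self.grid) < 1:
            raise ValidationError("scenario needs a nonempty time grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing")
        C = self.class_fixed.shape[0]
        if self.class_probs is not None:
            self.class_probs = np.asarray(self.class_probs, dtype=float)
            if self.class_probs.shape != (C,):
                raise ValidationError("class_probs length must match classes")
            if np.any(self.class_probs < 0) or \
                    abs(self.class_probs.sum() - 1) > 1e-8:
                raise ValidationError("class_probs must lie on the simplex")
        if self.membership_gamma is not None:
            self.membership_gamma = np.atleast_2d(
                np.asarray(self.membership_gamma, dtype=float))
            if self.membership_gamma.shape[0] != C:
                raise ValidationError("membership_gamma needs one row per class")
        if self.class_probs is None and self.membership_gamma is None:
            raise ValidationError(
                "give class_probs or membership_gamma (covariate-linked)")
        if self.outcome_family == "ordinal":
            if self.thresholds is None or self.n_categories is None:
                raise ValidationError(
                    "ordinal scenarios need thresholds and n_categories")
            tau = np.asarray(self.thresholds, dtype=float)
            tau = np.atleast_2d(tau)
            if tau.shape[0] == 1 and C > 1:
                tau = np.repeat(tau, C, axis=0)
            if np.any(np.diff(tau, axis=1) <= 0):
                raise ValidationError("thresholds must be strictly increasing")
            self.thresholds = tau
        if self.distal_means is not None:
            self.distal_means = np.asarray(self.distal_means, dtype=float)
        if self.re_cov is not None:
            # normalize: a 3-d array (or list of matrices) is per-class,
            # a single square matrix is shared
            if isinstance(self.re_cov, (list, tuple)) and \
                    np.asarray(self.re_cov[0]).ndim == 2:
                self.re_cov = [np.atleast_2d(np.asarray(m, dtype=float))
                               for m in self.re_cov]
                if len(self.re_cov) != C:
                    raise ValidationError(
                        "per-class re_cov needs one matrix per class")
            else:
                arr = np.atleast_2d(np.asarray(self.re_cov, dtype=float))
                if arr.ndim == 3:
                    self.re_cov = list(arr)
                else:
                    self.re_cov = arr

    @property
    def n_classes(self) -> int:
        return self.class_fixed.shape[0]

    def _re_cov_for(self, c: int) -> np.ndarray | None:
        if self.covariance_mode == "none" or self.re_cov is None:
            return None
        if isinstance(self.re_cov, list):
            return self.re_cov[c]
        return self.re_cov

    def _resid_sd_rec(self, c: int, grid_idx: np.ndarray) -> np.ndarray:
        rv = self.resid_var
        if isinstance(rv, (list, tuple)):
            rv = rv[c]
        rv = np.atleast_1d(np.asarray(rv, dtype=float))
        if rv.size == 1:
            return np.sqrt(np.full(grid_idx.size, rv[0]))
        return np.sqrt(rv[grid_idx])


def simulate(scenario: SimulationScenario,
             seed: int = 0) -> tuple[LongitudinalDataset, pd.DataFrame]:
    """Draw a dataset from the scenario; returns ``(dataset, truth)``.

    ``truth`` has one row per subject: true class (1-based), true random
    effects, the covariate and the distal outcome — for recovery testing.
    Identical scenario + seed give a bit-identical dataset.
    """
    rng = np.random.default_rng(seed)
    N, C = scenario.n_subjects, scenario.n_classes
    grid = np.asarray(scenario.grid)
    J = grid.size
    X, Z = build_design(grid, scenario.design, grid)
    q = Z.shape[1]

    x_cov = (rng.standard_normal(N)
             if (scenario.with_covariate
                 or scenario.membership_gamma is not None) else None)
    if scenario.membership_gamma is not None:
        eta = np.column_stack([np.ones(N), x_cov]) @ scenario.membership_gamma.T
        lp = eta - logsumexp(eta, axis=1, keepdims=True)
        probs = np.exp(lp)
        u = rng.random(N)
        classes = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    else:
        classes = rng.choice(C, size=N, p=scenario.class_probs)

    re = np.zeros((N, q))
    if q and scenario.covariance_mode != "none":
        for c in range(C):
            omega = scenario._re_cov_for(c)
            mask = classes == c
            if omega is not None and mask.any():
                L = np.linalg.cholesky(omega + 1e-12 * np.eye(q))
                re[mask] = rng.standard_normal((mask.sum(), q)) @ L.T

    gidx = np.arange(J)
    rows_id = np.repeat(np.arange(N), J)
    rows_t = np.tile(grid, N)
    eta = scenario.class_fixed[classes] @ X.T  # N x J class means
    if q:
        eta = eta + re @ Z.T
    if scenario.outcome_family == "continuous":
        noise = np.empty((N, J))
        for c in range(C):
            mask = classes == c
            sd = scenario._resid_sd_rec(c, gidx)
            noise[mask] = rng.standard_normal((mask.sum(), J)) * sd[None, :]
        vals = eta + noise
        if scenario.exponentiate:
            vals = np.exp(vals)
    else:
        latent = eta + rng.logistic(size=(N, J))
        tau = scenario.thresholds[classes]  # N x K
        vals = 1 + (latent[:, :, None] > tau[:, None, :]).sum(axis=2)
        vals = vals.astype(float)

    distal = None
    if scenario.distal_means is not None:
        mu = scenario.distal_means[classes]
        draw = mu + scenario.distal_sd * rng.standard_normal(N)
        distal = np.exp(draw) if scenario.distal_log else draw

    tab = pd.DataFrame({"id": rows_id, "time": rows_t, "value": vals.ravel()})
    covariates = (pd.DataFrame({"x": x_cov}, index=np.arange(N))
                  if x_cov is not None else None)
    ds = LongitudinalDataset(
        tab, outcome_family=scenario.outcome_family,
        n_categories=scenario.n_categories, covariates=covariates,
        distal=pd.Series(distal, index=np.arange(N))
        if distal is not None else None,
        grid=grid)
    if scenario.missing is not None:
        ds = apply_mar_dropout(ds, scenario.missing,
                               seed=int(rng.integers(2 ** 31)))
    truth = pd.DataFrame({"id": np.arange(N), "true_class": classes + 1})
    for k in range(q):
        truth[f"u{k}"] = re[:, k]
    if x_cov is not None:
        truth["covariate"] = x_cov
    if distal is not None:
        truth["distal"] = distal
    return ds, truth


def apply_mar_dropout(dataset: LongitudinalDataset, mechanism: MARDropout,
                      seed: int = 0) -> LongitudinalDataset:
    """Apply monotone MAR dropout wave by wave; reports realized missingness.

    The returned dataset carries a ``dropout_report`` frame with the realized
    per-wave missingness proportions.
    """
    if dataset.grid is None:
        raise ValidationError("MAR dropout needs a common wave grid")
    rng = np.random.default_rng(seed)
    tab = dataset.table
    J = dataset.grid.size
    # wide view: value per subject per wave (NaN where already absent)
    wide = np.full((dataset.n_subjects, J), np.nan)
    wide[dataset._sub_codes, dataset.grid_idx] = dataset.values
    cov = None
    if "covariate" in getattr(dataset.covariates, "columns", []):
        cov = dataset.covariates["covariate"].to_numpy(dtype=float)
    elif dataset.covariates is not None and dataset.covariates.shape[1] >= 1:
        cov = dataset.covariates.iloc[:, 0].to_numpy(dtype=float)
    alive = np.ones(dataset.n_subjects, dtype=bool)
    keep = np.ones_like(wide, dtype=bool)
    last_seen = wide[:, 0].copy()
    for j in range(1, J):
        eta = np.full(dataset.n_subjects, mechanism.intercept, dtype=float)
        if "previous" in mechanism.depends_on:
            eta = eta + mechanism.coef_prev * np.nan_to_num(last_seen)
        if cov is not None and "covariate" in mechanism.depends_on:
            eta = eta + mechanism.coef_cov * cov
        p_drop = expit(eta)
        drop_now = alive & (rng.random(dataset.n_subjects) < p_drop)
        alive = alive & ~drop_now
        keep[~alive, j] = False
        obs = alive & ~np.isnan(wide[:, j])
        last_seen[obs] = wide[obs, j]
    keep &= ~np.isnan(wide)
    sub_idx, wave_idx = np.nonzero(keep)
    tab_new = pd.DataFrame({
        "id": dataset.subjects[sub_idx],
        "time": dataset.grid[wave_idx],
        "value": wide[sub_idx, wave_idx]})
    out = LongitudinalDataset(
        tab_new, outcome_family=dataset.outcome_family,
        n_categories=dataset.n_categories,
        covariates=dataset.covariates, distal=dataset.distal,
        grid=dataset.grid, grid_tol=dataset.grid_tol,
        log_transformed=dataset.log_transformed)
    observed = keep.sum(axis=0)
    out.dropout_report = pd.DataFrame({
        "time": dataset.grid,
        "n_observed": observed,
        "pct_missing": 100.0 * (1 - observed / dataset.n_subjects)})
    return out


# ---------------------------------------------------------------------------
# presets


def preset_bmi_like(n_subjects: int = 4517) -> SimulationScenario:
    """Right-skewed continuous outcome at ages 8, 10, 11, 12, 13 and 16.

    Three classes with probabilities near (0.88, 0.07, 0.05): a dominant
    slowly-rising class, a steeply rising class, and a parallel-but-higher
    class. Trajectories are quadratic on the log scale with a shared
    random-effect covariance over intercept, linear and quadratic terms; the
    reported outcome is exponentiated, inducing the right skew typical of
    BMI. Class membership is linked to a standard-normal antecedent
    covariate, and a right-skewed distal outcome (log-normal around
    class-specific means) plus mild MAR dropout complete the scenario.
    """
    design = DesignSpec(degree=2, random_terms=(0, 1, 2), centre=8.0)
    class_fixed = np.array([
        [2.81, 0.020, 0.0012],   # dominant, slow rise (log scale)
        [2.86, 0.030, 0.0045],   # steeply rising
        [3.02, 0.020, 0.0012],   # parallel, higher
    ])
    sds = np.array([0.10, 0.012, 0.0015])
    corr = np.array([[1.0, 0.3, -0.2],
                     [0.3, 1.0, -0.4],
                     [-0.2, -0.4, 1.0]])
    re_cov = corr * np.outer(sds, sds)
    # intercepts give marginal shares near (0.88, 0.07, 0.05) for x ~ N(0,1)
    gamma = np.array([[0.0, 0.0],
                      [-2.56, 0.10],
                      [-2.92, 0.28]])
    return SimulationScenario(
        n_subjects=n_subjects,
        design=design,
        grid=(8.0, 10.0, 11.0, 12.0, 13.0, 16.0),
        class_fixed=class_fixed,
        membership_gamma=gamma,
        covariance_mode="shared",
        re_cov=re_cov,
        resid_var=0.0012,
        with_covariate=True,
        distal_means=np.array([1.00, 1.35, 1.30]),
        distal_sd=0.35,
        distal_log=True,
        exponentiate=True,
        missing=MARDropout(intercept=-3.8, coef_prev=0.08, coef_cov=-0.10),
    )


def preset_fussy_like(n_subjects: int = 5750) -> SimulationScenario:
    """Three-category ordinal outcome at eight ages from 1.3 to 9.6 years.

    Three classes with probabilities (0.751, 0.165, 0.084): a stable class,
    a class whose lowest ("did not happen") category grows with age, and a
    class whose highest ("worried") category grows with age. Latent
    trajectories are linear + quadratic in age (centred at the first wave)
    with a shared random intercept; thresholds are class-specific.
    """
    design = DesignSpec(degree=2, random_terms=(0,), centre=1.3)
    class_fixed = np.array([
        [0.0, 0.00, 0.000],     # stable
        [0.0, -0.40, 0.008],    # drifts down -> bottom category grows
        [0.0, 0.45, -0.010],    # drifts up -> top category grows
    ])
    thresholds = np.array([
        [-1.2, 1.6],
        [0.2, 2.6],
        [-0.4, 1.4],
    ])
    gamma = np.array([[0.0, 0.0],
                      [-1.52, 0.15],
                      [-2.19, -0.08]])
    return SimulationScenario(
        n_subjects=n_subjects,
        design=design,
        grid=(1.3, 2.0, 3.2, 4.6, 5.5, 6.9, 8.7, 9.6),
        class_fixed=class_fixed,
        outcome_family="ordinal",
        n_categories=3,
        thresholds=thresholds,
        membership_gamma=gamma,
        covariance_mode="shared",
        re_cov=np.array([[1.0]]),
        with_covariate=True,
        distal_means=np.array([1.00, 1.02, 0.97]),
        distal_sd=0.35,
        distal_log=True,
        missing=MARDropout(intercept=-2.8, coef_prev=0.10, coef_cov=-0.10),
    )


def scenario_from_results(fit: MixtureResults) -> SimulationScenario:
    """Generative scenario matching a fitted mixture (for the BLRT).

    Simulates complete balanced data on the fitted model's grid with the same
    number of subjects; the observed missingness pattern is not replicated.
    """
    ds = fit.model.dataset
    spec = fit.spec
    if ds.grid is None:
        raise ValidationError("parametric bootstrap needs a common grid")
    C = fit.n_classes
    cp = fit.params.class_params
    if spec.covariance_mode == "class_specific":
        re_cov = [p.re_cov for p in cp]
    elif spec.covariance_mode == "shared":
        re_cov = cp[0].re_cov
    else:
        re_cov = None
    if ds.outcome_family == "continuous":
        if spec.residual_mode == "class_specific":
            resid = [np.atleast_1d(p.resid_var) for p in cp]
            resid = [r if r.size > 1 else float(r[0]) for r in resid]
        else:
            r = np.atleast_1d(cp[0].resid_var)
            resid = r if r.size > 1 else float(r[0])
        thresholds = None
    else:
        resid = 1.0
        thresholds = np.vstack([p.thresholds for p in cp])
    return SimulationScenario(
        n_subjects=ds.n_subjects,
        design=spec.design,
        grid=tuple(ds.grid),
        class_fixed=np.vstack([p.fixed for p in cp]),
        outcome_family=ds.outcome_family,
        n_categories=ds.n_categories,
        thresholds=thresholds,
        class_probs=fit.params.class_probs,
        covariance_mode=spec.covariance_mode
        if not spec.constrain_re_zero else "none",
        re_cov=re_cov,
        resid_var=resid,
    )
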