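"""Numeric diagnostics for comparing and criticizing latent-class fits.

Everything is emitted as tidy tables: per-class distributions of the
subject-level trajectory coefficients (for comparing a mixture's classes
against a single-class mixed effects model), posterior-weighted residual
summaries with a skewness flag, cross-tabulations between two
classifications (ready for riverplot/alluvial tooling), and stacked
category-probability tables for ordinal fits. Plot rendering is left to the
caller; each table is one plotting call away from the corresponding figure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import LongitudinalDataset, ValidationError, build_design
from .mixed import MixedEffectsResults, predict_random_effects
from .mixture import MixtureResults

__all__ = [
    "class_crosstab",
    "random_effects_comparison",
    "residual_diagnostics",
    "stacked_probability_table",
]

SKEWNESS_FLAG = 1.0


def _quartiles(v: np.ndarray) -> dict:
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return {"q25": q25, "median": med, "q75": q75,
            "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))
            if v.size > 1 else 0.0, "n": int(v.size)}


def random_effects_comparison(mem_fit: MixedEffectsResults,
                              mixture_fit: MixtureResults,
                              dataset: LongitudinalDataset) -> pd.DataFrame:
    """Distributions of subject-level trajectory coefficients, by model.

    For each coefficient that carries a random effect in the single-class
    mixed model, the table gives quartile summaries of the subject-level
    coefficient (fixed + empirical-Bayes random part) under the mixed
    effects model, and per-class under the mixture: class fixed +
    class-specific empirical-Bayes prediction for a growth mixture model,
    or the bare class coefficient (zero within-class spread, by
    construction) for LCGA/LLCA.
    """
    terms = mem_fit.model.spec.random_terms
    mix_terms = mixture_fit.spec.design.random_terms
    if mixture_fit.spec.covariance_mode != "none" and \
            tuple(mix_terms) != tuple(terms):
        raise ValidationError(
            "mixed-model and mixture random coefficient sets differ; "
            f"{terms} vs {mix_terms}")
    if mem_fit.model.dataset.n_subjects != dataset.n_subjects:
        raise ValidationError("fits come from different datasets")
    u_mem = mem_fit.predict_random_effects()
    rows = []
    for k, term in enumerate(terms):
        coef = mem_fit.params.fixed[term] + u_mem[:, k]
        rows.append({"model": "mem", "class": 0, "term": term,
                     **_quartiles(coef)})
    has_re = mixture_fit.spec.covariance_mode != "none"
    u_mix = mixture_fit.predict_random_effects() if has_re else None
    for c in range(mixture_fit.n_classes):
        mask = mixture_fit.assignments == c + 1
        if not mask.any():
            continue
        beta_c = mixture_fit.params.class_params[c].fixed
        for k, term in enumerate(terms):
            if has_re:
                coef = beta_c[term] + u_mix[mask, k]
            else:
                coef = np.full(int(mask.sum()), beta_c[term])
            rows.append({"model": "mixture", "class": c + 1, "term": term,
                         **_quartiles(coef)})
    return pd.DataFrame(rows)


def _weighted_skewness(r: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    if sw < 2:
        return np.nan
    m = (w * r).sum() / sw
    d = r - m
    m2 = (w * d * d).sum() / sw
    if m2 <= 1e-24:
        return 0.0
    m3 = (w * d ** 3).sum() / sw
    return float(m3 / m2 ** 1.5)


def residual_diagnostics(fitted: MixtureResults,
                         dataset: LongitudinalDataset | None = None
                         ) -> pd.DataFrame:
    """Posterior-weighted residual summaries per class and grid time.

    Residuals are taken around the class mean trajectory (marginal with
    respect to the random effects). Cells with |skewness| > 1 are flagged as
    potential misspecification of the time trend or the error distribution.
    Continuous outcomes only.
    """
    ds = dataset if dataset is not None else fitted.model.dataset
    if ds.outcome_family != "continuous":
        raise ValidationError("residual diagnostics need a continuous outcome")
    if ds.grid is None:
        raise ValidationError("residual diagnostics need a time grid")
    X, _ = build_design(ds.times, fitted.spec.design, ds.grid, ds.grid_tol)
    post_rec = fitted.posterior[ds._sub_codes]
    rows = []
    for c in range(fitted.n_classes):
        resid = ds.values - X @ fitted.params.class_params[c].fixed
        w = post_rec[:, c]
        for j, t in enumerate(ds.grid):
            sel = ds.grid_idx == j
            r, wj = resid[sel], w[sel]
            sw = wj.sum()
            if sw < 1e-8:
                continue
            mean = (wj * r).sum() / sw
            var = (wj * (r - mean) ** 2).sum() / sw
            skew = _weighted_skewness(r, wj)
            rows.append({
                "class": c + 1, "time": t, "n_eff": sw,
                "mean": mean, "sd": float(np.sqrt(var)),
                "skewness": skew,
                "flagged": bool(np.isfinite(skew)
                                and abs(skew) > SKEWNESS_FLAG),
            })
    return pd.DataFrame(rows)


def class_crosstab(labels_a: np.ndarray, labels_b: np.ndarray,
                   name_a: str = "a", name_b: str = "b") -> pd.DataFrame:
    """Contingency table between two classifications of the same subjects.

    Returns counts (rows = ``labels_a`` classes, columns = ``labels_b``
    classes); row and column percentage tables are attached as
    ``.attrs['row_pct']`` and ``.attrs['col_pct']``. The long form in
    ``.attrs['long']`` feeds riverplot/alluvial tooling directly.
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValidationError("labelings must cover the same subjects")
    tab = pd.crosstab(pd.Series(a, name=name_a), pd.Series(b, name=name_b))
    tab.attrs["row_pct"] = 100.0 * tab.div(tab.sum(axis=1), axis=0)
    tab.attrs["col_pct"] = 100.0 * tab.div(tab.sum(axis=0), axis=1)
    long = tab.stack().rename("n").reset_index()
    tab.attrs["long"] = long[long["n"] > 0]
    return tab


def stacked_probability_table(fitted: MixtureResults,
                              times: np.ndarray | None = None) -> pd.DataFrame:
    """Per-class stacked category probabilities over time (ordinal fits)."""
    ds = fitted.model.dataset
    if ds.outcome_family != "ordinal":
        raise ValidationError("stacked probabilities need an ordinal outcome")
    curves, _ = fitted.predicted_trajectories(times)
    times = (times if times is not None
             else (ds.grid if ds.grid is not None else np.unique(ds.times)))
    rows = []
    for c in range(curves.shape[0]):
        for j, t in enumerate(np.asarray(times, dtype=float)):
            for k in range(curves.shape[2]):
                rows.append({"class": c + 1, "time": t,
                             "category": k + 1,
                             "probability": curves[c, j, k]})
    return pd.DataFrame(rows)
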