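"""Model comparison for latent-class trajectory models.

Information criteria (AIC, BIC and the sample-size-adjusted c-BIC), the
relative-entropy summary of classification sharpness, the parametric
bootstrap likelihood ratio test (BLRT) for the number of classes, and a
comparison table with small-class flags and a BIC-based recommendation.

``N`` in the BIC is the number of subjects, not the number of observations:
subjects are the independent sampling units of a longitudinal study. The
c-BIC replaces ``log N`` by ``log((N + 2) / 24)``, the usual sample-size
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset, ValidationError
from .mixture import (
    DegenerateClassError,
    MixtureResults,
    MixtureSpec,
    TrajectoryMixture,
)

__all__ = [
    "BLRTResult",
    "FitSummary",
    "blrt",
    "compare_models",
    "information_criteria",
    "relative_entropy",
    "summarize_fit",
]

SMALL_CLASS_PCT = 5.0


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    """(AIC, BIC, c-BIC) for a model with ``k`` free parameters on ``n`` units.

    AIC = -2 loglik + 2k; BIC = -2 loglik + k log n;
    c-BIC = -2 loglik + k log((n + 2) / 24).
    """
    if n < 1 or k < 1:
        raise ValidationError("need n >= 1 and k >= 1")
    d = -2.0 * loglik
    return (d + 2.0 * k,
            d + k * np.log(n),
            d + k * np.log((n + 2.0) / 24.0))


def relative_entropy(posterior: np.ndarray) -> float:
    """Relative entropy of a posterior classification, in [0, 1].

    ``1 - sum_i sum_c (-pi_ic log pi_ic) / (N log C)``; 1 means every subject
    is classified with certainty, 0 means the posterior is uninformative.
    Undefined (NaN) for a single class.
    """
    post = np.asarray(posterior, dtype=float)
    N, C = post.shape
    if C < 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(post > 0, post * np.log(post), 0.0)
    return float(1.0 + plogp.sum() / (N * np.log(C)))


@dataclass
class FitSummary:
    """One row of the model-comparison table."""

    n_classes: int
    loglik: float
    n_free_params: int
    n_subjects: int
    aic: float
    bic: float
    cbic: float
    entropy: float
    class_proportions: np.ndarray
    smallest_class_pct: float
    converged: bool
    label: str = ""


def summarize_fit(fit: MixtureResults, label: str = "") -> FitSummary:
    props = fit.class_proportions
    aic, bic, cbic = information_criteria(
        fit.loglik, fit.n_free_params, fit.n_subjects)
    return FitSummary(
        n_classes=fit.n_classes, loglik=fit.loglik,
        n_free_params=fit.n_free_params, n_subjects=fit.n_subjects,
        aic=aic, bic=bic, cbic=cbic,
        entropy=relative_entropy(fit.posterior),
        class_proportions=props,
        smallest_class_pct=100.0 * props.min(),
        converged=fit.converged, label=label)


def compare_models(fits: list[MixtureResults],
                   criterion: str = "bic") -> tuple[pd.DataFrame, dict]:
    """Comparison table plus a recommendation.

    Models with a class below 5% of the sample or without convergence are
    flagged; the recommendation is the lowest-``criterion`` model among the
    unflagged ones (all models, with a note, if every model is flagged).
    Disagreements between AIC, BIC and c-BIC winners are listed.
    """
    if not fits:
        raise ValidationError("no fitted models to compare")
    n0 = fits[0].n_subjects
    if any(f.n_subjects != n0 for f in fits):
        raise ValidationError("models were fitted on different datasets")
    fam0 = fits[0].spec.outcome_family
    if any(f.spec.outcome_family != fam0 for f in fits):
        raise ValidationError("models mix outcome families")
    summaries = sorted((summarize_fit(f) for f in fits),
                       key=lambda s: s.n_classes)
    rows = []
    for s in summaries:
        rows.append({
            "n_classes": s.n_classes, "loglik": s.loglik,
            "k": s.n_free_params, "AIC": s.aic, "BIC": s.bic,
            "cBIC": s.cbic, "entropy": s.entropy,
            "smallest_class_pct": s.smallest_class_pct,
            "converged": s.converged,
            "small_class_flag": s.smallest_class_pct < SMALL_CLASS_PCT
            and s.n_classes > 1,
            "flagged": (s.smallest_class_pct < SMALL_CLASS_PCT
                        and s.n_classes > 1) or not s.converged,
        })
    table = pd.DataFrame(rows)
    crit = {"aic": "AIC", "bic": "BIC", "cbic": "cBIC"}[criterion.lower()]
    unflagged = table[~table["flagged"]]
    pool = unflagged if len(unflagged) else table
    best_row = pool.loc[pool[crit].idxmin()]
    notes = []
    if not len(unflagged):
        notes.append("every candidate was flagged; recommending among all")
    winners = {c: int(table.loc[table[c].idxmin(), "n_classes"])
               for c in ("AIC", "BIC", "cBIC")}
    if len(set(winners.values())) > 1:
        notes.append(f"criteria disagree: {winners}")
    flagged_best = table.loc[table[crit].idxmin()]
    if bool(flagged_best["flagged"]) and len(unflagged):
        notes.append(
            f"lowest-{crit} model ({int(flagged_best['n_classes'])} classes) "
            "is flagged; recommending next-best unflagged model")
    recommendation = {
        "n_classes": int(best_row["n_classes"]),
        "criterion": crit,
        "winners_by_criterion": winners,
        "notes": notes,
    }
    return table, recommendation


@dataclass
class BLRTResult:
    """Parametric bootstrap likelihood ratio test for C vs C+1 classes."""

    lr_statistic: float
    p_value: float
    replicate_lrs: np.ndarray
    n_boot_requested: int
    n_boot_used: int
    n_failed: int
    high_failure_warning: bool
    fit_small: MixtureResults = None
    fit_large: MixtureResults = None


def blrt(dataset: LongitudinalDataset, spec_small: MixtureSpec,
         spec_large: MixtureSpec, n_boot: int = 50, n_starts: int = 5,
         seed: int = 0, tol: float = 1e-7, max_iter: int = 500,
         fit_small: MixtureResults | None = None,
         fit_large: MixtureResults | None = None) -> BLRTResult:
    """Bootstrap LR test of ``spec_small`` (C classes) vs ``spec_large`` (C+1).

    ``n_boot`` datasets are simulated from the fitted small model (complete
    data on the observed grid, same number of subjects); both models are
    refitted on each replicate with a reduced number of starts, and
    ``p = (1 + #{LR* >= LR}) / (n_boot + 1)``. Replicates whose refits fail
    are dropped and counted; more than 20% failures raises a warning flag.
    """
    from .simulate import scenario_from_results, simulate

    if spec_small.n_classes + 1 != spec_large.n_classes:
        raise ValidationError("BLRT compares C against C + 1 classes")
    rng = np.random.default_rng(seed)
    if fit_small is None:
        fit_small = TrajectoryMixture(dataset, spec_small).fit(
            n_starts=n_starts, seed=int(rng.integers(2 ** 31)), tol=tol,
            max_iter=max_iter)
    if fit_large is None:
        fit_large = TrajectoryMixture(dataset, spec_large).fit(
            n_starts=n_starts, seed=int(rng.integers(2 ** 31)), tol=tol,
            max_iter=max_iter)
    lr = 2.0 * (fit_large.loglik - fit_small.loglik)
    scenario = scenario_from_results(fit_small)
    reps = []
    n_failed = 0
    for b in range(n_boot):
        boot_seed = int(rng.integers(2 ** 31))
        try:
            sim, _ = simulate(scenario, seed=boot_seed)
            # replicate refits skip the final polish: the LR null
            # distribution does not need optimum sharpening beyond EM
            fs = TrajectoryMixture(sim, spec_small).fit(
                n_starts=max(2, n_starts // 2), seed=boot_seed, tol=tol,
                max_iter=max_iter, polish=False)
            fl = TrajectoryMixture(sim, spec_large).fit(
                n_starts=n_starts, seed=boot_seed, tol=tol,
                max_iter=max_iter, polish=False)
            reps.append(max(2.0 * (fl.loglik - fs.loglik), 0.0))
        except (DegenerateClassError, ValidationError,
                np.linalg.LinAlgError):
            n_failed += 1
    reps = np.asarray(reps)
    n_used = reps.size
    p = (1.0 + float((reps >= lr - 1e-10).sum())) / (n_used + 1.0)
    return BLRTResult(
        lr_statistic=float(lr), p_value=float(p), replicate_lrs=reps,
        n_boot_requested=n_boot, n_boot_used=n_used, n_failed=n_failed,
        high_failure_warning=n_failed > 0.2 * n_boot,
        fit_small=fit_small, fit_large=fit_large)
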