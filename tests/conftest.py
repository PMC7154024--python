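"""Shared fixtures: small seeded datasets for each model family."""

import numpy as np
import pandas as pd
import pytest

from trajmix.data import DesignSpec, LongitudinalDataset


def make_continuous(n_subjects, times, class_means, class_probs=None,
                    re_sd=0.0, slope_sd=0.0, resid_sd=1.0, seed=0):
    """Simple mixture-of-trajectories generator used by unit tests.

    ``class_means`` is a list of coefficient vectors on (1, t, t^2, ...).
    Returns (dataset, true 0-based labels).
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    C = len(class_means)
    probs = class_probs if class_probs is not None else [1.0 / C] * C
    X = np.vander(times, N=len(np.atleast_1d(class_means[0])),
                  increasing=True)
    rows, labels = [], []
    for i in range(n_subjects):
        c = rng.choice(C, p=probs)
        labels.append(c)
        mu = X @ np.atleast_1d(class_means[c])
        u0 = rng.normal(0, re_sd) if re_sd else 0.0
        u1 = rng.normal(0, slope_sd) if slope_sd else 0.0
        for t, m in zip(times, mu):
            rows.append((i, t, m + u0 + u1 * t + rng.normal(0, resid_sd)))
    ds = LongitudinalDataset(
        pd.DataFrame(rows, columns=["id", "time", "value"]))
    return ds, np.asarray(labels)


@pytest.fixture(scope="session")
def mem_dataset():
    """N=150, J=6, random intercept + slope, linear mean 10 + 0.5 t."""
    ds, _ = make_continuous(150, np.arange(6.0), [[10.0, 0.5]],
                            re_sd=1.2, slope_sd=0.25, resid_sd=1.0, seed=11)
    return ds


@pytest.fixture(scope="session")
def two_class_lcga():
    """Well-separated 2-class flat trajectories at 0 and 5, sigma 1."""
    ds, labels = make_continuous(
        400, np.arange(4.0), [[0.0], [5.0]], class_probs=[0.6, 0.4],
        resid_sd=1.0, seed=42)
    return ds, labels


@pytest.fixture(scope="session")
def ordinal_dataset():
    """Ordinal 3-category data, random intercept, linear latent trend."""
    rng = np.random.default_rng(7)
    times = np.array([0.0, 1.0, 2.0, 3.0])
    rows = []
    tau = np.array([-1.0, 1.5])
    for i in range(200):
        u = rng.normal(0, 1.0)
        for t in times:
            latent = 0.4 * t + u + rng.logistic()
            rows.append((i, t, 1 + int(latent > tau[0]) + int(latent > tau[1])))
    return LongitudinalDataset(
        pd.DataFrame(rows, columns=["id", "time", "value"]),
        outcome_family="ordinal", n_categories=3)
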