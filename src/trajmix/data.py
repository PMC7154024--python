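"""Long-format longitudinal data containers, design matrices and transformations.

The central container is :class:`LongitudinalDataset`: repeated observations
``Z_ij`` of one outcome (continuous, or ordered-categorical coded 1..K+1) on
subjects ``i`` at times ``t_ij``, plus optional time-constant subject-level
covariates and an optional distal outcome measured once per subject.

Missing outcome records are simply absent rows; all likelihoods in this
package are computed over the observed rows only, which is the maximum
likelihood treatment that is valid under missing-at-random dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "LongitudinalDataset",
    "PatternGroup",
    "ValidationError",
    "build_design",
    "log_transform",
    "read_long_table",
    "standardize_covariate",
    "write_long_table",
]


class ValidationError(ValueError):
    """Raised when input data violate the container invariants."""


@dataclass(frozen=True)
class DesignSpec:
    """Shape of the time trend and of the within-subject random variation.

    Parameters
    ----------
    basis
        ``"polynomial"`` builds columns ``1, t, t**2, ..., t**degree`` (with
        ``t`` optionally centred); ``"time_dummies"`` builds an intercept plus
        0/1 indicators for grid positions 2..J (the first grid time is the
        reference), which is the unconstrained-in-time basis used by
        longitudinal latent class analysis.
    degree
        Polynomial degree (ignored for time dummies).
    random_terms
        Indices of the polynomial terms that carry subject-level random
        coefficients (``(0,)`` = random intercept, ``(0, 1)`` = random
        intercept and slope, ...). Must be empty for the time-dummy basis.
    residual_variance_mode
        ``"constant"`` for a single residual variance, ``"time_specific"``
        for one variance per grid time.
    centre
        Constant subtracted from time before building polynomial columns, to
        curb collinearity between powers; reported so coefficients stay
        interpretable on the original scale.
    """

    basis: str = "polynomial"
    degree: int = 1
    random_terms: tuple[int, ...] = ()
    residual_variance_mode: str = "constant"
    centre: float = 0.0

    def __post_init__(self) -> None:
        if self.basis not in ("polynomial", "time_dummies"):
            raise ValidationError(f"unknown basis {self.basis!r}")
        if self.residual_variance_mode not in ("constant", "time_specific"):
            raise ValidationError(
                f"unknown residual_variance_mode {self.residual_variance_mode!r}"
            )
        if self.degree < 0:
            raise ValidationError("polynomial degree must be >= 0")
        terms = tuple(int(r) for r in self.random_terms)
        object.__setattr__(self, "random_terms", terms)
        if self.basis == "time_dummies" and terms:
            raise ValidationError("time-dummy basis cannot carry random terms")
        if self.basis == "polynomial":
            bad = [r for r in terms if r < 0 or r > self.degree]
            if bad:
                raise ValidationError(
                    f"random_terms {bad} outside fixed-effect terms 0..{self.degree}"
                )
            if list(terms) != sorted(set(terms)):
                raise ValidationError("random_terms must be strictly increasing")

    @property
    def n_random(self) -> int:
        return len(self.random_terms)

    def n_fixed(self, grid: Sequence[float] | None) -> int:
        """Number of fixed-effect columns (needs the grid for time dummies)."""
        if self.basis == "polynomial":
            return self.degree + 1
        if grid is None:
            raise ValidationError("time-dummy basis requires a common time grid")
        return len(grid)


def build_design(
    times: np.ndarray,
    spec: DesignSpec,
    grid: Sequence[float] | None = None,
    grid_tol: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Build fixed-effect and random-effect design matrices for given times.

    Returns ``(X, Z)`` where ``X`` is ``n x p`` and ``Z`` is the ``n x q``
    subset of the polynomial columns named in ``spec.random_terms``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValidationError("times must be nonempty")
    if spec.basis == "polynomial":
        tc = t - spec.centre
        X = np.vander(tc, N=spec.degree + 1, increasing=True)
    else:
        if grid is None:
            raise ValidationError("time-dummy basis requires a common time grid")
        grid = np.asarray(grid, dtype=float)
        idx = snap_to_grid(t, grid, grid_tol)
        X = np.zeros((t.size, grid.size))
        X[:, 0] = 1.0
        for j in range(1, grid.size):
            X[idx == j, j] = 1.0
    Z = X[:, list(spec.random_terms)] if spec.random_terms else np.empty((t.size, 0))
    return X, Z


def snap_to_grid(times: np.ndarray, grid: np.ndarray, tol: float = 0.25) -> np.ndarray:
    """Map each time to the index of the nearest grid point within ``tol``."""
    t = np.asarray(times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    idx = np.argmin(np.abs(t[:, None] - grid[None, :]), axis=1)
    off = np.abs(t - grid[idx])
    if np.any(off > tol):
        bad = t[off > tol]
        raise ValidationError(
            f"times {bad.tolist()} are more than {tol} from every grid point"
        )
    return idx


@dataclass
class PatternGroup:
    """Subjects sharing one observed-time pattern (for vectorised likelihoods)."""

    times: np.ndarray        # length J_g
    grid_idx: np.ndarray | None
    subject_rows: np.ndarray  # indices into the dataset's subject order
    values: np.ndarray       # n_g x J_g outcome matrix


class LongitudinalDataset:
    """Validated long-format repeated measures for one outcome.

    Parameters
    ----------
    table
        Long-format frame with columns ``id``, ``time``, ``value``.
    outcome_family
        ``"continuous"`` or ``"ordinal"``. Ordinal values must be integers in
        ``1..n_categories``.
    n_categories
        Number of ordered categories K+1 (ordinal only).
    covariates
        Optional frame of time-constant subject covariates indexed by id.
    distal
        Optional per-subject distal outcome (Series indexed by id); NaN for
        subjects without a distal measurement.
    grid
        Common observation grid. If omitted it is inferred from the distinct
        times when there are at most ``24`` of them; a grid is required for
        time-dummy bases and time-specific residual variances.
    grid_tol
        Snapping tolerance (time units) when matching times to the grid.
    """

    MAX_INFERRED_GRID = 24

    def __init__(
        self,
        table: pd.DataFrame,
        outcome_family: str = "continuous",
        n_categories: int | None = None,
        covariates: pd.DataFrame | None = None,
        distal: pd.Series | None = None,
        grid: Sequence[float] | None = None,
        grid_tol: float = 0.25,
        log_transformed: bool = False,
    ) -> None:
        required = {"id", "time", "value"}
        if not required.issubset(table.columns):
            raise ValidationError(f"table must have columns {sorted(required)}")
        if outcome_family not in ("continuous", "ordinal"):
            raise ValidationError(f"unknown outcome family {outcome_family!r}")
        tab = table.loc[:, ["id", "time", "value"]].copy()
        if not np.issubdtype(np.asarray(tab["time"]).dtype, np.number):
            raise ValidationError("time column must be numeric")
        tab = tab.dropna(subset=["value"])
        if tab.empty:
            raise ValidationError("no observed outcome records")
        dup = tab.duplicated(subset=["id", "time"])
        if dup.any():
            first = tab.loc[dup.idxmax()]
            raise ValidationError(
                f"duplicate record for subject {first['id']!r} at time {first['time']}"
            )
        if outcome_family == "ordinal":
            if n_categories is None or n_categories < 2:
                raise ValidationError("ordinal outcomes need n_categories >= 2")
            v = np.asarray(tab["value"], dtype=float)
            if not np.allclose(v, np.round(v)):
                raise ValidationError("ordinal values must be integers")
            v = v.astype(int)
            if v.min() < 1 or v.max() > n_categories:
                raise ValidationError(
                    f"ordinal values must lie in 1..{n_categories}; "
                    f"found range {v.min()}..{v.max()}"
                )
            tab["value"] = v
        tab = tab.sort_values(["id", "time"], kind="mergesort").reset_index(drop=True)

        self.table = tab
        self.outcome_family = outcome_family
        self.n_categories = n_categories if outcome_family == "ordinal" else None
        self.grid_tol = float(grid_tol)
        self.log_transformed = log_transformed

        self.subjects = np.asarray(tab["id"].unique())
        self.n_subjects = len(self.subjects)
        self._sub_codes = tab["id"].map(
            {s: k for k, s in enumerate(self.subjects)}
        ).to_numpy()
        self.times = tab["time"].to_numpy(dtype=float)
        self.values = tab["value"].to_numpy(dtype=float)

        if grid is not None:
            self.grid = np.asarray(sorted(grid), dtype=float)
        else:
            uniq = np.unique(self.times)
            self.grid = uniq if uniq.size <= self.MAX_INFERRED_GRID else None
        if self.grid is not None:
            self.grid_idx = snap_to_grid(self.times, self.grid, self.grid_tol)
        else:
            self.grid_idx = None

        self.covariates = self._check_subject_frame(covariates, "covariates")
        if distal is not None:
            distal = pd.Series(distal)
            distal = distal.reindex(self.subjects)
        self.distal = distal
        self._groups: list[PatternGroup] | None = None

    def _check_subject_frame(
        self, frame: pd.DataFrame | None, what: str
    ) -> pd.DataFrame | None:
        if frame is None:
            return None
        frame = pd.DataFrame(frame)
        missing = [s for s in self.subjects if s not in frame.index]
        if missing:
            raise ValidationError(f"{what} missing for subjects {missing[:5]}")
        return frame.loc[self.subjects]

    # -- vectorisation helpers -------------------------------------------------

    def pattern_groups(self) -> list[PatternGroup]:
        """Group subjects by identical observed-time pattern."""
        if self._groups is not None:
            return self._groups
        keys: dict[tuple, list[int]] = {}
        sub_slices: list[slice] = []
        starts = np.flatnonzero(
            np.r_[True, self._sub_codes[1:] != self._sub_codes[:-1]]
        )
        ends = np.r_[starts[1:], self._sub_codes.size]
        for k, (a, b) in enumerate(zip(starts, ends)):
            sub_slices.append(slice(a, b))
            if self.grid_idx is not None:
                key = tuple(self.grid_idx[a:b])
            else:
                key = tuple(np.round(self.times[a:b], 10))
            keys.setdefault(key, []).append(k)
        groups = []
        for key, members in keys.items():
            first = sub_slices[members[0]]
            times = self.times[first]
            gidx = self.grid_idx[first] if self.grid_idx is not None else None
            vals = np.vstack([self.values[sub_slices[m]] for m in members])
            groups.append(
                PatternGroup(times=times, grid_idx=gidx,
                             subject_rows=np.asarray(members), values=vals)
            )
        self._groups = groups
        return groups

    def subject_slices(self) -> list[slice]:
        starts = np.flatnonzero(
            np.r_[True, self._sub_codes[1:] != self._sub_codes[:-1]]
        )
        ends = np.r_[starts[1:], self._sub_codes.size]
        return [slice(a, b) for a, b in zip(starts, ends)]

    @property
    def n_records(self) -> int:
        return len(self.table)

    def replace_values(self, values: np.ndarray, **kw) -> "LongitudinalDataset":
        tab = self.table.copy()
        tab["value"] = values
        args = dict(
            outcome_family=self.outcome_family,
            n_categories=self.n_categories,
            covariates=self.covariates,
            distal=self.distal,
            grid=self.grid,
            grid_tol=self.grid_tol,
            log_transformed=self.log_transformed,
        )
        args.update(kw)
        return LongitudinalDataset(tab, **args)

    def summary(self) -> pd.DataFrame:
        """Counts and missingness per grid wave (requires a grid)."""
        if self.grid is None:
            raise ValidationError("summary per wave requires a time grid")
        counts = np.bincount(self.grid_idx, minlength=self.grid.size)
        return pd.DataFrame(
            {
                "time": self.grid,
                "n_observed": counts,
                "pct_missing": 100.0 * (1 - counts / self.n_subjects),
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        fam = self.outcome_family
        return (
            f"<LongitudinalDataset N={self.n_subjects} records={self.n_records} "
            f"family={fam}>"
        )


def read_long_table(
    path,
    column_map: Mapping[str, str] | None = None,
    outcome_family: str = "continuous",
    n_categories: int | None = None,
    covariate_columns: Sequence[str] = (),
    distal_column: str | None = None,
    grid: Sequence[float] | None = None,
    grid_tol: float = 0.25,
) -> LongitudinalDataset:
    """Read a long-format CSV into a validated :class:`LongitudinalDataset`.

    ``column_map`` maps the roles ``id``, ``time``, ``value`` to the file's
    column names. Rows with a missing outcome are dropped and counted in the
    dataset's ``load_report``; subjects with no observed outcome at all are
    excluded (they may still appear in covariate columns of retained rows).
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    cmap = {"id": "id", "time": "time", "value": "value"}
    if column_map:
        cmap.update(column_map)
    for role, col in cmap.items():
        if col not in raw.columns:
            raise ValidationError(f"column {col!r} (role {role!r}) not in file")
    tab = raw.rename(columns={v: k for k, v in cmap.items()})
    if not np.issubdtype(np.asarray(tab["time"]).dtype, np.number):
        raise ValidationError("time column must be numeric")
    n_missing = int(tab["value"].isna().sum())
    obs = tab.dropna(subset=["value"])
    kept_ids = obs["id"].unique()
    n_dropped_subjects = tab["id"].nunique() - len(kept_ids)

    covariates = None
    if covariate_columns:
        cov = obs.loc[:, ["id", *covariate_columns]].drop_duplicates("id")
        extra = obs.groupby("id")[list(covariate_columns)].nunique(dropna=False)
        if (extra > 1).any().any():
            raise ValidationError("covariates must be constant within subject")
        covariates = cov.set_index("id")
    distal = None
    if distal_column is not None:
        distal = obs.loc[:, ["id", distal_column]].drop_duplicates("id") \
            .set_index("id")[distal_column]

    ds = LongitudinalDataset(
        obs.loc[:, ["id", "time", "value"]],
        outcome_family=outcome_family,
        n_categories=n_categories,
        covariates=covariates,
        distal=distal,
        grid=grid,
        grid_tol=grid_tol,
    )
    ds.load_report = {
        "n_rows_read": len(raw),
        "n_missing_outcome_dropped": n_missing,
        "n_subjects_excluded": int(n_dropped_subjects),
    }
    return ds


def write_long_table(dataset: LongitudinalDataset, path) -> None:
    """Write the dataset back to CSV (inverse of :func:`read_long_table`)."""
    tab = dataset.table.copy()
    if dataset.covariates is not None:
        for col in dataset.covariates.columns:
            tab[col] = tab["id"].map(dataset.covariates[col])
    if dataset.distal is not None:
        tab["distal"] = tab["id"].map(dataset.distal)
    tab.to_csv(path, index=False)


def standardize_covariate(
    values: np.ndarray, mean: float | None = None, sd: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Internally standardize a covariate to mean 0, SD 1 (denominator n-1).

    Pass ``mean``/``sd`` to standardize against externally supplied moments
    (e.g. published reference values). Returns ``(z, mean, sd)`` so estimates
    can be back-transformed to the original scale.
    """
    x = np.asarray(values, dtype=float)
    if mean is None:
        if x.size < 2:
            raise ValidationError("need at least 2 values to standardize")
        mean = float(np.mean(x))
    if sd is None:
        sd = float(np.std(x, ddof=1))
    if sd <= 0:
        raise ValidationError("covariate has zero variance; cannot standardize")
    return (x - mean) / sd, float(mean), float(sd)


def log_transform(dataset: LongitudinalDataset) -> LongitudinalDataset:
    """Natural-log transform a positive continuous outcome.

    The returned dataset is flagged ``log_transformed`` so that predicted
    trajectories can be back-transformed (``exp`` of the predicted mean, a
    median-scale prediction under log-normal errors).
    """
    if dataset.outcome_family != "continuous":
        raise ValidationError("log transform applies to continuous outcomes only")
    bad = dataset.values <= 0
    if bad.any():
        row = dataset.table.iloc[int(np.flatnonzero(bad)[0])]
        raise ValidationError(
            f"nonpositive value {row['value']} for subject {row['id']!r} "
            f"at time {row['time']}"
        )
    return dataset.replace_values(np.log(dataset.values), log_transformed=True)
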