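"""Daily aggregation and imputation of irregular preoperative lab series.

Raw long-format measurements are collapsed onto a dense patient x test x day
grid (same-day repeats averaged), together with an immutable observed-mask
recording pre-imputation occupancy.  Count- and abnormality-type features are
always derived from the mask / raw values; imputation only fills values for
the mean- and slope-type features and never touches observed cells.

Three imputation schemes are provided:

* ``impute_locf`` — last observation carried forward within each
  patient-test series (oldest day toward surgery); leading gaps take the
  per-test cohort mean of observed values.
* ``impute_knn`` — each missing cell is the mean of that cell's value among
  the k nearest patients, where nearness is the mean absolute difference of
  per-test standardized values over the patient pair's jointly observed days.
* ``impute_hybrid`` — the farthest column (day = obs_days) is filled by
  carrying each series' earliest available observation backward (patient
  history), KNN everywhere else.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import TestCatalogEntry
from .synth import LabMeasurement

logger = logging.getLogger(__name__)

__all__ = [
    "DailyGrid",
    "aggregate_daily",
    "impute_locf",
    "impute_knn",
    "impute_hybrid",
    "write_grid_csv",
    "read_grid_csv",
]


@dataclass
class DailyGrid:
    """Patient x test x day value grid with a pre-imputation observed mask.

    The day axis runs from the oldest day (``obs_days`` before surgery) to
    day 0 (surgery day): column ``j`` holds day ``obs_days - j``.  ``values``
    is NaN where nothing was observed (until imputation); ``mask`` is True
    exactly where at least one raw value existed and is read-only.
    """

    patient_ids: list[str]
    test_names: list[str]
    obs_days: int
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n_p, n_t, n_d = len(self.patient_ids), len(self.test_names), self.obs_days + 1
        if self.values.shape != (n_p, n_t, n_d) or self.mask.shape != (n_p, n_t, n_d):
            raise ValueError("grid shape mismatch")
        self.mask.setflags(write=False)

    def day_index(self, day: int) -> int:
        if not 0 <= day <= self.obs_days:
            raise ValueError(f"day {day} outside [0, {self.obs_days}]")
        return self.obs_days - day

    @property
    def days(self) -> np.ndarray:
        """Day-before-surgery value of each column (obs_days .. 0)."""
        return np.arange(self.obs_days, -1, -1)

    def test_index(self, test_name: str) -> int:
        try:
            return self.test_names.index(test_name)
        except ValueError:
            raise KeyError(f"unknown test {test_name!r}") from None

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def copy_with(self, values: np.ndarray) -> "DailyGrid":
        return DailyGrid(self.patient_ids, self.test_names, self.obs_days, values, self.mask)


def aggregate_daily(
    measurements: Sequence[LabMeasurement],
    obs_days: int,
    patient_ids: Sequence[str] | None = None,
    test_names: Sequence[str] | None = None,
) -> DailyGrid:
    """Average same-day repeats onto the daily grid.

    Measurements farther back than ``obs_days`` are excluded.  Axis orders
    default to sorted unique values but can be pinned (e.g. to the patient
    roster and catalog order) so empty rows are preserved.
    """
    rows = [
        (m.patient_id, m.test_name, m.day, m.value)
        for m in measurements
        if 0 <= m.day <= obs_days
    ]
    df = pd.DataFrame(rows, columns=["patient_id", "test_name", "day", "value"])
    if patient_ids is None:
        patient_ids = sorted(df["patient_id"].unique()) if len(df) else []
    if test_names is None:
        test_names = sorted(df["test_name"].unique()) if len(df) else []
    patient_ids, test_names = list(patient_ids), list(test_names)

    n_p, n_t, n_d = len(patient_ids), len(test_names), obs_days + 1
    values = np.full((n_p, n_t, n_d), np.nan)
    mask = np.zeros((n_p, n_t, n_d), dtype=bool)
    if len(df):
        # sort everything so the result is independent of input row order
        df = df.sort_values(["patient_id", "test_name", "day", "value"], kind="mergesort")
        daily = df.groupby(["patient_id", "test_name", "day"], sort=True)["value"].mean()
        p_idx = {p: i for i, p in enumerate(patient_ids)}
        t_idx = {t: i for i, t in enumerate(test_names)}
        for (pid, test, day), val in daily.items():
            if pid not in p_idx:
                raise KeyError(f"patient {pid!r} not in the supplied roster")
            if test not in t_idx:
                raise KeyError(f"test {test!r} not in the supplied test list")
            j = obs_days - int(day)
            values[p_idx[pid], t_idx[test], j] = val
            mask[p_idx[pid], t_idx[test], j] = True
    return DailyGrid(patient_ids, test_names, obs_days, values, mask)


def _cohort_test_means(
    grid: DailyGrid, catalog: Sequence[TestCatalogEntry] | None
) -> np.ndarray:
    """Per-test mean of all observed values; reference midpoint fallback."""
    means = np.empty(len(grid.test_names))
    mids = {e.test_name: e.mid for e in catalog} if catalog is not None else {}
    for t, name in enumerate(grid.test_names):
        obs = grid.values[:, t, :][grid.mask[:, t, :]]
        if obs.size:
            means[t] = obs.mean()
        elif name in mids:
            logger.warning(
                "test %r has no observations cohort-wide; using reference midpoint", name
            )
            means[t] = mids[name]
        else:
            raise ValueError(
                f"test {name!r} has no observations and no catalog entry to fall back on"
            )
    return means


def impute_locf(
    grid: DailyGrid, catalog: Sequence[TestCatalogEntry] | None = None
) -> DailyGrid:
    """Last observation carried forward (oldest day toward surgery).

    Cells before the first observation of a series take the per-test cohort
    mean of observed values (reference midpoint if a test is never observed
    and a catalog is supplied).  Idempotent; the mask is untouched.
    """
    values = grid.values.copy()
    n_d = grid.obs_days + 1
    obs = grid.mask
    # index of most recent observed column at or before j, -1 if none
    idx = np.where(obs, np.arange(n_d), -1)
    idx = np.maximum.accumulate(idx, axis=2)
    filled = np.take_along_axis(np.where(obs, values, 0.0), np.maximum(idx, 0), axis=2)
    test_means = _cohort_test_means(grid, catalog)
    lead = test_means[None, :, None]
    values = np.where(idx >= 0, filled, lead)
    # observed cells keep their exact original values
    values[obs] = grid.values[obs]
    return grid.copy_with(values)


def _pairwise_distances(z: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Mean |z_i - z_j| over jointly observed days; inf when no joint days."""
    from ._solver import pairwise_mean_absdiff

    return pairwise_mean_absdiff(
        np.ascontiguousarray(np.where(observed, z, 0.0)),
        np.ascontiguousarray(observed),
    )


def impute_knn(
    grid: DailyGrid,
    k: int = 5,
    catalog: Sequence[TestCatalogEntry] | None = None,
) -> DailyGrid:
    """k-nearest-neighbour imputation within each test.

    Neighbours are ranked by mean absolute difference of standardized values
    over the pair's jointly observed days of the same test; patients sharing
    no observed day rank last.  A missing cell takes the mean of the cell's
    raw value among the k nearest patients that observed it; with no such
    patient it takes the per-test cohort mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = grid.values.copy()
    test_means = _cohort_test_means(grid, catalog)
    for t in range(len(grid.test_names)):
        v = grid.values[:, t, :]
        obs = grid.mask[:, t, :]
        missing_any = ~obs
        if not missing_any.any():
            continue
        vals_obs = v[obs]
        if vals_obs.size == 0:
            values[:, t, :] = test_means[t]
            continue
        mu, sd = vals_obs.mean(), vals_obs.std()
        if sd == 0:
            sd = 1.0
        z = (v - mu) / sd
        dist = _pairwise_distances(z, obs)
        for j in range(grid.obs_days + 1):
            miss_rows = np.flatnonzero(~obs[:, j])
            if miss_rows.size == 0:
                continue
            donors = np.flatnonzero(obs[:, j])
            if donors.size == 0:
                values[miss_rows, t, j] = test_means[t]
                continue
            donor_vals = v[donors, j]
            if donors.size <= k:
                values[miss_rows, t, j] = donor_vals.mean()
                continue
            sub = dist[np.ix_(miss_rows, donors)]
            nearest = np.argpartition(sub, k - 1, axis=1)[:, :k]
            values[miss_rows, t, j] = donor_vals[nearest].mean(axis=1)
    return grid.copy_with(values)


def write_grid_csv(grid: DailyGrid, values_path, mask_path) -> None:
    """Persist the grid as wide CSV: one row per patient-test, day_obs..day_0."""
    n_p, n_t = len(grid.patient_ids), len(grid.test_names)
    cols = [f"day_{d}" for d in grid.days]
    base = {
        "patient_id": np.repeat(grid.patient_ids, n_t),
        "test_name": np.tile(grid.test_names, n_p),
    }
    vdf = pd.DataFrame({**base}, copy=False)
    vdf[cols] = grid.values.reshape(n_p * n_t, -1)
    vdf.to_csv(values_path, index=False)
    mdf = pd.DataFrame({**base}, copy=False)
    mdf[cols] = grid.mask.reshape(n_p * n_t, -1).astype(int)
    mdf.to_csv(mask_path, index=False)


def read_grid_csv(values_path, mask_path) -> DailyGrid:
    vdf = pd.read_csv(values_path)
    mdf = pd.read_csv(mask_path)
    day_cols = [c for c in vdf.columns if c.startswith("day_")]
    obs_days = max(int(c.split("_")[1]) for c in day_cols)
    ordered = [f"day_{d}" for d in range(obs_days, -1, -1)]
    patient_ids = list(dict.fromkeys(vdf["patient_id"]))
    test_names = list(dict.fromkeys(vdf["test_name"]))
    n_p, n_t = len(patient_ids), len(test_names)
    values = vdf[ordered].to_numpy(dtype=float).reshape(n_p, n_t, obs_days + 1)
    mask = mdf[ordered].to_numpy().astype(bool).reshape(n_p, n_t, obs_days + 1)
    return DailyGrid(patient_ids, test_names, obs_days, values, mask)


def impute_hybrid(
    grid: DailyGrid,
    k: int = 5,
    catalog: Sequence[TestCatalogEntry] | None = None,
) -> DailyGrid:
    """Carry-back at the farthest day, KNN everywhere else.

    The day = obs_days column stands in for patient history: a missing cell
    there takes the series' earliest (oldest) available observation, falling
    back to the per-test cohort mean for empty series.  All other missing
    cells are filled by :func:`impute_knn`.
    """
    knn = impute_knn(grid, k=k, catalog=catalog)
    values = knn.values.copy()
    obs = grid.mask
    n_d = grid.obs_days + 1
    # earliest observed column index per series, n_d if never observed
    first = np.where(obs.any(axis=2), obs.argmax(axis=2), n_d)
    far_missing = ~obs[:, :, 0]
    test_means = _cohort_test_means(grid, catalog)
    p_i, t_i = np.nonzero(far_missing)
    for i, t in zip(p_i, t_i):
        if first[i, t] < n_d:
            values[i, t, 0] = grid.values[i, t, first[i, t]]
        else:
            values[i, t, 0] = test_means[t]
    return grid.copy_with(values)
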