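"""Temporal windowing and feature extraction.

Each test's observation interval is split into three contiguous windows —
S (short, closest to surgery), M (medium) and L (long) — and six feature
kinds are computed per test and window:

===================  ============================================  =========
kind                 definition                                    source
===================  ============================================  =========
mean                 mean of the (imputed) daily values            imputed
slope                OLS slope of value vs time toward surgery     imputed
nmbr_test            observed-day count in the window              mask
prop_nmbr_test       nmbr_test / observed days in whole interval   mask
high_abn_prop        high-abnormal count / observed in window      raw+mask
low_abn_prop         low-abnormal count / observed in window       raw+mask
===================  ============================================  =========

Three feature sets are assembled (columns named ``{Test}_{kind}_{window}``,
plus ``age`` and ``sex``):

* ``CRP`` — baseline: CRP window means only (5 columns total);
* ``BLM`` — value-only kinds {mean, slope, abn_prop} (126 + 2 columns);
* ``FLM`` — all six kinds above (252 + 2 columns for 14 tests, 3 windows).

A 15-day observation interval uses a single window labelled ``W``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import TestCatalogEntry
from .preprocess import DailyGrid
from .synth import DEFAULT_M_HI, DEFAULT_S_HI, PatientRecord

__all__ = [
    "WindowSpec",
    "window_mean",
    "window_slope",
    "window_counts",
    "abnormal_features",
    "build_feature_matrix",
    "feature_test",
    "FLM_KINDS",
    "BLM_KINDS",
    "FEATURE_SETS",
]

FLM_KINDS = ("mean", "slope", "nmbr_test", "prop_nmbr_test", "high_abn_prop", "low_abn_prop")
BLM_KINDS = ("mean", "slope", "abn_prop")
FEATURE_SETS = ("CRP", "BLM", "FLM")


@dataclass(frozen=True)
class WindowSpec:
    """Per-test S/M/L day ranges partitioning ``[obs_days, 0]``.

    ``s_hi`` and ``m_hi`` are the oldest days of the S and M windows:
    S = [s_hi, 0], M = [m_hi, s_hi + 1], L = [obs_days, m_hi + 1].  Per-test
    overrides replace the default boundaries.  With ``single_window`` the
    whole interval forms one window labelled ``W`` (the 15-day convention).
    """

    obs_days: int = 60
    s_hi: int = DEFAULT_S_HI
    m_hi: int = DEFAULT_M_HI
    per_test: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    single_window: bool = False

    def __post_init__(self) -> None:
        if not self.single_window:
            for s_hi, m_hi in [(self.s_hi, self.m_hi), *self.per_test.values()]:
                if not 0 <= s_hi <= 2:
                    raise ValueError(f"s_hi {s_hi} outside [0, 2]")
                if not 13 <= m_hi <= 18:
                    raise ValueError(f"m_hi {m_hi} outside [13, 18]")
                if m_hi >= self.obs_days:
                    raise ValueError("m_hi must be below obs_days")

    @classmethod
    def for_interval(cls, obs_days: int, **kwargs) -> "WindowSpec":
        """Default windows for an observation interval (single window at 15 d)."""
        return cls(obs_days=obs_days, single_window=(obs_days <= 15), **kwargs)

    def windows(self, test_name: str) -> list[tuple[str, int, int]]:
        """``(label, oldest_day, newest_day)`` triples covering the interval."""
        if self.single_window:
            return [("W", self.obs_days, 0)]
        s_hi, m_hi = self.per_test.get(test_name, (self.s_hi, self.m_hi))
        return [
            ("S", s_hi, 0),
            ("M", m_hi, s_hi + 1),
            ("L", self.obs_days, m_hi + 1),
        ]

    @property
    def labels(self) -> list[str]:
        return ["W"] if self.single_window else ["S", "M", "L"]


def _window_slice(grid: DailyGrid, window: tuple[int, int]) -> slice:
    hi, lo = window
    if not (grid.obs_days >= hi >= lo >= 0):
        raise ValueError(f"window {window} outside [0, {grid.obs_days}]")
    return slice(grid.day_index(hi), grid.day_index(lo) + 1)


def window_mean(grid: DailyGrid, test_name: str, window: tuple[int, int]) -> np.ndarray:
    """Per-patient mean of the imputed daily values over ``window=(hi, lo)``."""
    t = grid.test_index(test_name)
    return grid.values[:, t, _window_slice(grid, window)].mean(axis=1)


def window_slope(grid: DailyGrid, test_name: str, window: tuple[int, int]) -> np.ndarray:
    """Per-patient OLS slope of value against time running toward surgery.

    The time axis is minus the day-before-surgery, so a value rising as
    surgery approaches has a positive slope.  Single-day windows get 0.
    """
    t = grid.test_index(test_name)
    sl = _window_slice(grid, window)
    y = grid.values[:, t, sl]
    hi, lo = window
    x = -np.arange(hi, lo - 1, -1, dtype=float)
    if x.size < 2:
        return np.zeros(y.shape[0])
    xc = x - x.mean()
    return (y - y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)


def window_counts(
    grid: DailyGrid, test_name: str, window: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Observed-day count in the window and its share of the interval total.

    Both use the pre-imputation mask.  The proportion is 0 for patients with
    no observation of the test anywhere in the interval.
    """
    t = grid.test_index(test_name)
    nmbr = grid.mask[:, t, _window_slice(grid, window)].sum(axis=1).astype(float)
    total = grid.mask[:, t, :].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total > 0, nmbr / np.where(total > 0, total, 1.0), 0.0)
    return nmbr, prop


def abnormal_features(
    grid: DailyGrid,
    catalog_entry: TestCatalogEntry,
    window: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Abnormal-value counts/proportions from observed (pre-imputation) values.

    A daily value above ``ref_high`` counts high, below ``ref_low`` counts
    low.  Returns ``(nmbr_abn, high_abn_prop, low_abn_prop, abn_prop)`` with
    proportions over the window's observed count (all zero for empty windows).
    """
    t = grid.test_index(catalog_entry.test_name)
    sl = _window_slice(grid, window)
    vals = grid.values[:, t, sl]
    obs = grid.mask[:, t, sl]
    high = (obs & (vals > catalog_entry.ref_high)).sum(axis=1).astype(float)
    low = (obs & (vals < catalog_entry.ref_low)).sum(axis=1).astype(float)
    cnt = obs.sum(axis=1).astype(float)
    denom = np.where(cnt > 0, cnt, 1.0)
    high_prop = np.where(cnt > 0, high / denom, 0.0)
    low_prop = np.where(cnt > 0, low / denom, 0.0)
    return high + low, high_prop, low_prop, high_prop + low_prop


def build_feature_matrix(
    imputed: DailyGrid,
    raw: DailyGrid,
    windows: WindowSpec,
    catalog: Sequence[TestCatalogEntry],
    patients: Sequence[PatientRecord] | pd.DataFrame,
    feature_set: str = "FLM",
) -> pd.DataFrame:
    """Assemble the named feature matrix for one of the three feature sets.

    ``imputed`` supplies mean/slope features, ``raw`` (same axes, with its
    pre-imputation mask) the count and abnormality features.  The result is
    indexed by patient id, carries ``age`` and ``sex`` as final columns, and
    records the feature set in ``DataFrame.attrs['feature_set']``.
    """
    feature_set = feature_set.upper()
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}; expected one of {FEATURE_SETS}")
    if not imputed.is_complete():
        raise ValueError("imputed grid still contains missing values")
    if imputed.patient_ids != raw.patient_ids or imputed.test_names != raw.test_names:
        raise ValueError("imputed and raw grids must share axes")

    if isinstance(patients, pd.DataFrame):
        pdf = patients.set_index("patient_id") if "patient_id" in patients.columns else patients
    else:
        pdf = pd.DataFrame(
            {"age": [p.age for p in patients], "sex": [p.sex for p in patients]},
            index=[p.patient_id for p in patients],
        )
    pdf = pdf.loc[imputed.patient_ids]

    entries = {e.test_name: e for e in catalog}
    cols: dict[str, np.ndarray] = {}
    tests = [e.test_name for e in catalog if e.test_name in imputed.test_names]
    if feature_set == "CRP":
        for label, hi, lo in windows.windows("CRP"):
            cols[f"CRP_mean_{label}"] = window_mean(imputed, "CRP", (hi, lo))
    else:
        kinds = FLM_KINDS if feature_set == "FLM" else BLM_KINDS
        for test in tests:
            entry = entries[test]
            for label, hi, lo in windows.windows(test):
                w = (hi, lo)
                _, high_prop, low_prop, abn_prop = abnormal_features(raw, entry, w)
                nmbr, prop = window_counts(raw, test, w)
                per_kind = {
                    "mean": window_mean(imputed, test, w),
                    "slope": window_slope(imputed, test, w),
                    "nmbr_test": nmbr,
                    "prop_nmbr_test": prop,
                    "high_abn_prop": high_prop,
                    "low_abn_prop": low_prop,
                    "abn_prop": abn_prop,
                }
                for kind in kinds:
                    cols[f"{test}_{kind}_{label}"] = per_kind[kind]

    out = pd.DataFrame(cols, index=imputed.patient_ids)
    out["age"] = pdf["age"].to_numpy(dtype=float)
    out["sex"] = pdf["sex"].to_numpy(dtype=float)
    out.attrs["feature_set"] = feature_set
    return out


def feature_test(column: str, catalog: Sequence[TestCatalogEntry]) -> str | None:
    """Catalog test a feature column derives from; None for demographics."""
    if column in ("age", "sex"):
        return None
    for entry in catalog:
        if column.startswith(entry.test_name + "_"):
            return entry.test_name
    raise KeyError(f"feature {column!r} does not match any catalog test")
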