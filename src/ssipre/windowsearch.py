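"""Automatic temporal-window partition search.

Instead of hand-picking S/M/L boundaries from group-mean plots, this module
scores candidate partitionings of the observation interval by how well each
window separates the daily mean-value curves of SSI cases and controls:

* per day, a contrast ratio ``|mean_case - mean_ctrl| / (pooled CI
  half-width + eps)`` — a signal-to-uncertainty measure;
* per window, the distance = mean contrast ratio over the window's days;
* per partitioning, the score = product of its window distances (an additive
  sum is available as an alternative);
* the best partitioning maximizes the score, first within each window count
  ``k``, then across ``k <= k_max``.

Candidate partitionings follow a cut-day-selection convention: a candidate is
an unordered choice of ``k`` cut days from the ``n`` non-surgery days, so for
a 60-day interval and k = 3 there are C(60, 3) = 34,220 candidates.  Each cut
day is the oldest day of its window; days older than the oldest cut are
absorbed into the first window (the interval is closed at day 0 by
construction).  Distinct cut selections may therefore map to the same window
geometry — the enumeration counts selections.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .preprocess import aggregate_daily
from .synth import LabMeasurement, PatientRecord

__all__ = [
    "GroupCurves",
    "Partitioning",
    "group_curves",
    "window_distance",
    "enumerate_partitionings",
    "n_partitionings",
    "partition_score",
    "best_partitioning",
]

EPS = 1e-9
Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class GroupCurves:
    """Daily mean-value curves (with 95% CI half-widths) per outcome group.

    Arrays are indexed by day-before-surgery (position d = day d); rows 0/1
    are controls/cases.  NaN marks days without any observation in a group.
    """

    test_name: str
    obs_days: int
    mean: np.ndarray       # (2, obs_days + 1)
    halfwidth: np.ndarray  # (2, obs_days + 1)
    n_obs: np.ndarray      # (2, obs_days + 1)

    def contrast_ratio(self, eps: float = EPS) -> np.ndarray:
        """Per-day |case - control| over pooled CI half-width, gaps interpolated."""
        mean = np.vstack([_interp_nan(self.mean[g]) for g in (0, 1)])
        hw = np.vstack([_interp_nan(self.halfwidth[g]) for g in (0, 1)])
        pooled = np.sqrt(hw[0] ** 2 + hw[1] ** 2)
        return np.abs(mean[1] - mean[0]) / (pooled + eps)


def _interp_nan(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs (edge runs take the nearest value)."""
    x = x.astype(float).copy()
    ok = np.isfinite(x)
    if not ok.any():
        return np.zeros_like(x)
    idx = np.arange(len(x))
    x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return x


def group_curves(
    labs: Sequence[LabMeasurement],
    patients: Sequence[PatientRecord] | pd.DataFrame,
    test_name: str,
    obs_days: int = 60,
) -> GroupCurves:
    """Per-day group means and normal-approximation 95% CIs of daily values.

    Same-day repeats are first averaged per patient (the daily-grid
    convention); the curve then averages over the group's patients observed
    that day.  Days observed by fewer than two patients get a NaN half-width
    (interpolated later for distance computation).
    """
    if isinstance(patients, pd.DataFrame):
        labels = dict(zip(patients["patient_id"], patients["ssi"].astype(int)))
    else:
        labels = {p.patient_id: p.ssi for p in patients}
    grid = aggregate_daily(
        [m for m in labs if m.test_name == test_name],
        obs_days,
        patient_ids=sorted(labels),
        test_names=[test_name],
    )
    ssi = np.array([labels[p] for p in grid.patient_ids])
    vals = grid.values[:, 0, :]
    obs = grid.mask[:, 0, :]
    n_days = obs_days + 1
    mean = np.full((2, n_days), np.nan)
    hw = np.full((2, n_days), np.nan)
    n_obs = np.zeros((2, n_days), dtype=int)
    for g in (0, 1):
        rows = ssi == g
        if not rows.any():
            raise ValueError(f"group {g} is empty")
        v = vals[rows]
        m = obs[rows]
        cnt = m.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mu = np.where(cnt > 0, np.nansum(np.where(m, v, np.nan), axis=0) / np.maximum(cnt, 1), np.nan)
        mean[g] = mu
        n_obs[g] = cnt
        for j in np.flatnonzero(cnt >= 2):
            sd = v[m[:, j], j].std(ddof=1)
            hw[g, j] = Z95 * sd / math.sqrt(cnt[j])
    # grid columns run oldest -> newest; reindex by day-before-surgery
    return GroupCurves(
        test_name=test_name,
        obs_days=obs_days,
        mean=mean[:, ::-1].copy(),
        halfwidth=hw[:, ::-1].copy(),
        n_obs=n_obs[:, ::-1].copy(),
    )


def window_distance(
    curves: GroupCurves, window: tuple[int, int], eps: float = EPS
) -> float:
    """Mean per-day contrast ratio over ``window = (oldest, newest)`` days."""
    hi, lo = window
    if not curves.obs_days >= hi >= lo >= 0:
        raise ValueError(f"window {window} outside [0, {curves.obs_days}]")
    r = curves.contrast_ratio(eps)
    return float(r[lo : hi + 1].mean())


@dataclass(frozen=True)
class Partitioning:
    """Contiguous windows covering ``[obs_days, 0]``, from chosen cut days."""

    n_days: int
    cuts: tuple[int, ...]  # descending; each cut is the oldest day of a window
    windows: tuple[tuple[int, int], ...]

    @property
    def k(self) -> int:
        return len(self.cuts)


def _cuts_to_windows(n_days: int, cuts: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
    cuts = tuple(sorted(cuts, reverse=True))
    k = len(cuts)
    wins = []
    for i in range(k):
        hi = n_days if i == 0 else cuts[i]
        lo = cuts[i + 1] + 1 if i < k - 1 else 0
        wins.append((hi, lo))
    return tuple(wins)


def enumerate_partitionings(n_days: int, k: int) -> Iterator[Partitioning]:
    """All C(n_days, k) cut-day selections, each mapped to contiguous windows.

    Cut days are chosen from the ``n_days`` non-surgery days {1, ..., n_days};
    the oldest window absorbs any days older than the oldest cut, and the
    newest window always ends at day 0.
    """
    if not 1 <= k <= n_days:
        raise ValueError(f"need 1 <= k <= n_days, got k={k}, n_days={n_days}")
    for combo in combinations(range(1, n_days + 1), k):
        cuts = tuple(sorted(combo, reverse=True))
        yield Partitioning(n_days=n_days, cuts=cuts, windows=_cuts_to_windows(n_days, cuts))


def n_partitionings(n_days: int, k: int) -> int:
    """Number of candidate cut-day selections, C(n_days, k)."""
    if not 1 <= k <= n_days:
        raise ValueError(f"need 1 <= k <= n_days, got k={k}, n_days={n_days}")
    return math.comb(n_days, k)


def partition_score(
    distances: Sequence[float], mode: str = "product"
) -> float:
    """Combine window distances: product (default) or sum."""
    d = np.asarray(distances, dtype=float)
    if mode == "product":
        return float(np.prod(d))
    if mode == "sum":
        return float(np.sum(d))
    raise ValueError("mode must be 'product' or 'sum'")


def best_partitioning(
    labs: Sequence[LabMeasurement],
    patients: Sequence[PatientRecord] | pd.DataFrame,
    test_name: str,
    k_max: int,
    obs_days: int = 60,
    score_mode: str = "product",
    eps: float = EPS,
) -> tuple[Partitioning, float]:
    """Exhaustive two-step search for the best-scoring partitioning.

    For each ``k <= k_max`` every cut-day selection is scored by the product
    (or sum) of its window distances; the overall argmax is returned.  Ties
    prefer smaller ``k``, then lexicographically earlier (ascending) cuts —
    with ascending-order enumeration the first maximum found wins.
    """
    if k_max > obs_days:
        raise ValueError("k_max cannot exceed the number of non-surgery days")
    curves = group_curves(labs, patients, test_name, obs_days)
    r = curves.contrast_ratio(eps)
    csum = np.concatenate([[0.0], np.cumsum(r)])  # csum[d] = sum of r[0:d]

    def wdist(hi: int, lo: int) -> float:
        return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)

    best: tuple[Partitioning, float] | None = None
    for k in range(1, k_max + 1):
        for part in enumerate_partitionings(obs_days, k):
            score = partition_score([wdist(hi, lo) for hi, lo in part.windows], score_mode)
            if best is None or score > best[1]:
                best = (part, score)
    assert best is not None
    return best
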