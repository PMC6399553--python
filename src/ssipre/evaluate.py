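"""Repeated-holdout evaluation, metrics, selection stability and cost accounting.

Each experiment repeats a stratified 80/20 train/validation split (validation
size ``floor(0.2 n)``), tunes and fits the penalized lasso on the training
side, picks the classification threshold on training predictions (Youden's J)
and scores the validation side.  Per-repeat metrics are aggregated as means
with 95% t-distribution confidence intervals; feature-selection frequencies
and modal coefficient signs are tallied across repeats; and a provisional
blood-test cost is charged per validation patient: every recorded measurement
of every test appearing in that repeat's selected-feature set is billed at
the catalog price.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .catalog import TestCatalogEntry
from .features import feature_test
from .model import PenaltySpec, predict_proba, rose_oversample, select_lambda_cv
from .synth import LabMeasurement

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentSpec",
    "MetricReport",
    "SelectionFrequencyTable",
    "CostReport",
    "HoldoutResult",
    "roc_auc",
    "pr_auc",
    "classification_metrics",
    "choose_threshold",
    "repeated_holdout",
    "cost_report",
    "relative_reduction",
]

METRIC_COLUMNS = [
    "auc", "auprc", "threshold", "sensitivity", "specificity",
    "ppv", "npv", "n_selected_features",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Conditions of one repeated-holdout experiment."""

    n_repeats: int = 100
    train_fraction: float = 0.8
    feature_set: str = "FLM"
    p_max: int | None = None
    price_penalty: bool = False
    imputation: str = "hybrid"
    knn_k: int = 5
    obs_days: int = 60
    seed: int = 0
    folds: int = 10
    n_lambdas: int = 100
    rose: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class MetricReport:
    """Per-repeat metric table plus mean / 95% CI aggregation."""

    per_repeat: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = {}
        for col in self.per_repeat.columns:
            x = self.per_repeat[col].to_numpy(dtype=float)
            m = x.mean()
            if len(x) > 1 and x.std(ddof=1) > 0:
                lo, hi = stats.t.interval(0.95, len(x) - 1, loc=m, scale=stats.sem(x))
            else:
                lo = hi = m
            rows[col] = {"mean": m, "ci_low": lo, "ci_high": hi}
        return pd.DataFrame(rows).T


@dataclass
class SelectionFrequencyTable:
    """How often each feature enters the model across repeats, and with which sign."""

    n_repeats: int
    table: pd.DataFrame  # index: feature; columns: count, pos, neg, sign

    def top(self, min_count: int = 1) -> pd.DataFrame:
        return self.table[self.table["count"] >= min_count].sort_values(
            "count", ascending=False
        )


@dataclass
class CostReport:
    """Total provisional blood-test cost (NOK) over all validation patients."""

    total_nok: float
    per_repeat_nok: np.ndarray
    n_patient_evaluations: int


@dataclass
class HoldoutResult:
    metrics: MetricReport
    selection: SelectionFrequencyTable
    cost: CostReport | None
    n_validation_total: int
    selected_tests_per_repeat: list[tuple[str, ...]] = field(default_factory=list)
    validation_ids_per_repeat: list[tuple[str, ...]] = field(default_factory=list)
    nonzero_per_repeat: list[dict[str, float]] = field(default_factory=list)


def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall step curve."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()


def classification_metrics(scores, labels, threshold: float) -> ConfusionMetrics:
    """Confusion-table ratios at ``score >= threshold``; 0 (flagged) on 0/0."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    return ConfusionMetrics(
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        ppv=ratio(tp, tp + fp, "ppv"),
        npv=ratio(tn, tn + fn, "npv"),
        undefined=tuple(undefined),
    )


def choose_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J (sens + spec - 1); ties pick the lowest.

    Candidates are the observed score values and midpoints between adjacent
    distinct scores, so perfectly separated classes yield the gap midpoint.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    cands = np.sort(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]))
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_t, best_j = float(cands[0]), -np.inf
    for t in cands:
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        j = tp / n_pos + (n_neg - fp) / n_neg - 1.0
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def _measurement_counts(
    labs: Sequence[LabMeasurement] | pd.DataFrame, obs_days: int
) -> pd.DataFrame:
    if isinstance(labs, pd.DataFrame):
        df = labs
    else:
        df = pd.DataFrame(
            [(m.patient_id, m.test_name, m.day) for m in labs],
            columns=["patient_id", "test_name", "day"],
        )
    df = df[df["day"] <= obs_days]
    return df.groupby(["patient_id", "test_name"]).size().unstack(fill_value=0)


def cost_report(
    selected_tests_per_repeat: Sequence[Sequence[str]],
    validation_ids_per_repeat: Sequence[Sequence[str]],
    labs: Sequence[LabMeasurement] | pd.DataFrame,
    catalog: Sequence[TestCatalogEntry],
    obs_days: int = 60,
) -> CostReport:
    """Bill every recorded measurement of every selected test per validation patient."""
    counts = _measurement_counts(labs, obs_days)
    prices = {e.test_name: e.price for e in catalog}
    per_repeat = np.zeros(len(selected_tests_per_repeat))
    n_eval = 0
    for r, (tests, ids) in enumerate(
        zip(selected_tests_per_repeat, validation_ids_per_repeat)
    ):
        n_eval += len(ids)
        tests = [t for t in tests if t in counts.columns]
        if not tests:
            continue
        ids_present = [i for i in ids if i in counts.index]
        sub = counts.loc[ids_present, tests]
        per_repeat[r] = float(
            (sub * np.array([prices[t] for t in tests])[None, :]).to_numpy().sum()
        )
    return CostReport(
        total_nok=float(per_repeat.sum()),
        per_repeat_nok=per_repeat,
        n_patient_evaluations=n_eval,
    )


def relative_reduction(cost_a: CostReport | float, cost_b: CostReport | float) -> float:
    """Relative cost reduction of variant B against variant A: 1 - B/A."""
    a = cost_a.total_nok if isinstance(cost_a, CostReport) else float(cost_a)
    b = cost_b.total_nok if isinstance(cost_b, CostReport) else float(cost_b)
    if a == 0:
        return 0.0
    return 1.0 - b / a


def repeated_holdout(
    X: pd.DataFrame,
    y,
    spec: ExperimentSpec,
    penalty: PenaltySpec | None = None,
    labs: Sequence[LabMeasurement] | pd.DataFrame | None = None,
    catalog: Sequence[TestCatalogEntry] | None = None,
) -> HoldoutResult:
    """Run the repeated stratified-holdout experiment on a feature matrix.

    ``X`` must be indexed by patient id; ``penalty`` (when given) implements
    the price-penalized variant.  Supplying ``labs`` and ``catalog`` enables
    the per-repeat provisional cost accounting.
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    n_val = int(np.floor((1.0 - spec.train_fraction) * n + 1e-9))
    if n_val < 1 or n_val >= n:
        raise ValueError("train_fraction leaves an empty split")
    ss = np.random.SeedSequence(spec.seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_repeats)]

    idx_all = np.arange(n)
    rows = []
    sel_count: dict[str, int] = {}
    sel_pos: dict[str, int] = {}
    sel_neg: dict[str, int] = {}
    sel_tests_per_rep: list[tuple[str, ...]] = []
    val_ids_per_rep: list[tuple[str, ...]] = []
    nonzero_per_rep: list[dict[str, float]] = []
    n_validation_total = 0

    for rep, rs in enumerate(rep_seeds):
        tr, va = _stratified_split(idx_all, y, n_val, rs)
        Xtr, ytr = X.iloc[tr], y[tr]
        Xva, yva = X.iloc[va], y[va]
        if spec.rose:
            Xtr, ytr = rose_oversample(Xtr, ytr, seed=rs)
        model = select_lambda_cv(
            Xtr, ytr, penalty=penalty, folds=spec.folds, p_max=spec.p_max,
            seed=rs, n_lambdas=spec.n_lambdas,
        )
        p_tr = predict_proba(model, Xtr)
        thr = choose_threshold(p_tr, ytr)
        p_va = predict_proba(model, Xva)
        cm = classification_metrics(p_va, yva, thr)
        rows.append(
            {
                "auc": roc_auc(p_va, yva),
                "auprc": pr_auc(p_va, yva),
                "threshold": thr,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "ppv": cm.ppv,
                "npv": cm.npv,
                "n_selected_features": len(model.nonzero),
            }
        )
        nonzero = {
            name: float(b) for name, b in zip(model.feature_names, model.beta) if b != 0.0
        }
        nonzero_per_rep.append(nonzero)
        for name, b in nonzero.items():
            sel_count[name] = sel_count.get(name, 0) + 1
            if b > 0:
                sel_pos[name] = sel_pos.get(name, 0) + 1
            else:
                sel_neg[name] = sel_neg.get(name, 0) + 1
        if catalog is not None:
            tests = sorted(
                {
                    t
                    for t in (feature_test(f, catalog) for f in model.nonzero)
                    if t is not None
                }
            )
        else:
            tests = []
        sel_tests_per_rep.append(tuple(tests))
        val_ids_per_rep.append(tuple(X.index[va]))
        n_validation_total += len(va)

    per_repeat = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    features = sorted(sel_count)
    table = pd.DataFrame(
        {
            "count": [sel_count[f] for f in features],
            "pos": [sel_pos.get(f, 0) for f in features],
            "neg": [sel_neg.get(f, 0) for f in features],
        },
        index=pd.Index(features, name="feature"),
    )
    table["sign"] = np.where(table["pos"] >= table["neg"], "+", "-")
    selection = SelectionFrequencyTable(n_repeats=spec.n_repeats, table=table)

    cost = None
    if labs is not None and catalog is not None:
        cost = cost_report(sel_tests_per_rep, val_ids_per_rep, labs, catalog, spec.obs_days)

    return HoldoutResult(
        metrics=MetricReport(per_repeat=per_repeat),
        selection=selection,
        cost=cost,
        n_validation_total=n_validation_total,
        selected_tests_per_repeat=sel_tests_per_rep,
        validation_ids_per_repeat=val_ids_per_rep,
        nonzero_per_repeat=nonzero_per_rep,
    )


def _stratified_split(idx, y, n_val: int, seed: int, max_tries: int = 10):
    """Stratified split; resplit with the next seed if a side is single-class."""
    for attempt in range(max_tries):
        tr, va = train_test_split(
            idx, test_size=n_val, stratify=y, random_state=(seed + attempt) % (2**31)
        )
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2:
            if attempt:
                logger.info("resplit needed %d extra attempt(s)", attempt)
            return tr, va
    raise ValueError("could not produce a two-class split")
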