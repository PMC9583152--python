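"""Repeated-test evaluation of the ordinal risk classifier.

Per-drug feature banks hold 2,000 uncertainty samples per drug.  One *test
set* draws a single sample for each test drug (16 rows for the reference
panel); the procedure is repeated (10,000 times by default, independent
per-repeat RNG substreams) and each set is scored: one-vs-rest ROC AUC per
risk class (score = the class probability from the ordinal model), a 3x3
confusion matrix and the derived per-class diagnostics

    sensitivity = TP/(TP+FN)            specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)            accuracy    = (TP+TN)/n
    LR+ = sensitivity/(1-specificity)   LR- = (1-sensitivity)/specificity
    F1  = 2*precision*recall/(precision+recall)

Likelihood ratios undefined by zero division (specificity exactly 1 or 0)
are reported as missing with a reason code rather than infinite, so the
median/min/max summaries over repeats stay finite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from scipy.stats import rankdata

from ._seeding import named_seed
from .invitro import RISK_LEVELS
from .trace_features import FEATURE_NAMES
from .risk_olr import OrdinalRiskClassifier

__all__ = [
    "FeatureBank",
    "TestSetDraws",
    "ClassMetrics",
    "ConfusionSummary",
    "RepeatSummary",
    "make_test_sets",
    "roc_auc_ovr",
    "roc_curve_points",
    "confusion_metrics",
    "evaluate_repeats",
    "compare_datasets",
]

_BANK_META = ("dataset", "drug", "sample_index", "risk", "split")


@dataclass
class FeatureBank:
    """Per-drug feature samples: one row per (drug, sample_index).

    ``rows`` must carry the metadata columns
    (dataset, drug, sample_index, risk, split) plus the 12 feature columns.
    """

    rows: pd.DataFrame
    dataset_name: str = "default"

    def __post_init__(self):
        missing = [c for c in _BANK_META if c not in self.rows.columns]
        if missing:
            raise ValueError(f"feature bank missing column(s): {', '.join(missing)}")
        dup = self.rows.duplicated(subset=["drug", "sample_index"])
        if dup.any():
            raise ValueError("sample_index must be unique per drug")

    @property
    def feature_columns(self) -> list:
        return [c for c in FEATURE_NAMES if c in self.rows.columns]

    def subset(self, split: str) -> pd.DataFrame:
        return self.rows[self.rows["split"] == split]


def _as_rows(bank) -> pd.DataFrame:
    return bank.rows if isinstance(bank, FeatureBank) else bank


@dataclass
class TestSetDraws:
    """``indices[r, j]`` picks the sample of drug ``drugs[j]`` in repeat r."""

    drugs: list
    labels: np.ndarray          # actual risk label per drug
    sample_ids: list            # per drug: array of available sample_index values
    indices: np.ndarray         # (n_repeats, n_drugs) positions into sample_ids
    seed: int

    @property
    def n_repeats(self) -> int:
        return self.indices.shape[0]


def make_test_sets(bank, n_repeats: int = 10000, seed: int = 0,
                   feature: Optional[str] = None) -> TestSetDraws:
    """Draw ``n_repeats`` test sets, one sample per test drug per set.

    Draws are uniform and independent across repeats (each repeat gets its own
    spawned RNG substream, so results are order-independent) but exactly one
    per drug within a repeat.  If ``feature`` is given, samples with a missing
    value for that feature are excluded from the draw.
    """
    rows = _as_rows(bank)
    rows = rows[rows["split"] == "test"]
    if len(rows) == 0:
        raise ValueError("bank holds no test-split drugs")
    drugs = sorted(rows["drug"].unique())
    labels, sample_ids = [], []
    for d in drugs:
        sub = rows[rows["drug"] == d]
        if feature is not None:
            sub = sub[np.isfinite(sub[feature].to_numpy(dtype=float))]
        if len(sub) == 0:
            raise ValueError(f"drug {d!r} has zero usable samples")
        labels.append(sub["risk"].iloc[0])
        sample_ids.append(sub["sample_index"].to_numpy())

    counts = np.array([len(s) for s in sample_ids])
    children = named_seed(seed, "test-sets").spawn(n_repeats)
    indices = np.empty((n_repeats, len(drugs)), dtype=int)
    for r, child in enumerate(children):
        indices[r] = np.random.default_rng(child).integers(0, counts)
    return TestSetDraws(drugs, np.asarray(labels, dtype=object), sample_ids, indices, seed)


def roc_curve_points(scores, labels, positive_class) -> pd.DataFrame:
    """One-vs-rest ROC curve as (threshold, fpr, tpr) rows, CSV-ready."""
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels, dtype=object)
    fpr, tpr, thr = roc_curve(labels == positive_class, np.asarray(scores, dtype=float))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def roc_auc_ovr(scores, labels, positive_class) -> float:
    """Rank-based (midrank-tie) one-vs-rest ROC AUC of the positive class.

    Equals the normalised Mann-Whitney U statistic: the probability that a
    random positive outscores a random negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = labels == positive_class
    n_pos = int(pos.sum())
    n_neg = scores.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both positive and negative items required")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class ClassMetrics:
    """One-vs-rest counts and diagnostics for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    lr_plus: float
    lr_minus: float
    f1: float
    reasons: dict = field(default_factory=dict)


@dataclass
class ConfusionSummary:
    matrix: pd.DataFrame          # 3x3, rows = actual, cols = predicted
    per_class: dict               # class -> ClassMetrics
    accuracy: float
    n: int


def _safe_div(num, den):
    return num / den if den != 0 else math.nan


def confusion_metrics(predicted, actual, classes: Sequence[str] = RISK_LEVELS) -> ConfusionSummary:
    """3x3 confusion matrix and per-class one-vs-rest diagnostics."""
    predicted = np.asarray(predicted, dtype=object)
    actual = np.asarray(actual, dtype=object)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    n = predicted.size
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for a, p in zip(actual, predicted):
        mat.loc[a, p] += 1

    per_class = {}
    for c in classes:
        tp = int(((predicted == c) & (actual == c)).sum())
        fp = int(((predicted == c) & (actual != c)).sum())
        fn = int(((predicted != c) & (actual == c)).sum())
        tn = n - tp - fp - fn
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        prec = _safe_div(tp, tp + fp)
        reasons = {}
        if math.isnan(sens):
            reasons["sensitivity"] = "no actual positives"
        if math.isnan(spec):
            reasons["specificity"] = "no actual negatives"
        if math.isnan(prec):
            reasons["precision"] = "no predicted positives"
        if not math.isnan(spec) and spec == 1.0:
            lr_plus = math.nan
            reasons["lr_plus"] = "specificity = 1 (division by zero)"
        else:
            lr_plus = _safe_div(sens, 1.0 - spec) if not math.isnan(sens) else math.nan
        if not math.isnan(spec) and spec == 0.0:
            lr_minus = math.nan
            reasons["lr_minus"] = "specificity = 0 (division by zero)"
        else:
            lr_minus = _safe_div(1.0 - sens, spec) if not math.isnan(sens) else math.nan
        if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
            f1 = math.nan
            reasons.setdefault("f1", "precision + recall = 0 or undefined")
        else:
            f1 = 2 * prec * sens / (prec + sens)
        per_class[c] = ClassMetrics(tp, tn, fp, fn, sens, spec, prec, lr_plus, lr_minus, f1, reasons)

    accuracy = float((predicted == actual).mean())
    return ConfusionSummary(mat, per_class, accuracy, n)


@dataclass
class RepeatSummary:
    """median/min/max per (metric, class) over the repeated test sets."""

    table: pd.DataFrame           # index (metric, class); columns median, min, max, cell
    n_repeats: int

    def cell(self, metric: str, cls: str = "") -> str:
        return self.table.loc[(metric, cls), "cell"]


def _summarise(values: np.ndarray) -> tuple:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return (math.nan,) * 3
    return (float(np.median(finite)), float(finite.min()), float(finite.max()))


def _fmt(med, mn, mx) -> str:
    if math.isnan(med):
        return "-"
    return f"{med:.2f} ({mn:.2f}–{mx:.2f})"


def evaluate_repeats(model: OrdinalRiskClassifier, bank, feature: str,
                     n_repeats: int = 10000, seed: int = 0,
                     draws: Optional[TestSetDraws] = None) -> RepeatSummary:
    """Score the fitted single-feature model over repeated one-per-drug test
    sets; summarise each metric as median (min-max).

    ROC score for class c is the model's predicted probability of c
    (one-vs-rest).  Repeats where a metric is undefined (e.g. a class absent
    from the panel, or an LR zero-division) contribute missing cells and never
    abort the sweep.
    """
    model._check_converged()
    rows = _as_rows(bank)
    if draws is None:
        draws = make_test_sets(rows, n_repeats=n_repeats, seed=seed, feature=feature)
    n_repeats = draws.n_repeats
    drugs = draws.drugs
    labels = draws.labels

    # per-drug sample values for the scored feature, aligned with draws
    per_drug_vals = []
    test_rows = rows[rows["split"] == "test"]
    for d, ids in zip(drugs, draws.sample_ids):
        sub = test_rows[test_rows["drug"] == d].set_index("sample_index")
        per_drug_vals.append(sub.loc[ids, feature].to_numpy(dtype=float))

    D = len(drugs)
    X = np.empty((n_repeats, D))
    for j in range(D):
        X[:, j] = per_drug_vals[j][draws.indices[:, j]]

    c1 = expit(model.cutpoints_[0] - model.beta_ * X)
    c2 = expit(model.cutpoints_[1] - model.beta_ * X)
    probs = np.stack([c1, c2 - c1, 1.0 - c2], axis=-1)     # (R, D, 3)
    pred = np.where(c1 >= 0.5, 0, np.where(c2 < 0.5, 2, 1))
    act = np.array([list(model.class_order).index(l) for l in labels])

    records = []
    accuracy = (pred == act).mean(axis=1)
    records.append(("accuracy", "", accuracy))

    for k, cls in enumerate(model.class_order):
        act_c = act == k
        n_pos = int(act_c.sum())
        n_neg = D - n_pos
        if n_pos == 0 or n_neg == 0:
            auc = np.full(n_repeats, math.nan)
        else:
            ranks = rankdata(probs[:, :, k], axis=1)
            auc = (ranks[:, act_c].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        records.append(("auc", cls, auc))

        pred_c = pred == k
        tp = (pred_c & act_c).sum(axis=1).astype(float)
        fp = (pred_c & ~act_c).sum(axis=1).astype(float)
        fn = ((~pred_c) & act_c).sum(axis=1).astype(float)
        tn = D - tp - fp - fn
        with np.errstate(divide="ignore", invalid="ignore"):
            sens = np.where(tp + fn > 0, tp / (tp + fn), math.nan)
            spec = np.where(tn + fp > 0, tn / (tn + fp), math.nan)
            prec = np.where(tp + fp > 0, tp / (tp + fp), math.nan)
            lr_plus = np.where(spec < 1.0, sens / (1.0 - spec), math.nan)
            lr_minus = np.where(spec > 0.0, (1.0 - sens) / spec, math.nan)
            f1 = np.where(
                np.isfinite(prec) & np.isfinite(sens) & (prec + sens > 0),
                2 * prec * sens / (prec + sens), math.nan,
            )
        for name, vals in (("sensitivity", sens), ("specificity", spec),
                           ("precision", prec), ("lr_plus", lr_plus),
                           ("lr_minus", lr_minus), ("f1", f1)):
            records.append((name, cls, vals))

    idx, data = [], []
    for metric, cls, vals in records:
        med, mn, mx = _summarise(np.asarray(vals, dtype=float))
        idx.append((metric, cls))
        data.append({"median": med, "min": mn, "max": mx, "cell": _fmt(med, mn, mx)})
    table = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(idx, names=["metric", "class"]))
    return RepeatSummary(table, n_repeats)


def compare_datasets(a, b) -> tuple:
    """Variance-ratio F test (two-sided) then Welch's unequal-variance t test.

    Returns (f_statistic, f_p, t_statistic, t_p).  The Welch test uses the
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must have size >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both samples")
    f_stat = va / vb if vb > 0 else math.inf
    dfn, dfd = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f_stat, dfn, dfd)
    f_p = float(2 * min(cdf, 1 - cdf))
    t_res = stats.ttest_ind(a, b, equal_var=False)
    return float(f_stat), f_p, float(t_res.statistic), float(t_res.pvalue)
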