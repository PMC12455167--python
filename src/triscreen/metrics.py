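"""Screening-performance and agreement statistics.

Everything derives from the 2×2 confusion matrix of system verdicts against
the gold standard (the original review's final inclusion list).  The panel
mirrors what screening studies report under extreme class imbalance
(inclusion prevalence well below 5%):

* accuracy and class-conditional precision / recall / F1, computed twice —
  once with *include* and once with *exclude* as the positive class;
* F-β (β = 2 by default: missing an eligible study is costlier than
  over-including), balanced accuracy and the Matthews correlation
  coefficient, all robust to imbalance;
* Cohen's κ = (p_o − p_e)/(1 − p_e) and PABAK = 2·p_o − 1, the
  prevalence-adjusted bias-adjusted κ.  Under low prevalence the marginal
  chance agreement p_e approaches p_o and κ collapses toward 0 even when
  raw agreement is high; PABAK fixes the chance term at 1/2 and is the
  recommended agreement summary for screening corpora;
* record-count-weighted cross-dataset summaries with unweighted SD and
  range, and a paired κ-vs-PABAK significance test (paired two-tailed t
  when the paired differences pass Shapiro–Wilk normality at α = .05,
  Wilcoxon signed-rank otherwise).

Zero-denominator conventions (documented and tested): precision with zero
predicted positives is 0 with a warning; recall with zero actual positives
is undefined and reported as missing (None); MCC with a zero factor is 0;
κ with p_e = 1 is 1 when p_o = 1 and 0 otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "WeightedSummary",
    "PairedTestResult",
    "MetricWarning",
    "confusion_from_verdicts",
    "class_metrics",
    "agreement_metrics",
    "weighted_summary",
    "kappa_pabak_test",
]


class MetricWarning(UserWarning):
    """A metric hit a degenerate denominator and used a documented convention."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts of system verdicts vs gold labels.

    ``tp`` counts records the system and the gold both assign to the
    positive class (*include* by default).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swap_positive(self) -> "ConfusionMatrix":
        """The same table with the positive class flipped."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


def confusion_from_verdicts(
    verdicts: Mapping[str, str] | pd.DataFrame,
    gold: Mapping[str, str] | pd.DataFrame,
    positive: str = "include",
) -> ConfusionMatrix:
    """Tabulate final verdicts against gold labels.

    Tables may be mappings record_id → label or DataFrames whose first two
    columns are (record_id, label).  Labels must be binary over the two
    values {positive, other}.  Verdict ids absent from the gold table raise
    (records are never silently dropped); gold may be a superset.
    """
    v = _as_label_dict(verdicts, "verdicts")
    g = _as_label_dict(gold, "gold")
    unmatched = sorted(set(v) - set(g))
    if unmatched:
        raise ValueError(f"verdict record ids absent from gold table: {unmatched}")
    labels = set(v.values()) | {g[k] for k in v}
    if len(labels) > 2:
        raise ValueError(f"labels are not binary: {sorted(labels)}")
    if labels and positive not in labels and len(labels) == 2:
        raise ValueError(f"positive label {positive!r} not among labels {sorted(labels)}")
    tp = fp = fn = tn = 0
    for rid, verdict in v.items():
        truth = g[rid]
        if verdict == positive:
            tp += truth == positive
            fp += truth != positive
        else:
            fn += truth == positive
            tn += truth != positive
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _as_label_dict(table: Mapping[str, str] | pd.DataFrame, name: str) -> dict[str, str]:
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise ValueError(f"{name} table needs (record_id, label) columns")
        ids = table.iloc[:, 0].astype(str)
        labels = table.iloc[:, 1].astype(str)
        return dict(zip(ids, labels))
    return {str(k): str(val) for k, val in table.items()}


def _precision(tp: int, fp: int, side: str) -> float:
    if tp + fp == 0:
        warnings.warn(
            f"no predicted positives for {side} class; precision set to 0",
            MetricWarning,
            stacklevel=3,
        )
        return 0.0
    return tp / (tp + fp)


def _recall(tp: int, fn: int) -> float | None:
    if tp + fn == 0:
        return None  # no actual positives: recall undefined
    return tp / (tp + fn)


def _f_score(precision: float | None, recall: float | None, beta: float) -> float | None:
    if precision is None or recall is None:
        return None
    denom = beta * beta * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


def _mcc(cm: ConfusionMatrix) -> float:
    denom_sq = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom_sq == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom_sq)


@dataclass
class MetricReport:
    """The full metric panel for one confusion matrix.

    ``positive_*`` metrics treat the configured positive class (include, by
    default) as the target; ``negative_*`` metrics are the same quantities
    with the classes swapped.  ``None`` marks a metric undefined on this
    table (e.g. recall with zero actual positives).
    """

    cm: ConfusionMatrix
    beta: float
    accuracy: float
    positive_precision: float
    positive_recall: float | None
    positive_f1: float | None
    negative_precision: float
    negative_recall: float | None
    negative_f1: float | None
    f_beta: float | None
    balanced_accuracy: float | None
    mcc: float
    kappa: float = math.nan
    pabak: float = math.nan
    p_o: float = math.nan
    p_e: float = math.nan

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "positive_precision": self.positive_precision,
            "positive_recall": self.positive_recall,
            "positive_f1": self.positive_f1,
            "negative_precision": self.negative_precision,
            "negative_recall": self.negative_recall,
            "negative_f1": self.negative_f1,
            "f_beta": self.f_beta,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "pabak": self.pabak,
        }

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Display form: values rounded (2 d.p. by convention)."""
        return {
            k: (None if v is None or (isinstance(v, float) and math.isnan(v))
                else round(v, ndigits))
            for k, v in self.as_dict().items()
        }


def class_metrics(cm: ConfusionMatrix, beta: float = 2.0) -> MetricReport:
    """Classification metrics plus agreement metrics for one 2×2 table."""
    if cm.n < 1:
        raise ValueError("confusion matrix must contain at least one record")
    if beta <= 0:
        raise ValueError("beta must be positive")
    swapped = cm.swap_positive()
    pos_p = _precision(cm.tp, cm.fp, "positive")
    pos_r = _recall(cm.tp, cm.fn)
    neg_p = _precision(swapped.tp, swapped.fp, "negative")
    neg_r = _recall(swapped.tp, swapped.fn)
    balanced = None if pos_r is None or neg_r is None else (pos_r + neg_r) / 2
    p_o, p_e, kappa, pabak = agreement_metrics(cm)
    return MetricReport(
        cm=cm,
        beta=beta,
        accuracy=(cm.tp + cm.tn) / cm.n,
        positive_precision=pos_p,
        positive_recall=pos_r,
        positive_f1=_f_score(pos_p, pos_r, 1.0),
        negative_precision=neg_p,
        negative_recall=neg_r,
        negative_f1=_f_score(neg_p, neg_r, 1.0),
        f_beta=_f_score(pos_p, pos_r, beta),
        balanced_accuracy=balanced,
        mcc=_mcc(cm),
        kappa=kappa,
        pabak=pabak,
        p_o=p_o,
        p_e=p_e,
    )


def agreement_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """Observed agreement, chance agreement, Cohen's κ and PABAK.

    p_o = (tp+tn)/n;  p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / n²;
    κ = (p_o − p_e)/(1 − p_e);  PABAK = 2·p_o − 1.
    """
    if cm.n < 1:
        raise ValueError("confusion matrix must contain at least one record")
    n = cm.n
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if p_e == 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    pabak = 2 * p_o - 1
    return p_o, p_e, kappa, pabak


@dataclass
class WeightedSummary:
    """Cross-dataset summary: record-count-weighted means, unweighted SD, range.

    ``pooled_accuracy`` is Σ correct / Σ n, which equals the record-count
    weighted mean of the per-dataset accuracies.
    """

    per_dataset: list[dict[str, float | None]]
    weights: list[int]
    weighted_mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    value_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    pooled_accuracy: float | None = None


def weighted_summary(
    per_dataset: Sequence[tuple[Mapping[str, float | None], int]]
) -> WeightedSummary:
    """Summarize per-dataset metric panels across datasets.

    ``per_dataset`` pairs each dataset's metric mapping with its record
    count (the weight).  For each metric: weighted mean Σwᵢxᵢ/Σwᵢ over the
    datasets where the metric is defined; SD is the unweighted sample SD of
    the per-dataset values (0 for a single dataset); range is (min, max).
    """
    if not per_dataset:
        raise ValueError("need at least one dataset")
    if any(w <= 0 for _, w in per_dataset):
        raise ValueError("weights (record counts) must be positive")
    metrics_seen: list[str] = []
    for values, _ in per_dataset:
        for k in values:
            if k not in metrics_seen:
                metrics_seen.append(k)
    summary = WeightedSummary(
        per_dataset=[dict(v) for v, _ in per_dataset],
        weights=[w for _, w in per_dataset],
    )
    for metric in metrics_seen:
        pairs = [
            (float(v[metric]), w)
            for v, w in per_dataset
            if v.get(metric) is not None and not math.isnan(float(v[metric]))
        ]
        if not pairs:
            continue
        xs = np.array([x for x, _ in pairs])
        ws = np.array([w for _, w in pairs], dtype=float)
        summary.weighted_mean[metric] = float(np.sum(ws * xs) / np.sum(ws))
        summary.sd[metric] = float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0
        summary.value_range[metric] = (float(xs.min()), float(xs.max()))
    if "accuracy" in summary.weighted_mean:
        summary.pooled_accuracy = summary.weighted_mean["accuracy"]
    return summary


@dataclass
class PairedTestResult:
    """Result of the paired κ-vs-PABAK comparison across datasets."""

    method: str  # "paired t" or "wilcoxon signed rank"
    statistic: float | None
    df: int | None
    p_value: float | None
    normality_p: float | None
    mean_kappa: float
    mean_pabak: float
    degenerate: bool = False

    @property
    def significant(self) -> bool | None:
        return None if self.p_value is None else bool(self.p_value < 0.05)


def kappa_pabak_test(
    kappas: Sequence[float], pabaks: Sequence[float], alpha: float = 0.05
) -> PairedTestResult:
    """Paired two-tailed comparison of per-dataset κ against PABAK.

    The paired differences are first checked for normality with
    Shapiro–Wilk at the given α: normal differences get a paired two-tailed
    t test (df = n−1), non-normal ones a Wilcoxon signed-rank test.  All
    differences exactly zero is a degenerate case: flagged, no statistic.
    """
    k = np.asarray(kappas, dtype=float)
    p = np.asarray(pabaks, dtype=float)
    if k.shape != p.shape:
        raise ValueError("kappa and PABAK vectors must have equal length")
    if k.size < 3:
        raise ValueError("need at least 3 paired datasets")
    diffs = k - p
    mean_k, mean_p = float(k.mean()), float(p.mean())
    if np.all(diffs == 0):
        return PairedTestResult(
            method="degenerate", statistic=None, df=None, p_value=None,
            normality_p=None, mean_kappa=mean_k, mean_pabak=mean_p, degenerate=True,
        )
    if np.all(diffs == diffs[0]):
        # constant non-zero differences: zero variance, t undefined
        return PairedTestResult(
            method="degenerate", statistic=None, df=None, p_value=None,
            normality_p=None, mean_kappa=mean_k, mean_pabak=mean_p, degenerate=True,
        )
    normality_p = float(stats.shapiro(diffs).pvalue)
    if normality_p >= alpha:
        res = stats.ttest_rel(k, p, alternative="two-sided")
        return PairedTestResult(
            method="paired t",
            statistic=float(res.statistic),
            df=int(k.size - 1),
            p_value=float(res.pvalue),
            normality_p=normality_p,
            mean_kappa=mean_k,
            mean_pabak=mean_p,
        )
    res = stats.wilcoxon(k, p, alternative="two-sided")
    return PairedTestResult(
        method="wilcoxon signed rank",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        normality_p=normality_p,
        mean_kappa=mean_k,
        mean_pabak=mean_p,
    )
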