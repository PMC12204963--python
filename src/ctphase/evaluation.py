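"""Diagnostic-accuracy statistics for phase classification.

One-vs-rest confusion counts per class, and from them sensitivity,
specificity, accuracy, PPV, NPV and AUC with 95% CIs, plus subgroup χ²
tests with Bonferroni correction.

Two conventions matter for reproducing printed clinical tables:

* **AUC of a hard classifier.**  For an argmax (single-operating-point)
  classifier the ROC has one interior vertex and its area equals balanced
  accuracy, (sensitivity + specificity)/2.  That is the reported "AUC"
  here; a score-based ROC AUC is available separately when probability
  outputs exist.
* **Rounding.**  Percentages are rounded half-up to 1 decimal and AUCs to
  3 decimals (half-up, not banker's: 96.875 → 96.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .volumes import PHASES

__all__ = [
    "ClassCounts", "ClassMetrics", "MetricsReport", "confusion_from_predictions",
    "metrics_from_counts", "proportion_ci", "chi_square_subgroups",
    "compare_strategies", "roc_auc_scores",
]


def round_half_up(x: Fraction | float, decimals: int) -> float:
    """Decimal half-up rounding (printed-table convention)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassCounts:
    """One-vs-rest confusion counts per class: (TP, FN, TN, FP)."""

    counts: dict[str, tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        totals = {sum(v) for v in self.counts.values()}
        if len(totals) > 1:
            raise ValueError(f"per-class totals differ: {sorted(totals)}")
        for cls, (tp, fn, tn, fp) in self.counts.items():
            if min(tp, fn, tn, fp) < 0:
                raise ValueError(f"negative count for class {cls}")

    @property
    def total(self) -> int:
        return sum(next(iter(self.counts.values())))

    def __getitem__(self, cls: str) -> tuple[int, int, int, int]:
        return self.counts[cls]

    def classes(self) -> list[str]:
        return list(self.counts)


def confusion_from_predictions(predicted: list[str], true: list[str],
                               classes: tuple[str, ...] = PHASES) -> ClassCounts:
    """Build one-vs-rest counts from parallel label lists."""
    if len(predicted) != len(true):
        raise ValueError("label lists differ in length")
    for lbl in (*predicted, *true):
        if lbl not in classes:
            raise ValueError(f"unknown label {lbl!r}")
    pred = np.asarray(predicted)
    tru = np.asarray(true)
    counts = {}
    for cls in classes:
        tp = int(np.sum((pred == cls) & (tru == cls)))
        fn = int(np.sum((pred != cls) & (tru == cls)))
        fp = int(np.sum((pred == cls) & (tru != cls)))
        tn = int(np.sum((pred != cls) & (tru != cls)))
        counts[cls] = (tp, fn, tn, fp)
    return ClassCounts(counts)


def confusion_matrix(predicted: list[str], true: list[str],
                     classes: tuple[str, ...] = PHASES) -> pd.DataFrame:
    """Full cross-tabulation, rows = truth, columns = prediction."""
    m = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for p, t in zip(predicted, true):
        m.loc[t, p] += 1
    return m


@dataclass
class ClassMetrics:
    """Rounded metrics for one class; ``None`` marks an undefined metric."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    auc: float | None
    fractions: dict[str, tuple[int, int]] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    overall_accuracy: float          # percent, 1 decimal
    overall_fraction: tuple[int, int]
    ci_method: str = "wilson"

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for cls, m in self.per_class.items():
            rows[cls] = {
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "accuracy": m.accuracy, "ppv": m.ppv, "npv": m.npv, "auc": m.auc,
            }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [self.to_frame().to_string(),
                 f"overall accuracy: {self.overall_accuracy}% "
                 f"({self.overall_fraction[0]}/{self.overall_fraction[1]})",
                 f"CI method: {self.ci_method}"]
        return "\n".join(lines)


def proportion_ci(successes: int, n: int, method: str = "wilson") -> tuple[float, float]:
    """Two-sided 95% CI for a proportion, in percent.

    ``method`` is ``'wilson'`` (default) or ``'clopper-pearson'``.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("require 0 <= successes <= n, n > 0")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(successes, n, alpha=0.05, method=sm_method)
    return float(lo) * 100.0, float(hi) * 100.0


def metrics_from_counts(counts: ClassCounts | dict, ci_method: str = "wilson",
                        with_ci: bool = True) -> MetricsReport:
    """Sensitivity/specificity/accuracy/PPV/NPV/AUC from confusion counts.

    AUC is the hard-classifier convention (sensitivity + specificity)/2.
    Zero-denominator metrics are reported as undefined (``None``), never
    as 0.  Overall accuracy pools TPs across classes: Σ TP_c / total.
    """
    if not isinstance(counts, ClassCounts):
        counts = ClassCounts(dict(counts))
    per_class: dict[str, ClassMetrics] = {}
    for cls in counts.classes():
        tp, fn, tn, fp = counts[cls]
        total = tp + fn + tn + fp
        fracs = {
            "sensitivity": (tp, tp + fn),
            "specificity": (tn, tn + fp),
            "accuracy": (tp + tn, total),
            "ppv": (tp, tp + fp),
            "npv": (tn, tn + fn),
        }
        vals: dict[str, float | None] = {}
        cis: dict[str, tuple[float, float]] = {}
        for name, (num, den) in fracs.items():
            if den == 0:
                vals[name] = None
                continue
            vals[name] = round_half_up(Fraction(num, den) * 100, 1)
            if with_ci:
                cis[name] = proportion_ci(num, den, method=ci_method)
        if (tp + fn) and (tn + fp):
            auc_frac = (Fraction(tp, tp + fn) + Fraction(tn, tn + fp)) / 2
            auc = round_half_up(auc_frac, 3)
        else:
            auc = None
        per_class[cls] = ClassMetrics(
            sensitivity=vals["sensitivity"], specificity=vals["specificity"],
            accuracy=vals["accuracy"], ppv=vals["ppv"], npv=vals["npv"],
            auc=auc, fractions=fracs, ci=cis,
        )
    correct = sum(counts[c][0] for c in counts.classes())
    total = counts.total
    overall = round_half_up(Fraction(correct, total) * 100, 1) if total else None
    return MetricsReport(per_class=per_class, overall_accuracy=overall,
                         overall_fraction=(correct, total), ci_method=ci_method)


def roc_auc_scores(scores: np.ndarray, true: list[str],
                   classes: tuple[str, ...] = PHASES) -> dict[str, float]:
    """Score-based one-vs-rest ROC AUC (Mann-Whitney) per class."""
    scores = np.asarray(scores, dtype=float)
    out = {}
    for j, cls in enumerate(classes):
        y = np.asarray([t == cls for t in true])
        if y.all() or not y.any():
            out[cls] = float("nan")
            continue
        u = stats.mannwhitneyu(scores[y, j], scores[~y, j]).statistic
        out[cls] = float(u / (y.sum() * (~y).sum()))
    return out


def chi_square_subgroups(table, n_comparisons: int = 1) -> dict:
    """Pearson χ² on a contingency table, Bonferroni-adjusted p-value.

    Returns ``{'statistic', 'dof', 'p_value', 'p_adjusted'}`` with
    ``p_adjusted = min(1, p × n_comparisons)``.  Rows or columns whose
    expected counts are zero are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("expected cell counts of zero: empty row or column")
    res = stats.chi2_contingency(t, correction=False)
    p = float(res.pvalue)
    return {
        "statistic": float(res.statistic),
        "dof": int(res.dof),
        "p_value": p,
        "p_adjusted": min(1.0, p * n_comparisons),
    }


@dataclass
class StrategyComparison:
    one_step: MetricsReport
    two_step: MetricsReport
    overall_one_step: float
    overall_two_step: float

    def summary(self) -> str:
        return (
            "one-step strategy\n" + self.one_step.summary()
            + "\n\ntwo-step strategy\n" + self.two_step.summary()
        )


def _flatten_labels(preds, calibrated: bool):
    labels, truths, ids = [], [], []
    for p in preds:
        use = p.labels_calibrated if (calibrated and p.labels_calibrated) else p.labels_raw
        labels.extend(use)
        truths.extend(p.true_labels)
        ids.append(p.exam_id)
    return labels, truths, ids


def compare_strategies(pred_one_step, pred_two_step, truths: list[str] | None = None,
                       calibrated: bool = False) -> StrategyComparison:
    """Side-by-side phase-wise metrics for the two strategies.

    Accepts lists of ``ExamPrediction`` (truths taken from the exams) or
    plain label lists with explicit ``truths``.  Phase-wise metrics use
    raw labels by default (calibration is an exam-level correction).
    """
    if pred_one_step and isinstance(pred_one_step[0], str):
        if truths is None:
            raise ValueError("plain label lists require explicit truths")
        l1, l2 = list(pred_one_step), list(pred_two_step)
        t1 = t2 = list(truths)
        if not len(l1) == len(l2) == len(t1):
            raise ValueError("label lists differ in length")
    else:
        l1, t1, ids1 = _flatten_labels(pred_one_step, calibrated)
        l2, t2, ids2 = _flatten_labels(pred_two_step, calibrated)
        if ids1 != ids2 or len(l1) != len(l2):
            raise ValueError("strategies were run on different exam sets")
        if truths is not None:
            t1 = t2 = list(truths)
    r1 = metrics_from_counts(confusion_from_predictions(l1, t1))
    r2 = metrics_from_counts(confusion_from_predictions(l2, t2))
    return StrategyComparison(
        one_step=r1, two_step=r2,
        overall_one_step=r1.overall_accuracy,
        overall_two_step=r2.overall_accuracy,
    )
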