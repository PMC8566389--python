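"""Statistical evaluation of PD-vs-TRC classifiers.

Confusion matrices at a 0.5 probability cutoff (PD is the positive class),
accuracy / sensitivity / specificity with exact Clopper-Pearson 95%
intervals, a one-sided exact binomial test of accuracy against the
no-information rate (the majority-class proportion), exact McNemar
comparisons between paired classifiers, and a pooled ROC over the
out-of-fold probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix", "EvalReport", "confusion_from_predictions",
    "binary_metrics", "clopper_pearson", "nir_binomial_test",
    "mcnemar_test", "roc_auc", "evaluation_report",
]


@dataclass
class ConfusionMatrix:
    """2x2 counts with progressive disease (PD) as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn


def confusion_from_predictions(probs, labels, cutoff: float = 0.5,
                               positive_label="PD") -> ConfusionMatrix:
    """Tally the 2x2 table; a case is called PD iff its probability is
    strictly greater than the cutoff (ties go to TRC)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError(f"length mismatch: {probs.shape} vs {labels.shape}")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    truth = labels == positive_label
    pred = probs > cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & truth)),
        fn=int(np.sum(~pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def binary_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity; an undefined denominator yields
    NaN (reported as missing), never 0."""
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(cm.tp + cm.tn, cm.n),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
    }


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles; the lower
    bound is 0 when x = 0 and the upper bound 1 when x = n."""
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if not 0 <= x <= n or n <= 0:
        raise ValueError(f"require 0 <= x <= n with n > 0, got x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def nir_binomial_test(correct: int, n: int, nir: float) -> float:
    """One-sided exact binomial tail P(X >= correct | n, nir): is the
    observed accuracy above the no-information rate?"""
    if not 0 <= correct <= n:
        raise ValueError("require 0 <= correct <= n")
    if not 0 < nir < 1:
        raise ValueError("no-information rate must be in (0, 1)")
    return float(stats.binomtest(correct, n, nir, alternative="greater").pvalue)


def mcnemar_test(correct_a, correct_b) -> float:
    """Exact two-sided McNemar test on the discordant pairs of two paired
    per-case correctness vectors; p = 1 when there is no discordance."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n_ab = int(np.sum(a & ~b))   # A right, B wrong
    n_ba = int(np.sum(~a & b))   # B right, A wrong
    n_disc = n_ab + n_ba
    if n_disc == 0:
        return 1.0
    return float(stats.binomtest(n_ab, n_disc, 0.5, alternative="two-sided").pvalue)


def roc_auc(probs, labels, positive_label="PD"):
    """Pooled ROC curve and AUC; the AUC equals the Mann-Whitney U statistic
    scaled by n+ * n-, with ties counted one half."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels) == positive_label
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes")
    pos = probs[y]
    neg = probs[~y]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (pos.size * neg.size)
    fpr, tpr, thresholds = roc_curve(y.astype(int), probs)
    return float(auc), np.column_stack([fpr, tpr, thresholds])


@dataclass
class EvalReport:
    """The derived metrics mirrored by the confusion-matrix table."""

    confusion: ConfusionMatrix
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    nir: float
    nir_p_one_sided: float
    nir_p_two_sided: float
    cutoff: float = 0.5
    auc: float | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = {"tp": self.confusion.tp, "fn": self.confusion.fn,
                          "fp": self.confusion.fp, "tn": self.confusion.tn}
        d.pop("roc_points")
        return d


def evaluation_report(cm: ConfusionMatrix, nir: float | None = None,
                      probs=None, labels=None, cutoff: float = 0.5) -> EvalReport:
    """Assemble the full report for one classifier.

    ``nir`` defaults to the majority-class rate implied by the matrix
    itself. If out-of-fold probabilities are supplied, the pooled ROC/AUC
    is included.
    """
    m = binary_metrics(cm)
    if nir is None:
        nir = max(cm.n_positive, cm.n - cm.n_positive) / cm.n

    def ci(num: int, den: int):
        return clopper_pearson(num, den) if den > 0 else (float("nan"),) * 2

    two_sided = float(stats.binomtest(cm.n_correct, cm.n, nir,
                                      alternative="two-sided").pvalue)
    auc = roc_pts = None
    if probs is not None and labels is not None:
        auc, roc_pts = roc_auc(probs, labels)
    return EvalReport(
        confusion=cm,
        accuracy=m["accuracy"], accuracy_ci=ci(cm.n_correct, cm.n),
        sensitivity=m["sensitivity"], sensitivity_ci=ci(cm.tp, cm.tp + cm.fn),
        specificity=m["specificity"], specificity_ci=ci(cm.tn, cm.tn + cm.fp),
        nir=nir,
        nir_p_one_sided=nir_binomial_test(cm.n_correct, cm.n, nir),
        nir_p_two_sided=two_sided,
        cutoff=cutoff, auc=auc, roc_points=roc_pts,
    )
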