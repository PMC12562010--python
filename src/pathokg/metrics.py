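"""Evaluation statistics for pathogenicity classifiers.

Balanced accuracy is the headline metric: the mean of sensitivity and
specificity, robust to the strong benign/pathogenic imbalance of clinical
variant sets.  Inference on a balanced accuracy treats it as a success
proportion: the observed success count is ``round(balanced_accuracy x
n_test)``, which feeds a one-sided exact binomial test against chance
(p = 0.5) and a Wilson score interval.  A percentile bootstrap over
(prediction, label) pairs provides a non-parametric cross-check on the
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from pathokg.errors import RangeError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the pathogenic class is positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise RangeError("confusion counts must be non-negative")
        if self.total == 0:
            raise RangeError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predicted: np.ndarray, labels: np.ndarray) -> "ConfusionMatrix":
        predicted = np.asarray(predicted).astype(bool)
        labels = np.asarray(labels).astype(bool)
        if predicted.shape != labels.shape:
            raise RangeError("prediction/label length mismatch")
        return cls(
            tp=int(np.sum(predicted & labels)),
            fp=int(np.sum(predicted & ~labels)),
            tn=int(np.sum(~predicted & ~labels)),
            fn=int(np.sum(~predicted & labels)),
        )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def rates(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and balanced accuracy.

    Rates with a zero denominator are reported as ``None`` (absent), never
    coerced to 0; balanced accuracy requires both classes present.
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    balanced = (sens + spec) / 2 if sens is not None and spec is not None else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "balanced_accuracy": balanced,
    }


def adjusted_successes(balanced_accuracy: float, n_test: int) -> int:
    """Observed successes implied by a balanced accuracy on n test cases.

    Rounded half away from zero (the product is a count).
    """
    if not 0.0 <= balanced_accuracy <= 1.0:
        raise RangeError(f"balanced accuracy {balanced_accuracy} outside [0, 1]")
    if n_test < 1:
        raise RangeError("n_test must be >= 1")
    return int(math.floor(balanced_accuracy * n_test + 0.5))


def binomial_pvalue(balanced_accuracy: float, n_test: int) -> float:
    """One-sided exact binomial p-value for above-chance balanced accuracy.

    With successes ``k = round(balanced_accuracy x n_test)`` and
    X ~ Binomial(n_test, 0.5), returns P[X >= k] (upper tail).
    """
    k = adjusted_successes(balanced_accuracy, n_test)
    return float(stats.binom.sf(k - 1, n_test, 0.5))


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Closed form: with z the two-sided normal quantile and p̂ = k/n,
    center (p̂ + z²/2n) / (1 + z²/n), half-width
    z·sqrt(p̂(1−p̂)/n + z²/4n²) / (1 + z²/n).  Bounds always lie in [0, 1]
    and bracket p̂.
    """
    if n < 1:
        raise RangeError("n must be >= 1")
    if not 0 <= successes <= n:
        raise RangeError(f"successes {successes} outside [0, {n}]")
    if not 0.0 < confidence < 1.0:
        raise RangeError("confidence must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    phat = successes / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def balanced_accuracy_score(predicted: np.ndarray, labels: np.ndarray) -> float:
    cm = ConfusionMatrix.from_predictions(predicted, labels)
    value = rates(cm)["balanced_accuracy"]
    if value is None:
        raise RangeError("balanced accuracy undefined: one class absent")
    return value


def bootstrap_ci(
    predictions: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for balanced accuracy.

    Resamples (prediction, label) pairs with replacement; replicates that
    lose one class entirely are skipped (balanced accuracy undefined there).
    """
    predictions = np.asarray(predictions).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if predictions.shape != labels.shape:
        raise RangeError("prediction/label length mismatch")
    if n_boot < 100:
        raise RangeError("n_boot must be >= 100")
    if labels.all() or not labels.any():
        raise RangeError("bootstrap requires both classes in the labels")
    rng = np.random.default_rng(seed)
    n = len(labels)
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.all() or not lab.any():
            continue
        values.append(balanced_accuracy_score(predictions[idx], lab))
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Full evaluation summary for one test partition."""

    confusion: ConfusionMatrix
    n_test: int
    balanced_accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix, confidence: float = 0.95) -> "EvalReport":
        r = rates(cm)
        ba = r["balanced_accuracy"]
        ci_low = ci_high = p_value = None
        if ba is not None:
            k = adjusted_successes(ba, cm.total)
            ci_low, ci_high = wilson_ci(k, cm.total, confidence)
            p_value = binomial_pvalue(ba, cm.total)
        return cls(
            confusion=cm,
            n_test=cm.total,
            balanced_accuracy=ba,
            sensitivity=r["sensitivity"],
            specificity=r["specificity"],
            ppv=r["ppv"],
            npv=r["npv"],
            ci_low=ci_low,
            ci_high=ci_high,
            p_value=p_value,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn}
        return d
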