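"""Turning posterior attentiveness probabilities into labels, and scoring them.

Two rules are implemented.  The threshold rule flags person i as careless
when their posterior attentiveness probability falls strictly below 0.5.
The proportion (ranking) rule takes the estimated population attentive
proportion pi-hat, computes k = round(N * (1 - pi-hat)), and flags the k
persons with the smallest probabilities.

The confusion metrics treat *attentive* as the positive class, so:
sensitivity = attentive correctly labeled / truly attentive;
precision   = truly attentive / labeled attentive;
FPR         = careless labeled attentive / truly careless;
FNR         = attentive labeled careless / truly attentive.
These are deliberate, nonstandard orientations (FPR is the rate at which
careless respondents slip through) and are implemented verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATTENTIVE",
    "CARELESS",
    "ClassificationResult",
    "MetricReport",
    "classify_threshold",
    "classify_proportion",
    "confusion_metrics",
]

ATTENTIVE = "attentive"
CARELESS = "careless"


@dataclass
class ClassificationResult:
    labels: np.ndarray            # strings attentive/careless, one per person
    rule: str                     # "threshold" or "proportion"
    threshold: float = None
    flagged_count: int = None

    @property
    def careless_mask(self) -> np.ndarray:
        return self.labels == CARELESS


@dataclass
class MetricReport:
    """Five classification metrics; undefined ratios are NaN, never 0."""

    accuracy: float
    sensitivity: float
    precision: float
    fpr: float
    fnr: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "fpr": self.fpr,
            "fnr": self.fnr,
        }


def _check_probs(person_prob) -> np.ndarray:
    p = np.asarray(person_prob, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("person_prob must be a nonempty vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def classify_threshold(person_prob, threshold: float = 0.5) -> ClassificationResult:
    """Careless iff probability strictly below the threshold (ties attentive)."""
    p = _check_probs(person_prob)
    labels = np.where(p < threshold, CARELESS, ATTENTIVE).astype(str)
    return ClassificationResult(labels=labels, rule="threshold", threshold=threshold)


def classify_proportion(person_prob, attentive_prop_hat: float) -> ClassificationResult:
    """Flag the k = round(N(1 - pi-hat)) least attentive persons.

    Ties in probability are broken by ascending person index; rounding is
    half-away-from-zero.
    """
    p = _check_probs(person_prob)
    if not (0.0 < attentive_prop_hat < 1.0):
        raise ValueError("attentive_prop_hat must lie strictly inside (0, 1)")
    n = p.size
    k = int(math.floor(n * (1.0 - attentive_prop_hat) + 0.5))
    labels = np.full(n, ATTENTIVE, dtype=object)
    if k > 0:
        order = np.argsort(p, kind="stable")   # stable sort -> index tie-break
        labels[order[:k]] = CARELESS
    return ClassificationResult(labels=labels.astype(str), rule="proportion",
                                flagged_count=k)


def confusion_metrics(truth, predicted) -> MetricReport:
    """Score predicted labels against true class memberships."""
    t = np.asarray(truth, dtype=str)
    p = np.asarray(predicted, dtype=str)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    true_att = t == ATTENTIVE
    true_care = ~true_att
    pred_att = p == ATTENTIVE

    def ratio(num, den):
        return float(num) / float(den) if den > 0 else float("nan")

    return MetricReport(
        accuracy=float(np.mean(t == p)),
        sensitivity=ratio(np.sum(true_att & pred_att), np.sum(true_att)),
        precision=ratio(np.sum(true_att & pred_att), np.sum(pred_att)),
        fpr=ratio(np.sum(true_care & pred_att), np.sum(true_care)),
        fnr=ratio(np.sum(true_att & ~pred_att), np.sum(true_att)),
    )
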