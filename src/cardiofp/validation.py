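"""Confusion-matrix evaluation of template-matching classification.

A complex is a *positive* when its correlation coefficient reaches the
correlation factor (it is accepted for averaging); the ground truth is
whether it actually resembles the template.  From the four counts the
standard screening metrics follow:

    PPV         = TP / (TP + FP)   — accepted complexes that truly resemble
    sensitivity = TP / (TP + FN)   — resembling complexes that were accepted
    specificity = TN / (TN + FP)   — dissimilar complexes that were rejected

all reported as percentages rounded to two decimals.  A zero denominator
makes the metric undefined; it is rendered as an en-dash and excluded from
macro-means.  Multi-dataset summaries are macro-averages: each dataset's
metrics are computed from its own counts (unrounded) and then averaged with
equal weight, with rounding applied only at the end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ParameterError

__all__ = [
    "ConfusionCounts",
    "ValidationSummary",
    "confusion",
    "ppv",
    "sensitivity",
    "specificity",
    "summarize",
    "align_to_truth",
    "UNDEFINED",
]

#: Rendering of an undefined (0/0) metric.
UNDEFINED = "–"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels_true: Sequence[bool], labels_pred: Sequence[bool]) -> ConfusionCounts:
    """Count TP/FP/TN/FN from resemblance truth and accepted predictions."""
    t = np.asarray(labels_true, dtype=bool)
    p = np.asarray(labels_pred, dtype=bool)
    if t.shape != p.shape:
        raise ParameterError(
            f"label vectors differ in length: {t.shape} vs {p.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def align_to_truth(
    detected_indices: Sequence[int],
    beat_times: Sequence[int],
    beat_labels: Sequence[str],
    sample_rate: float,
    tol_ms: float = 10.0,
) -> list[str]:
    """Map detected beat positions onto ground-truth labels.

    Each detected index is assigned the label of the nearest annotated beat;
    a detection farther than ``tol_ms`` from every annotated beat is labelled
    ``"spurious"``.  Used by the synthetic benchmarks to score classification
    output against the generator's annotations.
    """
    bt = np.asarray(beat_times)
    tol = tol_ms / 1000.0 * sample_rate
    out: list[str] = []
    for d in np.asarray(detected_indices):
        k = int(np.argmin(np.abs(bt - d)))
        out.append(beat_labels[k] if abs(int(bt[k]) - int(d)) <= tol else "spurious")
    return out


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return num / den * 100.0


def _rounded(v: float | None) -> float | str:
    return UNDEFINED if v is None else round(v, 2)


def ppv(c: ConfusionCounts) -> float | str:
    """Positive predictive value in percent (2 decimals); "–" when TP+FP = 0."""
    return _rounded(_pct(c.tp, c.tp + c.fp))


def sensitivity(c: ConfusionCounts) -> float | str:
    """TP / (TP + FN) in percent (2 decimals); "–" when TP+FN = 0."""
    return _rounded(_pct(c.tp, c.tp + c.fn))


def specificity(c: ConfusionCounts) -> float | str:
    """TN / (TN + FP) in percent (2 decimals); "–" when TN+FP = 0."""
    return _rounded(_pct(c.tn, c.tn + c.fp))


@dataclass
class ValidationSummary:
    """Per-dataset metrics plus their unweighted macro-means, in percent."""

    per_dataset: pd.DataFrame  # columns TP FP TN FN PPV Sensitivity Specificity
    mean_ppv: float | str
    mean_sensitivity: float | str
    mean_specificity: float | str


def summarize(datasets: Sequence[ConfusionCounts]) -> ValidationSummary:
    """Macro-average screening metrics over datasets.

    Each dataset's metrics are computed from its own counts; the means weight
    datasets equally and ignore undefined entries; rounding to two decimals
    happens only after averaging.
    """
    if not datasets:
        raise InsufficientDataError("need at least one dataset to summarize")
    raw = {
        "PPV": [_pct(c.tp, c.tp + c.fp) for c in datasets],
        "Sensitivity": [_pct(c.tp, c.tp + c.fn) for c in datasets],
        "Specificity": [_pct(c.tn, c.tn + c.fp) for c in datasets],
    }

    def mean_defined(vals: list[float | None]) -> float | str:
        defined = [v for v in vals if v is not None]
        if not defined:
            return UNDEFINED
        return round(float(np.mean(defined)), 2)

    table = pd.DataFrame(
        {
            "TP": [c.tp for c in datasets],
            "FP": [c.fp for c in datasets],
            "TN": [c.tn for c in datasets],
            "FN": [c.fn for c in datasets],
            "PPV": [_rounded(v) for v in raw["PPV"]],
            "Sensitivity": [_rounded(v) for v in raw["Sensitivity"]],
            "Specificity": [_rounded(v) for v in raw["Specificity"]],
        }
    )
    return ValidationSummary(
        per_dataset=table,
        mean_ppv=mean_defined(raw["PPV"]),
        mean_sensitivity=mean_defined(raw["Sensitivity"]),
        mean_specificity=mean_defined(raw["Specificity"]),
    )
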