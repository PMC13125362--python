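"""Deployment-oriented evaluation: ROC / PR curves, bootstrap subset
resampling, three-zone triage thresholds and predictive values.

Scores are PD posteriors in [0, 1]; labels use 1 = PD (positive class).
The triage zones follow a screening logic: scores below T_low = 0.30 rule
PD out, scores above T_high = 0.70 rule it in, and the closed interval
[T_low, T_high] is a gray zone referred for further assessment (boundary
points are conservatively assigned to the gray zone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

__all__ = [
    "UndefinedMetricError",
    "ResampleError",
    "ScoredSample",
    "CurveReport",
    "TriageThresholds",
    "BootstrapReport",
    "roc",
    "pr",
    "bootstrap_eval",
    "triage",
    "triage_zones",
    "ppv_npv",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. single-class score set)."""


class ResampleError(RuntimeError):
    """Could not draw a class-covering bootstrap resample."""


@dataclass(frozen=True)
class ScoredSample:
    subject_id: str
    p: float
    label: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.p):
            raise ValueError("score must be finite")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def _as_arrays(samples, scores=None):
    """Accept (labels, scores) arrays or a sequence of ScoredSample."""
    if scores is not None:
        return (np.asarray(samples, dtype=int).reshape(-1),
                np.asarray(scores, dtype=float).reshape(-1))
    samples = list(samples)
    return (np.array([s.label for s in samples], dtype=int),
            np.array([s.p for s in samples], dtype=float))


@dataclass
class CurveReport:
    """Operating points of a threshold sweep plus the area under the curve."""

    x: np.ndarray          # FPR (ROC) or recall (PR)
    y: np.ndarray          # TPR (ROC) or precision (PR)
    thresholds: np.ndarray
    area: float
    kind: str


def roc(samples, scores=None) -> CurveReport:
    """ROC curve and AUC over the sweep of unique score thresholds.

    The AUC equals the probability that a random PD sample outscores a
    random control, counting ties as one half.
    """
    labels, p = _as_arrays(samples, scores)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, p)
    return CurveReport(fpr, tpr, thr, float(roc_auc_score(labels, p)), "roc")


def pr(samples, scores=None) -> CurveReport:
    """Precision-recall curve with step-interpolated area (average
    precision). By sweep convention, the recall = 0 endpoint carries
    precision 1; linear interpolation is deliberately not used because it
    inflates the area."""
    labels, p = _as_arrays(samples, scores)
    if labels.sum() == 0:
        raise UndefinedMetricError("PR needs at least one positive sample")
    precision, recall, thr = precision_recall_curve(labels, p)
    return CurveReport(recall, precision, thr,
                       float(average_precision_score(labels, p)), "pr")


@dataclass(frozen=True)
class TriageThresholds:
    t_low: float = 0.30
    t_high: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 < self.t_low < self.t_high < 1.0:
            raise ValueError("need 0 < T_low < T_high < 1")


def triage(p: float, thresholds: TriageThresholds = TriageThresholds()) -> str:
    """Three-zone triage of one PD posterior: ``rule_out`` below T_low,
    ``rule_in`` above T_high, ``gray`` on the closed interval between."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("posterior must lie in [0, 1]")
    if p < thresholds.t_low:
        return "rule_out"
    if p > thresholds.t_high:
        return "rule_in"
    return "gray"


def triage_zones(scores, thresholds: TriageThresholds = TriageThresholds()):
    """Vectorized triage; returns an array of zone names."""
    return np.array([triage(float(p), thresholds) for p in np.asarray(scores).ravel()])


def ppv_npv(samples, scores=None, threshold: float = 0.5):
    """Positive/negative predictive values after dichotomizing at
    ``threshold`` (positive when p > threshold). Returns
    ``(ppv, npv, counts)``; an empty predicted class yields NaN with the
    metric name recorded in ``counts['undefined']`` rather than an error."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    labels, p = _as_arrays(samples, scores)
    pred = p > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    undefined = []
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    if tp + fp == 0:
        undefined.append("ppv")
    if tn + fn == 0:
        undefined.append("npv")
    counts = {"tp": tp, "fp": fp, "tn": tn, "fn": fn, "undefined": undefined}
    return ppv, npv, counts


@dataclass
class BootstrapReport:
    n_boot: int
    fraction: float
    seed: int
    per_resample: dict               # metric -> array of per-resample values
    summary: dict                    # metric -> (median, q2.5, q97.5)
    with_replacement: bool = False
    redraws: int = 0


_METRIC_FUNCS = {
    "auc": lambda l, s: roc(l, s).area,
    "auprc": lambda l, s: pr(l, s).area,
    "accuracy": lambda l, s: float(np.mean((s > 0.5).astype(int) == l)),
}


def bootstrap_eval(samples, scores=None, fraction: float = 0.7,
                   n_boot: int = 100, seed: int = 0,
                   metrics=("auc", "auprc"),
                   with_replacement: bool = False,
                   max_redraws: int = 100) -> BootstrapReport:
    """Metric stability under subset resampling.

    Draws ``n_boot`` subsets of size ``round(fraction * N)`` (without
    replacement by default, matching a reduced-cohort reading of a "70%
    bootstrap subset"; set ``with_replacement`` for the classical
    bootstrap). Resamples missing a class are redrawn, up to ``max_redraws``
    per resample, and the number of redraws is reported.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    labels, p = _as_arrays(samples, scores)
    n = len(labels)
    size = int(round(fraction * n))
    if size < 2:
        raise ValueError("resample size must be at least 2")
    rng = np.random.default_rng(seed)
    per = {m: [] for m in metrics}
    redraws = 0
    for _ in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.choice(n, size=size, replace=with_replacement)
            if len(np.unique(labels[idx])) == 2:
                break
            redraws += 1
        else:
            raise ResampleError("could not draw a resample with both classes")
        for m in metrics:
            per[m].append(_METRIC_FUNCS[m](labels[idx], p[idx]))
    per = {m: np.asarray(v) for m, v in per.items()}
    summary = {m: (float(np.median(v)), float(np.quantile(v, 0.025)),
                   float(np.quantile(v, 0.975))) for m, v in per.items()}
    return BootstrapReport(n_boot, fraction, seed, per, summary,
                           with_replacement, redraws)
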