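"""Binary-classification metrics, threshold prioritization, and ensemble baselines.

All metrics derive from confusion counts (TP/TN/FP/FN):

    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1   = 2TP / (2TP + FP + FN)
    acc  = (TP+TN) / N
    sens = TP / (TP+FN)        spec = TN / (TN+FP)
    BA   = (sens + spec) / 2
    PPV  = TP / (TP+FP)        NPV  = TN / (TN+FN)

Degenerate denominators return the conventional fallback (MCC 0, PPV/NPV
NaN) with a warning rather than failing. The threshold-prioritization table
tests, at each probability cutoff from 0.1 to 0.9, whether the predicted
call is associated with the true label (Pearson chi-square on the 2x2
table) and reports PPV/NPV — how trustworthy positive and negative calls
are at that cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN tallies of one thresholded prediction run."""

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

    def as_table(self) -> np.ndarray:
        """2x2 contingency table: rows predicted pos/neg, cols actual pos/neg."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass
class MetricsBundle:
    mcc: float
    f1: float
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        """Report-style rounding; full precision is kept on the object."""
        out = {k: round(v, ndigits) for k, v in vars(self).items() if v is not None}
        if self.auc is None:
            out["auc"] = None
        return out


@dataclass
class ThresholdRow:
    threshold: float
    counts: ConfusionCounts
    p_value: float
    ppv: float
    npv: float


def confusion_at_threshold(
    probs: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Tally confusion counts calling ``prob >= threshold`` positive."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError(f"probs and labels misaligned: {probs.shape} vs {labels.shape}")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def compute_metrics(c: ConfusionCounts, auc: float | None = None) -> MetricsBundle:
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    mcc_denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    if mcc_denom == 0.0:
        warnings.warn("MCC denominator is zero; returning 0.0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_denom
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return MetricsBundle(
        mcc=mcc,
        f1=f1,
        accuracy=(tp + tn) / c.total,
        balanced_accuracy=(sens + spec) / 2,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
    )


def ppv_npv(c: ConfusionCounts) -> tuple[float, float]:
    """Positive / negative predictive value; an undefined side is NaN + warning."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    if c.tp + c.fp:
        ppv = c.tp / (c.tp + c.fp)
    else:
        warnings.warn("no positive calls; PPV undefined", stacklevel=2)
        ppv = math.nan
    if c.tn + c.fn:
        npv = c.tn / (c.tn + c.fn)
    else:
        warnings.warn("no negative calls; NPV undefined", stacklevel=2)
        npv = math.nan
    return ppv, npv


def roc_auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """AUC: probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(probs, dtype=float)))


def chi_square_association(c: ConfusionCounts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df=1) on the predicted-vs-actual 2x2 table.

    ``correction=True`` switches on the Yates continuity correction. Returns
    (statistic, p-value); a table with an empty margin has no association to
    test and returns (nan, nan).
    """
    table = c.as_table()
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan, math.nan
    res = chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def threshold_prioritization(
    probs: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] | None = None,
    correction: bool = False,
) -> list[ThresholdRow]:
    """Per-cutoff association table: counts, chi-square p, PPV, NPV.

    Default cutoffs run from 0.1 to 0.9 in steps of 0.1.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.1, 0.95, 0.1), 10)
    rows = []
    for t in thresholds:
        t = float(t)
        if not 0.0 < t < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {t}")
        c = confusion_at_threshold(probs, labels, t)
        _, p = chi_square_association(c, correction=correction)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ppv, npv = ppv_npv(c)
        rows.append(ThresholdRow(threshold=t, counts=c, p_value=p, ppv=ppv, npv=npv))
    return rows


def ensemble_majority_vote(member_calls: np.ndarray) -> np.ndarray:
    """Consensus class per compound from member 0/1 calls (rows = compounds).

    An exact tie goes to the positive class, consistent with the >=0.5
    positive convention.
    """
    calls = np.atleast_2d(np.asarray(member_calls, dtype=float))
    return (calls.mean(axis=1) >= 0.5).astype(int)


def ensemble_average_probability(member_probs: np.ndarray) -> np.ndarray:
    """Consensus call: mean member probability < 0.5 -> negative, else positive."""
    probs = np.atleast_2d(np.asarray(member_probs, dtype=float))
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return (probs.mean(axis=1) >= 0.5).astype(int)
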