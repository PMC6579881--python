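"""Relevance metrics and staining-quality (AOF) metrics.

Two metric families support the pipeline's quality control:

* one-vs-rest relevance metrics (precision, recall, F1, Matthews
  correlation coefficient) for comparing a computational classification
  -- debarcoding codes or cell-subset labels -- against a reference;

* the Average Overlap Frequency (AOF) family for staining quality.
  AOF assumes a marker has a negative and a positive modality and
  scores their overlap in [0, 1]: 0 for complete separation.  Each
  modality is summarized by a fitted normal; the negative events above
  the positive fit's 5th percentile and the positive events below the
  negative fit's 95th percentile are the "overlapping" events:

      AOF = 1/2 ( |X-_h| / |X-|  +  |X+_l| / |X+| )

  Two identical modalities give AOF = Phi(1.645) ~= 0.95, the
  formula's intrinsic ceiling.  Scaled^2 AOF z-scores each marker's
  AOF across samples (negatives floored at 0, then squared), and
  Quality^2 AOF sums Scaled^2 over markers to give one quality score
  per sample.  Splitting the acquisition window into time quartiles
  and tracking per-quartile AOF flags time-dependent background drift
  (e.g. an instrument malfunction raising background over a run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fcs import EventMatrix

__all__ = [
    "ConfusionCounts",
    "confusion",
    "precision",
    "recall",
    "f1",
    "mcc",
    "classification_report",
    "aof",
    "split_modalities",
    "scaled_aof",
    "quality",
    "AofReport",
    "quartile_drift",
]

#: z at the 95th percentile of a standard normal.
_Z95 = float(norm.ppf(0.95))


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(truth, pred, target) -> ConfusionCounts:
    """One-vs-rest confusion counts with ``truth`` as the reference."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    t = truth == target
    p = pred == target
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        FP=int(np.sum(~t & p)),
        TN=int(np.sum(~t & ~p)),
        FN=int(np.sum(t & ~p)),
    )


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 with a warning when nothing was called positive."""
    denom = c.TP + c.FP
    if denom == 0:
        warnings.warn("precision undefined (no predicted positives); returning 0")
        return 0.0
    return c.TP / denom


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 with a warning when there are no true positives."""
    denom = c.TP + c.FN
    if denom == 0:
        warnings.warn("recall undefined (no actual positives); returning 0")
        return 0.0
    return c.TP / denom


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a marginal is empty."""
    denom = (
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return ((c.TP * c.TN) - (c.FP * c.FN)) / np.sqrt(denom)


def classification_report(truth, pred) -> pd.DataFrame:
    """Per-class precision/recall/F1/MCC, one-vs-rest over all truth classes."""
    classes = pd.unique(np.asarray(truth))
    rows = []
    for cls in classes:
        c = confusion(truth, pred, cls)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = precision(c), recall(c)
        rows.append(
            {"class": cls, "n": c.TP + c.FN, "precision": p, "recall": r,
             "f1": f1(p, r), "mcc": mcc(c)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AOF family


def aof(neg_values, pos_values) -> float:
    """Average Overlap Frequency between two modalities, in [0, 1]."""
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both modalities must be non-empty")

    def _fit(v):
        mu = float(np.mean(v))
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return mu, sd

    neg_mu, neg_sd = _fit(neg)
    pos_mu, pos_sd = _fit(pos)
    # 5th percentile of the positive fit / 95th of the negative fit.
    pos_p05 = pos_mu - _Z95 * pos_sd
    neg_p95 = neg_mu + _Z95 * neg_sd
    frac_neg_high = float(np.mean(neg > pos_p05))
    frac_pos_low = float(np.mean(pos < neg_p95))
    return float(np.clip(0.5 * (frac_neg_high + frac_pos_low), 0.0, 1.0))


def _two_means_boundary(values: np.ndarray) -> float:
    """Exact 1-d 2-means: boundary at the midpoint of the two cluster means."""
    v = np.sort(values)
    n = v.size
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    total, total_sq = csum[-1], csq[-1]
    sizes_l = np.arange(1, n)
    sum_l = csum[:-1]
    sq_l = csq[:-1]
    sum_r = total - sum_l
    sq_r = total_sq - sq_l
    sizes_r = n - sizes_l
    ss = (sq_l - sum_l**2 / sizes_l) + (sq_r - sum_r**2 / sizes_r)
    i = int(np.argmin(ss))
    mean_l = sum_l[i] / sizes_l[i]
    mean_r = sum_r[i] / sizes_r[i]
    return 0.5 * (mean_l + mean_r)


def split_modalities(values, method: str = "two_means", threshold: float | None = None,
                     labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Partition marker values into (negative, positive) modalities.

    ``two_means`` finds the exact 1-d 2-means split and cuts at the
    midpoint of the two cluster centers; ``fixed_threshold`` cuts at a
    user-supplied value; ``labeled`` uses a caller-supplied boolean
    positive mask (e.g. membership in expected-positive subsets).
    """
    v = np.asarray(values, dtype=float)
    if method == "two_means":
        if v.size < 2:
            raise ValueError("two_means needs at least two values")
        if np.ptp(v) == 0:
            raise ValueError("values are constant; no modality structure")
        b = _two_means_boundary(v)
        return v[v <= b], v[v > b]
    if method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold requires a threshold")
        return v[v <= threshold], v[v > threshold]
    if method == "labeled":
        if labels is None:
            raise ValueError("labeled split requires a positive mask")
        mask = np.asarray(labels, dtype=bool)
        if mask.shape != v.shape:
            raise ValueError("labels length must match values")
        return v[~mask], v[mask]
    raise ValueError(f"unknown modality split method {method!r}")


def scaled_aof(aof_matrix: pd.DataFrame) -> pd.DataFrame:
    """Scaled^2 AOF: per-marker z-score across samples, floored at 0, squared.

    Rows are markers, columns samples.  A constant row (sd = 0) scales
    to 0; a single-sample matrix scales to all zeros with a warning.
    """
    m = pd.DataFrame(aof_matrix, dtype=float)
    if m.shape[1] < 2:
        warnings.warn("Scaled^2 AOF needs >= 2 samples; returning zeros")
        return m * 0.0
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    z = m.sub(mean, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    return z.clip(lower=0.0) ** 2


def quality(scaled: pd.DataFrame) -> pd.Series:
    """Quality^2 AOF: per-sample sum of Scaled^2 AOF over markers."""
    return pd.DataFrame(scaled).sum(axis=0)


@dataclass
class AofReport:
    """AOF matrix (marker x sample) with its derived quality scores."""

    aof: pd.DataFrame
    scaled: pd.DataFrame
    quality: pd.Series
    modality_meta: pd.DataFrame | None = None

    @classmethod
    def from_aof(cls, aof_matrix: pd.DataFrame, modality_meta=None) -> "AofReport":
        s = scaled_aof(aof_matrix)
        return cls(aof=pd.DataFrame(aof_matrix), scaled=s, quality=quality(s),
                   modality_meta=modality_meta)


def quartile_drift(
    events: EventMatrix,
    marker: str,
    modality_method: str = "two_means",
    drift_threshold: float = 0.1,
    labels=None,
) -> tuple[list[float], bool]:
    """AOF per acquisition-time quartile plus a drift flag.

    Events are split into four equal-count quartiles by acquisition
    time; the flag raises when AOF in the last quartile exceeds the
    first by more than ``drift_threshold``.  Restricting analysis to
    the first quartile recovers pre-drift staining quality.
    """
    if events.acquisition_time is None:
        raise ValueError("events carry no acquisition time")
    order = np.argsort(events.acquisition_time, kind="stable")
    values = events.column(marker)[order]
    mask = None if labels is None else np.asarray(labels, dtype=bool)[order]
    aofs = []
    for idx in np.array_split(np.arange(values.size), 4):
        chunk = values[idx]
        neg, pos = split_modalities(
            chunk, method=modality_method,
            labels=None if mask is None else mask[idx],
        )
        aofs.append(aof(neg, pos))
    flag = (aofs[-1] - aofs[0]) > drift_threshold
    return aofs, bool(flag)
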