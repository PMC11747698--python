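"""Panel performance: assessors against the chemical gold standard.

The "safe box" gold standard declares a carcass tainted when skatole
reaches 0.2 ppm or androstenone reaches 1.5 ppm; an assessor calls a
sample tainted when the ordinal score is >= 2.  Each assessor is scored
by sensitivity, specificity, precision (PPV), NPV and accuracy on the
records where both the chemical pair and the score are observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SKA_THRESHOLD_PPM = 0.2
ANON_THRESHOLD_PPM = 1.5
SENS_CUTOFF = 2


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Diagnostic proportions; NaN marks an undefined (0/0) ratio."""

    sensitivity: float
    specificity: float
    precision: float
    npv: float
    accuracy: float
    ska_threshold: float = SKA_THRESHOLD_PPM
    anon_threshold: float = ANON_THRESHOLD_PPM
    sens_cutoff: int = SENS_CUTOFF


def gold_standard(ska_ppm, anon_ppm, thr_ska: float = SKA_THRESHOLD_PPM,
                  thr_anon: float = ANON_THRESHOLD_PPM) -> np.ndarray:
    """Binary taint label: 1 if either compound reaches its threshold.

    Missing concentrations propagate as NaN so the record can be
    excluded, never silently treated as untainted.
    """
    ska = np.asarray(ska_ppm, dtype=float)
    anon = np.asarray(anon_ppm, dtype=float)
    if np.any(ska[~np.isnan(ska)] < 0) or np.any(anon[~np.isnan(anon)] < 0):
        raise ValueError("concentrations must be non-negative")
    out = ((ska >= thr_ska) | (anon >= thr_anon)).astype(float)
    out[np.isnan(ska) | np.isnan(anon)] = np.nan
    return out


def sensory_positive(score, cutoff: int = SENS_CUTOFF) -> np.ndarray:
    """Binary test label from an ordinal score: 1 iff score >= cutoff."""
    arr = np.asarray(score, dtype=float)
    out = (arr >= cutoff).astype(float)
    out[np.isnan(arr)] = np.nan
    return out


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def confusion_and_metrics(gold, test, **thresholds
                          ) -> tuple[ConfusionCounts, PerformanceMetrics]:
    """Confusion counts and diagnostic metrics on jointly observed pairs."""
    g = np.asarray(gold, dtype=float).ravel()
    t = np.asarray(test, dtype=float).ravel()
    if g.size != t.size:
        raise ValueError("gold and test vectors differ in length")
    both = ~(np.isnan(g) | np.isnan(t))
    g, t = g[both].astype(bool), t[both].astype(bool)
    counts = ConfusionCounts(
        tp=int(np.sum(g & t)), fp=int(np.sum(~g & t)),
        tn=int(np.sum(~g & ~t)), fn=int(np.sum(g & ~t)))
    metrics = PerformanceMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.fp + counts.tn),
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.fn + counts.tn),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        **thresholds)
    return counts, metrics


def panel_performance(df: pd.DataFrame, assessor_columns: list[str],
                      thr_ska: float = SKA_THRESHOLD_PPM,
                      thr_anon: float = ANON_THRESHOLD_PPM,
                      cutoff: int = SENS_CUTOFF) -> pd.DataFrame:
    """Per-assessor diagnostics table for a phenotype frame."""
    gold = gold_standard(df["ska_ppm"], df["anon_ppm"], thr_ska, thr_anon)
    rows = []
    for col in assessor_columns:
        test = sensory_positive(df[col].to_numpy(), cutoff)
        counts, met = confusion_and_metrics(
            gold, test, ska_threshold=thr_ska, anon_threshold=thr_anon,
            sens_cutoff=cutoff)
        rows.append({
            "assessor": col, "n": counts.total,
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
            "sensitivity": met.sensitivity, "specificity": met.specificity,
            "precision": met.precision, "npv": met.npv,
            "accuracy": met.accuracy})
    return pd.DataFrame(rows)
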