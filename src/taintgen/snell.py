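"""Snell scaling of ordinal sensory scores.

Each trained assessor uses the 0-5 scale differently, so the ordinal
scores are replaced per assessor by continuous values on an underlying
normal (liability) scale.  For the four bounded classes the value is the
average of the standard-normal quantiles of the cumulative frequencies at
the class boundaries; the two extreme (open) classes are offset outward
from their single boundary by -ln(F)/(1-F), where F is the cumulative
frequency at that boundary.  This is the classical z-score approximation
to Snell scoring; no post-hoc standardization is applied.

An empty interior class collapses onto its shared boundary quantile; an
empty extreme class receives the (unused, but finite) open-class value at
the nearest informative boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

N_CLASSES = 6


class DegenerateScaleError(ValueError):
    """All observations fall in a single extreme class; no scale exists."""


class EmptyDistributionError(ValueError):
    """No non-missing scores to tally."""


@dataclass(frozen=True)
class ScoreDistribution:
    """Per-assessor score-class frequencies for classes 0-5."""

    assessor_id: str
    counts: np.ndarray | None
    n: int
    frequencies: np.ndarray

    def __post_init__(self):
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.shape != (N_CLASSES,):
            raise ValueError("frequencies must have 6 entries (classes 0-5)")
        if np.any(freq < 0):
            raise ValueError("negative class frequency")
        if abs(freq.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "frequencies", freq)

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative frequencies at the 5 interior class boundaries."""
        return np.cumsum(self.frequencies)[:5]

    @classmethod
    def from_frequencies(cls, frequencies, assessor_id: str = "",
                         n: int = 0) -> "ScoreDistribution":
        """Build from (possibly printed/rounded) class frequencies."""
        freq = np.asarray(frequencies, dtype=float)
        total = freq.sum()
        if total <= 0:
            raise EmptyDistributionError("frequencies sum to zero")
        return cls(assessor_id, None, n, freq / total)


@dataclass(frozen=True)
class SnellScale:
    """Continuous Snell values for score classes 0-5 of one assessor."""

    assessor_id: str
    class_values: np.ndarray
    mean: float
    sd: float


def class_frequencies(scores, assessor_id: str = "") -> ScoreDistribution:
    """Tally non-missing ordinal scores (0-5) into a ScoreDistribution."""
    arr = np.asarray(scores, dtype=float).ravel()
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise EmptyDistributionError(
            f"assessor {assessor_id!r}: no non-missing scores")
    if np.any((obs < 0) | (obs > 5) | (obs != np.round(obs))):
        raise ValueError("scores must be integers in 0..5 (or missing)")
    counts = np.bincount(obs.astype(np.int64), minlength=N_CLASSES)
    n = int(counts.sum())
    return ScoreDistribution(assessor_id, counts, n, counts / n)


def _open_class_offset(F: float) -> float:
    """Outward offset -ln(F)/(1-F) for an extreme (open) class."""
    return -np.log(F) / (1.0 - F)


def snell_scale(dist: ScoreDistribution) -> SnellScale:
    """Compute the 6 continuous class values from a score distribution."""
    freq = dist.frequencies
    occupied = np.flatnonzero(freq > 0)
    if occupied.size < 2:
        raise DegenerateScaleError(
            f"assessor {dist.assessor_id!r}: all mass in one class")
    cum = dist.cumulative
    # boundary b (=1..5) separates class b-1 from class b; informative
    # boundaries are those with 0 < F < 1
    valid = (cum > 0.0) & (cum < 1.0)
    if not valid.any():
        raise DegenerateScaleError(
            f"assessor {dist.assessor_id!r}: no informative class boundary")
    z = np.full(5, np.nan)
    z[valid] = norm.ppf(cum[valid])
    first = int(np.flatnonzero(valid)[0])
    last = int(np.flatnonzero(valid)[-1])

    values = np.empty(N_CLASSES)
    lower_open = z[first] - _open_class_offset(cum[first])
    upper_open = z[last] + _open_class_offset(cum[last])
    for c in range(N_CLASSES):
        if c <= first:          # class 0, plus any leading empty classes
            values[c] = lower_open if c == 0 else np.nan
        if c >= last + 1:       # class 5, plus any trailing empty classes
            values[c] = upper_open if c == N_CLASSES - 1 else np.nan
    for c in range(1, N_CLASSES - 1):
        lo, hi = c - 1, c       # boundary indices (0-based into cum/z)
        zs = [z[b] for b in (lo, hi) if valid[b]]
        if zs:
            values[c] = float(np.mean(zs))
    # any interior class outside the occupied range shares the open value
    for c in range(1, N_CLASSES - 1):
        if np.isnan(values[c]):
            values[c] = lower_open if c <= first else upper_open
    if np.isnan(values[0]):
        values[0] = lower_open
    if np.isnan(values[-1]):
        values[-1] = upper_open

    mean = float(np.sum(freq * values))
    sd = float(np.sqrt(np.sum(freq * (values - mean) ** 2)))
    return SnellScale(dist.assessor_id, values, mean, sd)


def transform_scores(scores, scale: SnellScale) -> np.ndarray:
    """Replace ordinal scores by their Snell class values (missing stays)."""
    arr = np.asarray(scores, dtype=float).ravel()
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    vals = arr[obs]
    if np.any((vals < 0) | (vals > 5) | (vals != np.round(vals))):
        raise ValueError("scores must be integers in 0..5 (or missing)")
    out[obs] = scale.class_values[vals.astype(np.int64)]
    return out


def snell_transform_frame(df, assessor_columns: list[str],
                          prefix: str = "SENSt_"):
    """Snell-transform every assessor column of a phenotype table.

    Returns ``(transformed_df, scales)`` where the transformed frame has a
    ``SENSt_<i>`` column per input ``sens_<i>`` column, and ``scales`` maps
    assessor column -> SnellScale.  Each scale is computed on that
    assessor's own non-missing records.
    """
    import pandas as pd

    out = {}
    scales = {}
    for col in assessor_columns:
        dist = class_frequencies(df[col].to_numpy(), assessor_id=col)
        scale = snell_scale(dist)
        ident = col.split("_")[-1] if "_" in col else col
        out[f"{prefix}{ident}"] = transform_scores(df[col].to_numpy(), scale)
        scales[col] = scale
    return pd.DataFrame(out, index=df.index), scales
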