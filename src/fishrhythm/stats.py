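"""Inter-onset-interval statistics: nPVI, coefficient of variation, histograms.

The inter-onset interval (IOI) is the time from one element's onset to the
next element's onset — element duration plus the following gap. All rhythm
statistics in this package operate on IOIs:

* **nPVI** (normalized pairwise variability index)::

      nPVI = 100/(m-1) * sum_{k=1}^{m-1} |d_k - d_{k+1}| / ((d_k + d_{k+1})/2)

  for m IOIs d_1..d_m. It is 0 for a perfectly isochronous sequence and
  approaches 200 for extreme alternation; it is invariant under uniform
  time rescaling. A value below 30 is a strong indicator of an underlying
  isochronous pattern, while high values are inconclusive (a long jittered
  but fundamentally isochronous sequence can score high).

* **C_V** — the coefficient of variation, sd(IOIs)/mean(IOIs). The sample
  standard deviation (m-1 denominator) is used by default; with the small
  IOI counts typical of field sequences the choice is material, and the
  sample form is the conservative one. Set ``ddof=0`` for the population
  variant.

* **Sturges histograms** of IOIs pooled across all sequences of one sound
  type, with ``k = ceil(log2(n)) + 1`` equal-width bins spanning the pooled
  range; the distribution shape (unimodal / bimodal / broad) is the first
  qualitative cue for isochrony, induced isochrony or arrhythmia.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import SoundSequence

#: nPVI below this value strongly indicates an underlying isochronous
#: pattern; values at or above it are inconclusive (never "not isochronous").
NPVI_ISOCHRONY_BOUND = 30.0


@dataclass
class IOISequence:
    """Ordered positive inter-onset intervals of one sequence, in seconds."""

    iois: np.ndarray
    sequence_id: str = "seq"

    def __post_init__(self) -> None:
        self.iois = np.asarray(self.iois, dtype=float)
        if self.iois.ndim != 1:
            raise ValidationError("iois must be one-dimensional")
        if len(self.iois) and (not np.all(np.isfinite(self.iois)) or np.any(self.iois <= 0)):
            raise ValidationError(f"sequence {self.sequence_id!r}: all IOIs must be finite and > 0")

    def __len__(self) -> int:
        return len(self.iois)

    @property
    def n_elements(self) -> int:
        return len(self.iois) + 1


@dataclass
class IOIHistogram:
    """Sturges-binned histogram of pooled IOIs (counts and percentages)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    pool_label: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def as_percent(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total * 100.0 if total else np.zeros_like(self.counts, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: bin_left, bin_right, count, percent."""
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "percent": self.as_percent,
            }
        )


class IsochronyIndicator(str, enum.Enum):
    """Interpretation of an nPVI value against the isochrony bound.

    The reading is asymmetric: a low nPVI strongly indicates isochrony,
    but a high nPVI never rules it out.
    """

    STRONG_ISOCHRONY_INDICATOR = "strong_isochrony_indicator"
    INCONCLUSIVE = "inconclusive"


def compute_iois(sequence: SoundSequence) -> IOISequence:
    """Extract the IOI sequence (consecutive onset differences) of *sequence*."""
    if len(sequence) < 2:
        raise InsufficientDataError(
            f"sequence {sequence.sequence_id!r} has {len(sequence)} element(s); "
            "need at least 2 to form an IOI"
        )
    return IOISequence(iois=np.diff(sequence.onsets), sequence_id=sequence.sequence_id)


def _check_iois(iois: IOISequence | np.ndarray, minimum: int, what: str) -> np.ndarray:
    d = iois.iois if isinstance(iois, IOISequence) else np.asarray(iois, dtype=float)
    if len(d) < minimum:
        raise InsufficientDataError(f"{what} requires at least {minimum} IOIs, got {len(d)}")
    if np.any(d <= 0):
        raise ValidationError(f"{what}: all IOIs must be positive")
    return d


def npvi(iois: IOISequence | np.ndarray) -> float:
    """Normalized pairwise variability index of a set of IOIs.

    Zero iff all IOIs are equal; invariant under uniform rescaling of time;
    bounded in [0, 200) for positive IOIs.
    """
    d = _check_iois(iois, 2, "nPVI")
    pair_means = (d[:-1] + d[1:]) / 2.0
    return float(100.0 * np.mean(np.abs(np.diff(d)) / pair_means))


def coefficient_of_variation(iois: IOISequence | np.ndarray, ddof: int = 1) -> float:
    """C_V = sd(IOIs) / mean(IOIs), sample standard deviation by default."""
    d = _check_iois(iois, 2, "coefficient of variation")
    return float(np.std(d, ddof=ddof) / np.mean(d))


def sturges_bin_count(n: int) -> int:
    """Number of histogram bins by Sturges' rule: ceil(log2(n)) + 1."""
    if n < 1:
        raise InsufficientDataError("Sturges' rule needs at least one observation")
    return math.ceil(math.log2(n)) + 1


def sturges_histogram(pooled_iois, pool_label: str = "") -> IOIHistogram:
    """Histogram of IOIs pooled across sequences, binned by Sturges' rule.

    Bins are equal-width over [min, max] of the pooled IOIs. When all IOIs
    are identical the range is degenerate; a single bin of machine-epsilon
    nominal width then holds every observation so the count-conservation
    invariant still holds.
    """
    d = np.asarray(
        pooled_iois.iois if isinstance(pooled_iois, IOISequence) else pooled_iois, dtype=float
    )
    if len(d) == 0:
        raise InsufficientDataError("histogram requires at least one IOI")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValidationError("histogram: all IOIs must be finite and positive")
    k = sturges_bin_count(len(d))
    lo, hi = float(d.min()), float(d.max())
    if hi == lo:  # degenerate zero range: one nominal-width bin
        width = np.spacing(max(abs(lo), 1.0))
        edges = np.array([lo, lo + width])
        counts = np.array([len(d)])
    else:
        counts, edges = np.histogram(d, bins=k, range=(lo, hi))
    return IOIHistogram(bin_edges=edges, counts=counts, pool_label=pool_label)


def isochrony_indicator(npvi_value: float) -> IsochronyIndicator:
    """Map an nPVI value to the strong-isochrony indicator (strict < 30)."""
    if npvi_value < 0:
        raise ValidationError(f"nPVI cannot be negative, got {npvi_value}")
    if npvi_value < NPVI_ISOCHRONY_BOUND:
        return IsochronyIndicator.STRONG_ISOCHRONY_INDICATOR
    return IsochronyIndicator.INCONCLUSIVE


def pool_iois(sequences: list[SoundSequence]) -> np.ndarray:
    """Concatenate IOIs of all analysable sequences (≥3 elements) in a pool."""
    pools = [
        compute_iois(s).iois for s in sequences if s.meets_analysis_minimum
    ]
    if not pools:
        raise InsufficientDataError("no sequence in the pool meets the 3-element minimum")
    return np.concatenate(pools)
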