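"""Recurrence matrices of inter-onset intervals.

A recurrence plot visualizes the pairwise distances between all IOIs of a
sequence: a square matrix of side n_IOIs, mirrored on the diagonal, with
``D[i, j] = |ioi_i - ioi_j|`` (the Euclidean metric between scalar IOIs).
An isochronous sequence gives a uniformly near-zero matrix; alternating
short/long IOIs give a checkerboard; arrhythmic sequences give large,
unstructured distances. Colour scaling is per sequence — the normalized
matrix rescales distances to [0, 1] within each sequence and must never be
shared across sequences — so the *raw* maximum distance is the quantity to
compare between sequences or species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .stats import IOISequence


@dataclass
class RecurrenceMatrix:
    """Pairwise |IOI_i - IOI_j| distances (seconds) with per-sequence scaling."""

    distances: np.ndarray
    sequence_id: str = "seq"

    @property
    def n_iois(self) -> int:
        return self.distances.shape[0]

    @property
    def normalized(self) -> np.ndarray:
        """Distances rescaled to [0, 1]; an all-zero matrix stays all-zero."""
        m = self.distances.max()
        return self.distances / m if m > 0 else np.zeros_like(self.distances)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances)


def recurrence_matrix(iois: IOISequence | np.ndarray) -> RecurrenceMatrix:
    """Build the IOI distance matrix of one sequence (symmetric, zero diagonal)."""
    seq_id = iois.sequence_id if isinstance(iois, IOISequence) else "seq"
    d = iois.iois if isinstance(iois, IOISequence) else np.asarray(iois, dtype=float)
    if len(d) < 2:
        raise InsufficientDataError(f"recurrence matrix requires at least 2 IOIs, got {len(d)}")
    if np.any(d <= 0):
        raise ValidationError("recurrence matrix: all IOIs must be positive")
    distances = np.abs(d[:, None] - d[None, :])
    return RecurrenceMatrix(distances=distances, sequence_id=seq_id)


def max_distance(matrix: RecurrenceMatrix) -> float:
    """Maximum raw IOI distance (seconds) — the cross-sequence scale comparator."""
    return float(matrix.distances.max())
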