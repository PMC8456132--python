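"""Reading and writing element annotations and result tables.

Annotations give onset/offset times (seconds) of discrete sound elements.
Two dialects are supported:

* ``raven`` — Raven Pro selection tables: tab-delimited with a header row
  containing at least "Begin Time (s)" and "End Time (s)" columns (the
  "(s)" suffix and letter case vary between Raven versions and are both
  accepted). Raven writes one row per channel for the same selection, so
  rows are de-duplicated on the (begin, end) pair.
* ``csv`` — a plain comma-separated dialect with columns ``onset_s``,
  ``offset_s`` and optional ``label`` and ``sequence_id``.

No audio is read anywhere in this package; times are seconds from the
start of the annotated file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ParseError, ValidationError

#: Sequences need at least this many elements before rhythm statistics are
#: meaningful (one IOI pair); shorter runs are kept but flagged.
MIN_ELEMENTS_FOR_ANALYSIS = 3

#: Decimal places used for the de-duplication key on (begin, end) pairs.
_DEDUP_DECIMALS = 6


@dataclass(frozen=True)
class Element:
    """One annotated sound, bounded by silence, with onset/offset in seconds."""

    onset: float
    offset: float
    label: str | None = None
    source_file: str | None = None
    sequence_tag: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.onset) and math.isfinite(self.offset)):
            raise ValidationError(f"element times must be finite, got ({self.onset}, {self.offset})")
        if self.onset < 0:
            raise ValidationError(f"element onset must be non-negative, got {self.onset}")
        if self.offset <= self.onset:
            raise ValidationError(
                f"element offset must exceed onset, got onset={self.onset}, offset={self.offset}"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SoundSequence:
    """An ordered run of elements attributed to one individual.

    Elements must be strictly ordered by onset and non-overlapping
    (``offset_i <= onset_{i+1}``). The three-element analysis minimum is
    *not* enforced here so that partial sequences remain inspectable; use
    :attr:`meets_analysis_minimum` or let the stats layer raise.
    """

    elements: list[Element]
    sequence_id: str = "seq"
    species_tag: str | None = None

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.elements]
        for i in range(len(onsets) - 1):
            if onsets[i + 1] <= onsets[i]:
                raise ValidationError(
                    f"sequence {self.sequence_id!r}: elements {i} and {i + 1} are not "
                    f"strictly ordered by onset ({onsets[i]} vs {onsets[i + 1]})"
                )
            if self.elements[i].offset > onsets[i + 1]:
                raise ValidationError(
                    f"sequence {self.sequence_id!r}: element {i} (offset "
                    f"{self.elements[i].offset}) overlaps element {i + 1} "
                    f"(onset {onsets[i + 1]})"
                )

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.elements], dtype=float)

    @property
    def duration(self) -> float:
        """Span from first onset to last offset, seconds (0 when empty)."""
        if not self.elements:
            return 0.0
        return self.elements[-1].offset - self.elements[0].onset

    @property
    def meets_analysis_minimum(self) -> bool:
        return len(self.elements) >= MIN_ELEMENTS_FOR_ANALYSIS


def _find_column(columns: Iterable[str], key: str) -> str | None:
    """Case-insensitive lookup of a column whose name contains *key*."""
    for col in columns:
        if key.lower() in str(col).lower():
            return str(col)
    return None


def _parse_time(value, row: int, column: str) -> float:
    try:
        t = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric value {value!r} in column {column!r}") from None
    if not math.isfinite(t):
        raise ParseError(f"row {row}: non-finite value {value!r} in column {column!r}")
    if t < 0:
        raise ParseError(f"row {row}: negative time {t} in column {column!r}")
    return t


def read_selection_table(path: str | Path, dialect: str = "raven") -> list[Element]:
    """Read element annotations from *path*.

    Parameters
    ----------
    path
        Annotation file.
    dialect
        ``"raven"`` for a Raven Pro selection table (tab-delimited),
        ``"csv"`` for the plain comma-separated dialect.

    Returns
    -------
    list of Element, sorted by onset, de-duplicated on (begin, end) pairs
    rounded to 6 decimals (Raven duplicates selections per channel).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "raven":
        frame = pd.read_csv(path, sep="\t")
        begin_col = _find_column(frame.columns, "begin time")
        end_col = _find_column(frame.columns, "end time")
        label_col = _find_column(frame.columns, "annotation")
        missing = []
        if begin_col is None:
            missing.append("Begin Time (s)")
        if end_col is None:
            missing.append("End Time (s)")
        if missing:
            raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
        tag_col = None
    elif dialect == "csv":
        frame = pd.read_csv(path)
        begin_col, end_col = "onset_s", "offset_s"
        for col in (begin_col, end_col):
            if col not in frame.columns:
                raise FormatError(f"{path.name}: missing required column(s): {col}")
        label_col = "label" if "label" in frame.columns else None
        tag_col = "sequence_id" if "sequence_id" in frame.columns else None
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'raven' or 'csv'")

    elements: list[Element] = []
    seen: set[tuple[float, float]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        record = dict(zip(frame.columns, row))
        onset = _parse_time(record[begin_col], i, begin_col)
        offset = _parse_time(record[end_col], i, end_col)
        if offset <= onset:
            raise ValidationError(
                f"{path.name} row {i}: offset ({offset}) must exceed onset ({onset})"
            )
        key = (round(onset, _DEDUP_DECIMALS), round(offset, _DEDUP_DECIMALS))
        if key in seen:
            continue
        seen.add(key)
        label = record.get(label_col) if label_col else None
        tag = record.get(tag_col) if tag_col else None
        elements.append(
            Element(
                onset=onset,
                offset=offset,
                label=None if label is None or pd.isna(label) else str(label),
                source_file=path.name,
                sequence_tag=None if tag is None or pd.isna(tag) else str(tag),
            )
        )
    elements.sort(key=lambda e: e.onset)
    return elements


def assemble_sequences(
    elements: Sequence[Element],
    gap_threshold: float | None = None,
    sequence_id_prefix: str = "seq",
) -> list[SoundSequence]:
    """Group onset-sorted elements into sequences.

    With ``gap_threshold=None`` (the default) all elements form a single
    sequence — the regime of one sequence per acoustic sample, which needs
    no silence threshold. Otherwise a new sequence starts whenever the
    onset-to-onset gap exceeds *gap_threshold* seconds. Elements carrying
    an explicit ``sequence_tag`` (plain-CSV dialect) are grouped by tag
    first; the gap rule then applies within each tag group.

    Sequences shorter than three elements are returned, not dropped; check
    :attr:`SoundSequence.meets_analysis_minimum`.
    """
    elements = list(elements)
    for i in range(len(elements) - 1):
        if elements[i + 1].onset < elements[i].onset:
            raise ValidationError("elements must be sorted by onset before assembly")
        if elements[i].offset > elements[i + 1].onset:
            raise ValidationError(
                f"elements {i} and {i + 1} overlap "
                f"(offset {elements[i].offset} > onset {elements[i + 1].onset})"
            )

    groups: list[tuple[str | None, list[Element]]] = []
    if any(e.sequence_tag is not None for e in elements):
        order: dict[str | None, list[Element]] = {}
        for e in elements:
            order.setdefault(e.sequence_tag, []).append(e)
        groups = list(order.items())
    elif elements:
        groups = [(None, elements)]

    sequences: list[SoundSequence] = []
    counter = 1
    for tag, group in groups:
        runs: list[list[Element]] = [[group[0]]]
        for prev, cur in zip(group, group[1:]):
            if gap_threshold is not None and cur.onset - prev.onset > gap_threshold:
                runs.append([cur])
            else:
                runs[-1].append(cur)
        for run in runs:
            seq_id = tag if tag is not None and len(runs) == 1 else f"{sequence_id_prefix}{counter:03d}"
            sequences.append(SoundSequence(elements=run, sequence_id=seq_id))
            counter += 1
    return sequences


#: Column order of the summary CSV; one row per analysed sequence.
SUMMARY_COLUMNS = [
    "sequence_id",
    "n_elements",
    "duration_s",
    "npvi",
    "cv",
    "ioi_beat_hz",
    "fft_beat_hz",
    "isochrony_type",
    "isochrony_indicator",
    "warnings",
]


def write_summary(summaries: Sequence, path: str | Path) -> None:
    """Write per-sequence rhythm summaries as CSV.

    Accepts any iterable of objects exposing the ``SUMMARY_COLUMNS`` fields
    (e.g. :class:`fishrhythm.report.RhythmSummary`). Numeric values are
    written with 10 significant digits so a read-back round-trips to that
    precision. Deterministic column order; empty input yields a header-only
    file.
    """
    rows = []
    for s in summaries:
        row = {}
        for col in SUMMARY_COLUMNS:
            value = getattr(s, col, None)
            if col == "warnings" and isinstance(value, (list, tuple)):
                value = ";".join(value)
            row[col] = value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.10g")


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read a summary CSV written by :func:`write_summary`."""
    return pd.read_csv(path)


def require_analysis_minimum(sequence: SoundSequence) -> None:
    """Raise unless *sequence* meets the three-element analysis minimum."""
    if not sequence.meets_analysis_minimum:
        raise InsufficientDataError(
            f"sequence {sequence.sequence_id!r} has {len(sequence)} element(s); "
            f"rhythm analysis requires at least {MIN_ELEMENTS_FOR_ANALYSIS}"
        )
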