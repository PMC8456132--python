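"""Pipeline tying the stages together: per-sequence summaries and pool reports.

One invocation analyses one *pool* — all sequences of a single sound type
— mirroring how rhythm figures are produced per species: IOI histograms
are pooled over all sequences of the pool, while nPVI, C_V, recurrence
matrices and beats are per sequence.

Beats are only computed when a rhythm can plausibly be assumed. The pool's
pooled IOI histogram is first classified (unimodal / bimodal with
near-integer-multiple modes / broad); a broad shape combined with high
variability flags the pool as arrhythmic, in which case best-fitting beats
would be meaningless and are skipped (``force_beats=True`` overrides).
The shape classification is a descriptive heuristic, not a hypothesis
test; its thresholds are exposed in :class:`AnalysisConfig` and every
parameter in effect is logged at INFO so outputs are self-describing.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd
import yaml

from . import beat as beat_mod
from . import io as io_mod
from . import recurrence as rec_mod
from . import stats as stats_mod
from .errors import InsufficientDataError
from .io import SoundSequence
from .stats import IOIHistogram

logger = logging.getLogger("fishrhythm")


class PoolShape(str, enum.Enum):
    """Descriptive shape of a pooled IOI histogram."""

    UNIMODAL = "unimodal"
    MULTIMODAL_MULTIPLE = "multimodal_multiple"
    BROAD = "broad"


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, with the conventions it pins down."""

    dialect: str = "raven"
    gap_threshold_s: float | None = None
    sampling_rate_hz: float = beat_mod.DEFAULT_SAMPLING_RATE_HZ
    window_low_hz: float = beat_mod.DEFAULT_WINDOW_HZ[0]
    window_high_hz: float = beat_mod.DEFAULT_WINDOW_HZ[1]
    freq_resolution_hz: float = beat_mod.DEFAULT_FREQ_RESOLUTION_HZ
    multiple_tolerance: float = beat_mod.DEFAULT_MULTIPLE_TOLERANCE
    cv_ddof: int = 1
    force_beats: bool = False
    #: relative half-width of the window around a mode centre within which
    #: pooled IOIs count as belonging to that mode
    mode_window: float = 0.25
    #: share of pooled IOIs the top mode must hold to read as unimodal
    unimodal_share: float = 0.75
    #: combined share of the top two modes required for a bimodal reading
    bimodal_share: float = 0.75
    #: relative tolerance for the top-two mode centres' near-integer ratio
    mode_ratio_tolerance: float = 0.25

    @property
    def window_hz(self) -> tuple[float, float]:
        return (self.window_low_hz, self.window_high_hz)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a YAML or JSON config file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def log_parameters(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


@dataclass
class RhythmSummary:
    """Per-sequence rhythm parameters; the row format of the summary CSV."""

    sequence_id: str
    n_elements: int
    duration_s: float
    npvi: float | None = None
    cv: float | None = None
    ioi_beat_hz: float | None = None
    fft_beat_hz: float | None = None
    isochrony_type: str = beat_mod.IsochronyType.UNASSESSED.value
    isochrony_indicator: str | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class PoolReport:
    """Pool-level descriptive annotations (aids to interpretation, no tests)."""

    pool_shape: PoolShape
    arrhythmic: bool
    top_mode_center_s: float
    top_mode_percent: float
    second_mode_center_s: float | None
    second_mode_percent: float | None
    mode_ratio: float | None
    mode_ratio_near_integer: bool | None
    npvi_median: float | None
    npvi_range: tuple[float, float] | None
    cv_median: float | None
    ioi_beat_median_hz: float | None
    fft_beat_median_hz: float | None
    note: str = ""

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["pool_shape"] = self.pool_shape.value
        return out


@dataclass
class _PoolModes:
    """Top IOI modes of a pool: refined centres and mass shares."""

    histogram: IOIHistogram
    center1_s: float
    share1: float
    center2_s: float | None = None
    share2: float | None = None
    ratio: float | None = None
    ratio_near_integer: bool | None = None


def _refine_mode(d: np.ndarray, center: float, window: float) -> tuple[float, np.ndarray]:
    """Refine a bin-centre mode estimate to the median of nearby IOIs."""
    sel = np.abs(d - center) <= window * center
    refined = float(np.median(d[sel])) if sel.any() else float(center)
    return refined, np.abs(d - refined) <= window * refined


def _find_pool_modes(pooled: np.ndarray, config: AnalysisConfig) -> _PoolModes:
    d = np.asarray(pooled, dtype=float)
    histogram = stats_mod.sturges_histogram(d, pool_label="pool")
    centers = histogram.bin_centers
    counts = histogram.counts
    top = int(np.argmax(counts))
    c1, sel1 = _refine_mode(d, float(centers[top]), config.mode_window)
    modes = _PoolModes(histogram=histogram, center1_s=c1, share1=float(sel1.mean()))
    # second mode: the best bin whose centre lies outside the first window
    outside = np.abs(centers - c1) > config.mode_window * c1
    if outside.any() and counts[outside].max() > 0:
        second = int(np.flatnonzero(outside)[np.argmax(counts[outside])])
        c2, sel2 = _refine_mode(d, float(centers[second]), config.mode_window)
        modes.center2_s = c2
        modes.share2 = float((sel2 & ~sel1).mean())
        ratio = max(c1, c2) / min(c1, c2)
        nearest = float(np.rint(ratio))
        modes.ratio = float(ratio)
        modes.ratio_near_integer = bool(
            nearest >= 1 and abs(ratio - nearest) <= config.mode_ratio_tolerance * nearest
        )
    return modes


def classify_pool_shape(
    pooled_iois: np.ndarray, config: AnalysisConfig | None = None
) -> PoolShape:
    """Descriptive shape of a pool's IOI distribution.

    Unimodal: a single mode (refined from the top Sturges bin) holds at
    least ``unimodal_share`` of pooled IOIs within a relative window.
    Multimodal-with-multiples: two separated modes jointly hold at least
    ``bimodal_share`` and their centres sit at a near-integer ratio ≥ 2 —
    the signature of silent-beat (induced) isochrony. Anything else is
    broad, the arrhythmic signature. Descriptive heuristic, not a test.
    """
    config = config or AnalysisConfig()
    modes = _find_pool_modes(np.asarray(pooled_iois, dtype=float), config)
    if modes.share1 >= config.unimodal_share:
        return PoolShape.UNIMODAL
    if (
        modes.center2_s is not None
        and modes.share1 + modes.share2 >= config.bimodal_share
        and modes.ratio is not None
        and np.rint(modes.ratio) >= 2
        and modes.ratio_near_integer
    ):
        return PoolShape.MULTIMODAL_MULTIPLE
    return PoolShape.BROAD


def analyze_sequences(
    sequences: TypingSequence[SoundSequence], config: AnalysisConfig | None = None
) -> tuple[list[RhythmSummary], IOIHistogram | None, PoolReport | None, dict]:
    """Run the full per-pool pipeline on assembled sequences.

    Returns (summaries, pooled histogram, pool report, artifacts). The
    artifacts dict maps sequence_id to its recurrence matrix and beat
    estimate for downstream export/plotting. Sequences below the
    three-element minimum appear in the summaries with statistics withheld
    and a warning.
    """
    config = config or AnalysisConfig()
    config.log_parameters()
    summaries: list[RhythmSummary] = []
    artifacts: dict = {"recurrence": {}, "beats": {}}
    analysable = [s for s in sequences if s.meets_analysis_minimum]

    histogram: IOIHistogram | None = None
    report: PoolReport | None = None
    pooled: np.ndarray | None = None
    arrhythmic = False
    if analysable:
        pooled = stats_mod.pool_iois(list(analysable))
        histogram = stats_mod.sturges_histogram(pooled, pool_label="pool")
        shape = classify_pool_shape(pooled, config)
        arrhythmic = shape is PoolShape.BROAD
        if arrhythmic and not config.force_beats:
            logger.info(
                "pool histogram is broad (no dominant or multiple-related modes): "
                "flagged arrhythmic, skipping best-fitting beats (use force_beats to override)"
            )

    for seq in sequences:
        summary = RhythmSummary(
            sequence_id=seq.sequence_id,
            n_elements=len(seq),
            duration_s=seq.duration,
        )
        if not seq.meets_analysis_minimum:
            summary.warnings.append("below_analysis_minimum")
            summaries.append(summary)
            continue
        iois = stats_mod.compute_iois(seq)
        summary.npvi = stats_mod.npvi(iois)
        summary.cv = stats_mod.coefficient_of_variation(iois, ddof=config.cv_ddof)
        summary.isochrony_indicator = stats_mod.isochrony_indicator(summary.npvi).value
        artifacts["recurrence"][seq.sequence_id] = rec_mod.recurrence_matrix(iois)
        if arrhythmic and not config.force_beats:
            summary.warnings.append("beats_skipped_arrhythmic_pool")
        else:
            estimate = beat_mod.estimate_beat(
                seq,
                sampling_rate=config.sampling_rate_hz,
                window_hz=config.window_hz,
                freq_resolution_hz=config.freq_resolution_hz,
                multiple_tolerance=config.multiple_tolerance,
            )
            summary.ioi_beat_hz = estimate.ioi_beat_hz
            summary.fft_beat_hz = estimate.fft_beat_hz
            summary.isochrony_type = estimate.isochrony_type.value
            summary.warnings.extend(estimate.warnings)
            artifacts["beats"][seq.sequence_id] = estimate
        summaries.append(summary)

    if pooled is not None:
        report = pool_report(summaries, pooled, config)
    return summaries, histogram, report, artifacts


def pool_report(
    summaries: TypingSequence[RhythmSummary],
    pooled_iois: np.ndarray,
    config: AnalysisConfig | None = None,
) -> PoolReport:
    """Descriptive pool-level annotations from computed summaries.

    Reports the top IOI modes and whether their centres sit at a
    near-integer ratio, plus medians/ranges of nPVI, C_V and both beats.
    These are explicitly descriptive aids, not hypothesis tests.
    """
    config = config or AnalysisConfig()
    if not summaries:
        raise InsufficientDataError("pool report requires at least one analysed sequence")
    pooled = np.asarray(pooled_iois, dtype=float)
    shape = classify_pool_shape(pooled, config)
    modes = _find_pool_modes(pooled, config)

    npvis = [s.npvi for s in summaries if s.npvi is not None]
    cvs = [s.cv for s in summaries if s.cv is not None]
    ioi_beats = [s.ioi_beat_hz for s in summaries if s.ioi_beat_hz is not None]
    fft_beats = [s.fft_beat_hz for s in summaries if s.fft_beat_hz is not None]

    notes = {
        PoolShape.UNIMODAL: "single dominant IOI mode: consistent with an isochronous pattern",
        PoolShape.MULTIMODAL_MULTIPLE: (
            "top IOI modes at a near-integer ratio: consistent with induced isochrony (silent beats)"
        ),
        PoolShape.BROAD: "no dominant IOI mode / broad range: no rhythm assumed, beats withheld",
    }
    return PoolReport(
        pool_shape=shape,
        arrhythmic=shape is PoolShape.BROAD,
        top_mode_center_s=modes.center1_s,
        top_mode_percent=modes.share1 * 100.0,
        second_mode_center_s=modes.center2_s,
        second_mode_percent=None if modes.share2 is None else modes.share2 * 100.0,
        mode_ratio=modes.ratio,
        mode_ratio_near_integer=modes.ratio_near_integer,
        npvi_median=float(np.median(npvis)) if npvis else None,
        npvi_range=(float(np.min(npvis)), float(np.max(npvis))) if npvis else None,
        cv_median=float(np.median(cvs)) if cvs else None,
        ioi_beat_median_hz=float(np.median(ioi_beats)) if ioi_beats else None,
        fft_beat_median_hz=float(np.median(fft_beats)) if fft_beats else None,
        note=notes[shape] + " (descriptive annotation, not a hypothesis test)",
    )


def analyze_files(
    paths: TypingSequence[str | Path],
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
    make_plots: bool = False,
) -> tuple[list[RhythmSummary], IOIHistogram | None, PoolReport | None]:
    """Read annotation files, run the pipeline, optionally write artifacts.

    All files of one invocation form one pool (one sound type), but each
    file is one acoustic sample with its own time axis: elements are
    assembled into sequences per file (usually one sequence per sample;
    the gap threshold can split within a file), never across files.
    Artifacts written to *outdir*: ``summary.csv``, ``histogram.csv``,
    ``recurrence_<id>.csv``, ``spectrum_<id>.csv``, ``report.json`` and,
    with ``make_plots=True``, the four-panel figure set.
    """
    config = config or AnalysisConfig()
    sequences: list[SoundSequence] = []
    for path in paths:
        elements = io_mod.read_selection_table(path, dialect=config.dialect)
        stem = Path(path).name.split(".")[0]
        assembled = io_mod.assemble_sequences(
            elements, gap_threshold=config.gap_threshold_s, sequence_id_prefix=f"{stem}_"
        )
        if len(assembled) == 1 and assembled[0].elements[0].sequence_tag is None:
            assembled[0].sequence_id = stem
        sequences.extend(assembled)
    summaries, histogram, report, artifacts = analyze_sequences(sequences, config)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io_mod.write_summary(summaries, outdir / "summary.csv")
        if histogram is not None:
            histogram.to_frame().to_csv(outdir / "histogram.csv", index=False, float_format="%.10g")
        for seq_id, matrix in artifacts["recurrence"].items():
            matrix.to_frame().to_csv(
                outdir / f"recurrence_{seq_id}.csv", index=False, float_format="%.10g"
            )
        for seq_id, estimate in artifacts["beats"].items():
            pd.DataFrame(estimate.fft_spectrum, columns=["frequency_hz", "magnitude"]).to_csv(
                outdir / f"spectrum_{seq_id}.csv", index=False, float_format="%.10g"
            )
        if report is not None:
            (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        if make_plots:
            from . import plots

            plots.figure_panels(summaries, histogram, artifacts, outdir)
    return summaries, histogram, report
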