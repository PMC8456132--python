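"""Optional figure panels: histogram, recurrence plot, variation, beat scatter.

Numeric CSVs are the pipeline's contract; these figures are convenience
views mirroring the standard four-panel layout of rhythm reports.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .recurrence import RecurrenceMatrix
from .stats import IOIHistogram


def plot_histogram(histogram: IOIHistogram, ax=None):
    """Pooled IOI histogram with percentages on the y-axis."""
    ax = ax or plt.gca()
    widths = np.diff(histogram.bin_edges)
    ax.bar(histogram.bin_edges[:-1], histogram.as_percent, width=widths, align="edge",
           edgecolor="black", color="steelblue")
    ax.set_xlabel("IOI (s)")
    ax.set_ylabel("% of pooled IOIs")
    return ax


def plot_recurrence(matrix: RecurrenceMatrix, ax=None):
    """Per-sequence normalized recurrence plot: 0 -> white, 1 -> black."""
    ax = ax or plt.gca()
    im = ax.imshow(matrix.normalized, cmap="gray_r", vmin=0.0, vmax=1.0, origin="lower")
    ax.set_xlabel("IOI index")
    ax.set_ylabel("IOI index")
    ax.figure.colorbar(im, ax=ax, label="normalized IOI distance")
    return ax


def plot_variation(summaries, ax=None):
    """Per-sequence nPVI and C_V on a log y-axis."""
    ax = ax or plt.gca()
    xs = np.arange(len(summaries))
    npvis = [s.npvi for s in summaries]
    cvs = [s.cv for s in summaries]
    ax.scatter(xs, npvis, marker="o", label="nPVI")
    ax.scatter(xs, cvs, marker="s", label="C_V")
    ax.set_yscale("log")
    ax.set_xlabel("sequence")
    ax.set_ylabel("value (log scale)")
    ax.legend()
    return ax


def plot_beats(summaries, ax=None):
    """Best-fitting beats by method, per sequence."""
    ax = ax or plt.gca()
    xs = np.arange(len(summaries))
    ax.scatter(xs, [s.ioi_beat_hz for s in summaries], marker="o", label="IOI beat")
    ax.scatter(xs, [s.fft_beat_hz for s in summaries], marker="^", label="FFT beat")
    ax.set_xlabel("sequence")
    ax.set_ylabel("beat (Hz)")
    ax.legend()
    return ax


def figure_panels(summaries, histogram, artifacts, outdir: str | Path) -> list[Path]:
    """Write the standard panels as PNGs into *outdir*; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    analysed = [s for s in summaries if s.npvi is not None]

    if histogram is not None:
        fig, ax = plt.subplots()
        plot_histogram(histogram, ax)
        path = outdir / "panel_histogram.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if artifacts["recurrence"]:
        seq_id, matrix = next(iter(artifacts["recurrence"].items()))
        fig, ax = plt.subplots()
        plot_recurrence(matrix, ax)
        ax.set_title(seq_id)
        path = outdir / "panel_recurrence.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    if analysed:
        fig, ax = plt.subplots()
        plot_variation(analysed, ax)
        path = outdir / "panel_variation.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    with_beats = [s for s in analysed if s.fft_beat_hz is not None]
    if with_beats:
        fig, ax = plt.subplots()
        plot_beats(with_beats, ax)
        path = outdir / "panel_beats.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
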