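"""Best-fitting beat estimation and isochrony classification.

A *beat* is the rate (Hz) of an underlying regular grid that best
describes a sequence's element timing. Two estimators are provided:

1. **IOI beat** — the reciprocal of the mean IOI: how many intervals fit
   into one second on average. For a sequence with an element every
   200 ms this is 5 Hz.
2. **Fourier beat** — the sequence's onsets are binarized onto a regular
   time grid (default 20 Hz, so beats up to the 10 Hz Nyquist limit are
   resolvable), the mean is removed to suppress the 0 Hz component, the
   train is zero-padded for a fine frequency grid, and the beat is the
   frequency of maximum spectral magnitude within a search window.

The two estimators deliberately disagree on *induced isochrony*: when
IOIs are integer multiples of a base period (some grid beats are "silent",
carried by no element), the IOI beat averages across the silent beats and
lands below the grid rate, while the Fourier beat recovers the grid rate
itself. :func:`classify_isochrony` makes that distinction explicit:
*signal* isochrony when every IOI matches one beat period, *induced* when
every IOI is an integer multiple of the period with at least one multiple
≥ 2, *none* otherwise.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from .errors import InsufficientDataError, ResolutionError, ValidationError
from .io import SoundSequence, require_analysis_minimum
from .stats import IOISequence

#: Default binarization rate, Hz. Half of it (10 Hz) bounds resolvable beats.
DEFAULT_SAMPLING_RATE_HZ = 20.0
#: Default spectral search window, Hz (low, high]. The nominal window for
#: fish sounds is 1-10 Hz, but sequences with multi-second IOIs carry beats
#: well below 1 Hz, so the default opens the low end; pass (1.0, 10.0) to
#: restrict to the nominal window.
DEFAULT_WINDOW_HZ = (0.1, 10.0)
#: Default frequency-grid spacing after zero-padding, Hz.
DEFAULT_FREQ_RESOLUTION_HZ = 0.01
#: Default relative tolerance when matching IOIs to beat-period multiples.
DEFAULT_MULTIPLE_TOLERANCE = 0.15
#: Spectral peaks within this relative margin of the maximum magnitude
#: count as tied; the lowest-frequency tied peak wins.
DEFAULT_TIE_TOLERANCE = 0.02
#: Trains shorter than this have an intrinsic frequency resolution too low
#: for a meaningful spectral peak and are flagged with a warning.
MIN_TRAIN_DURATION_S = 1.0


class IsochronyType(str, enum.Enum):
    SIGNAL = "signal"
    INDUCED = "induced"
    NONE = "none"
    UNASSESSED = "unassessed"


@dataclass
class BinarizedOnsetTrain:
    """Element onsets as a 0/1 vector on a regular time grid.

    ``samples[i] = 1`` iff an onset falls nearest to grid time
    ``t0 + i / sampling_rate``; onsets are re-referenced so the first onset
    is grid index 0.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    t0: float = 0.0

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    @property
    def duration(self) -> float:
        """Grid span in seconds (number of sample periods covered)."""
        return len(self.samples) / self.sampling_rate

    @property
    def n_onsets(self) -> int:
        return int(self.samples.sum())


@dataclass
class BeatEstimate:
    """Result of beat estimation for one sequence."""

    ioi_beat_hz: float | None = None
    fft_beat_hz: float | None = None
    fft_spectrum: np.ndarray | None = None  # shape (n, 2): frequency_hz, magnitude
    search_window_hz: tuple[float, float] | None = None
    isochrony_type: IsochronyType = IsochronyType.UNASSESSED
    warnings: list[str] = field(default_factory=list)


def ioi_beat(iois: IOISequence | np.ndarray) -> float:
    """Beat frequency as the reciprocal mean IOI (beats per second, Hz)."""
    d = iois.iois if isinstance(iois, IOISequence) else np.asarray(iois, dtype=float)
    if len(d) == 0:
        raise InsufficientDataError("IOI beat requires at least one IOI")
    if np.any(d <= 0):
        raise ValidationError("IOI beat: all IOIs must be positive")
    return float(1.0 / np.mean(d))


def binarize_onsets(
    sequence: SoundSequence, sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
) -> BinarizedOnsetTrain:
    """Map element onsets to the nearest samples of a regular grid.

    The maximum timing error introduced is half a sample period (25 ms at
    the default 20 Hz). Two onsets closer than one sample period would
    collapse onto one sample; this raises instead of silently merging.
    """
    require_analysis_minimum(sequence)
    if sampling_rate <= 0:
        raise ValidationError(f"sampling rate must be positive, got {sampling_rate}")
    onsets = sequence.onsets - sequence.onsets[0]
    indices = np.rint(onsets * sampling_rate).astype(int)
    if len(np.unique(indices)) != len(indices):
        raise ResolutionError(
            f"onsets collide at {sampling_rate} Hz (minimum IOI "
            f"{np.diff(onsets).min():.4g} s < one sample period "
            f"{1.0 / sampling_rate:.4g} s); use a higher sampling rate"
        )
    samples = np.zeros(indices[-1] + 1, dtype=float)
    samples[indices] = 1.0
    return BinarizedOnsetTrain(
        samples=samples, sampling_rate=float(sampling_rate), t0=float(sequence.onsets[0])
    )


def fourier_beat(
    train: BinarizedOnsetTrain,
    window_hz: tuple[float, float] = DEFAULT_WINDOW_HZ,
    freq_resolution_hz: float = DEFAULT_FREQ_RESOLUTION_HZ,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> BeatEstimate:
    """Spectral-peak beat of a binarized onset train.

    The mean is removed (suppressing the 0 Hz component a 0/1 train would
    otherwise be dominated by), the train is zero-padded so the frequency
    grid is at least as fine as *freq_resolution_hz*, and the beat is the
    frequency of maximum magnitude within ``window_hz`` (low exclusive,
    high inclusive). Ties break toward the lowest frequency, preferring
    the fundamental over its harmonics: a strictly isochronous comb puts
    *equal* magnitude on every harmonic, so local spectral maxima within
    ``tie_tolerance`` (relative) of the global maximum count as tied and
    the lowest-frequency one is returned.

    Note the zero-padded grid only interpolates the spectrum: the intrinsic
    resolution remains ~1/duration, and trains shorter than ~1 s are
    flagged with a low-resolution warning.
    """
    low, high = window_hz
    if not (0 <= low < high):
        raise ValidationError(f"invalid search window {window_hz}")
    if high > train.nyquist + 1e-12:
        raise ValidationError(
            f"window high {high} Hz exceeds Nyquist {train.nyquist} Hz "
            f"at sampling rate {train.sampling_rate} Hz"
        )
    if freq_resolution_hz <= 0:
        raise ValidationError("frequency resolution must be positive")

    notes: list[str] = []
    if train.duration < MIN_TRAIN_DURATION_S:
        msg = (
            f"train spans only {train.duration:.3g} s; intrinsic frequency "
            "resolution is very low"
        )
        warnings.warn(msg, stacklevel=2)
        notes.append("low_frequency_resolution")

    x = train.samples - train.samples.mean()
    n_fft = max(len(x), int(np.ceil(train.sampling_rate / freq_resolution_hz)))
    freqs = sp_fft.rfftfreq(n_fft, d=1.0 / train.sampling_rate)
    magnitude = np.abs(sp_fft.rfft(x, n=n_fft))
    in_window = (freqs > low) & (freqs <= high + 1e-12)
    if not np.any(in_window):
        raise ValidationError(f"no spectral bins inside the window {window_hz}")
    win_freqs = freqs[in_window]
    win_mag = magnitude[in_window]
    top = int(np.argmax(win_mag))
    # candidate peaks: local maxima (plus the global one, which may sit at a
    # window edge) within the tie margin of the maximum magnitude
    peak_idx, _ = sp_signal.find_peaks(win_mag)
    candidates = np.union1d(peak_idx, [top])
    tied = candidates[win_mag[candidates] >= (1.0 - tie_tolerance) * win_mag[top]]
    peak = int(tied.min())  # lowest frequency among tied peaks
    return BeatEstimate(
        fft_beat_hz=float(win_freqs[peak]),
        fft_spectrum=np.column_stack([win_freqs, win_mag]),
        search_window_hz=(float(low), float(high)),
        warnings=notes,
    )


def classify_isochrony(
    iois: IOISequence | np.ndarray,
    beat: BeatEstimate | float,
    tolerance: float = DEFAULT_MULTIPLE_TOLERANCE,
) -> IsochronyType:
    """Classify a sequence as signal isochrony, induced isochrony, or none.

    Each IOI is matched exhaustively against integer multiples k ≥ 1 of
    the beat period 1/f (the floor and ceiling of IOI·f suffice: the
    relative band around any other multiple cannot contain the IOI). If
    every IOI is within ``tolerance`` (relative to k/f) of some multiple
    and all matched k = 1, the grid is fully occupied: *signal* isochrony.
    If every IOI matches but some k ≥ 2, silent beats occur: *induced*
    isochrony. Any unmatched IOI yields *none*. Note that with a relative
    tolerance t, multiples k ≥ 1/(2t) always fit; the classification is
    only discriminating when the beat period is comparable to the IOIs.
    """
    if not (0 < tolerance < 0.5):
        raise ValidationError(f"tolerance must be in (0, 0.5), got {tolerance}")
    f = beat.fft_beat_hz if isinstance(beat, BeatEstimate) else float(beat)
    if f is None or f <= 0:
        raise ValidationError("a positive beat frequency is required for classification")
    d = iois.iois if isinstance(iois, IOISequence) else np.asarray(iois, dtype=float)
    if len(d) == 0:
        raise InsufficientDataError("classification requires at least one IOI")
    period = 1.0 / f
    k_lo = np.maximum(1, np.floor(d / period)).astype(int)
    k_hi = np.maximum(1, np.ceil(d / period)).astype(int)
    rel_lo = np.abs(d - k_lo * period) / (k_lo * period)
    rel_hi = np.abs(d - k_hi * period) / (k_hi * period)
    fit_lo, fit_hi = rel_lo <= tolerance, rel_hi <= tolerance
    if not np.all(fit_lo | fit_hi):
        return IsochronyType.NONE
    # among fitting multiples take the better (smaller relative error)
    k = np.where(fit_lo & (~fit_hi | (rel_lo <= rel_hi)), k_lo, k_hi)
    return IsochronyType.SIGNAL if np.all(k == 1) else IsochronyType.INDUCED


def estimate_beat(
    sequence: SoundSequence,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
    window_hz: tuple[float, float] = DEFAULT_WINDOW_HZ,
    freq_resolution_hz: float = DEFAULT_FREQ_RESOLUTION_HZ,
    multiple_tolerance: float = DEFAULT_MULTIPLE_TOLERANCE,
) -> BeatEstimate:
    """Full beat estimate for one sequence: both estimators + classification."""
    from .stats import compute_iois

    iois = compute_iois(sequence)
    train = binarize_onsets(sequence, sampling_rate=sampling_rate)
    estimate = fourier_beat(train, window_hz=window_hz, freq_resolution_hz=freq_resolution_hz)
    estimate.ioi_beat_hz = ioi_beat(iois)
    estimate.isochrony_type = classify_isochrony(iois, estimate, tolerance=multiple_tolerance)
    return estimate
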