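"""Beat estimation: mean-IOI inversion, binarized-train FFT, classification."""

import numpy as np
import pytest

from fishrhythm import (
    GeneratorSpec,
    InsufficientDataError,
    IsochronyType,
    ResolutionError,
    ValidationError,
    binarize_onsets,
    classify_isochrony,
    estimate_beat,
    fourier_beat,
    generate_sequence,
    ioi_beat,
)


class TestIOIBeat:
    @pytest.mark.parametrize(
        "iois, expected_hz",
        [
            ([0.2, 0.2, 0.2, 0.2], 5.0),  # a beat every 200 ms is a 5 Hz beat
            ([0.5, 2.0, 0.5, 2.0], 0.8),  # 1 / mean(1.25)
            ([1.0, 1.0, 1.0], 1.0),
        ],
    )
    def test_reciprocal_mean(self, iois, expected_hz):
        assert ioi_beat(np.array(iois)) == pytest.approx(expected_hz)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            ioi_beat(np.array([]))
        with pytest.raises(ValidationError):
            ioi_beat(np.array([0.5, -0.5]))


class TestBinarizeOnsets:
    def test_nearest_sample_indices(self, make_sequence):
        train = binarize_onsets(make_sequence([0.0, 0.2, 0.4], duration=0.01), 20.0)
        assert list(np.flatnonzero(train.samples)) == [0, 4, 8]
        assert train.n_onsets == 3

    def test_onset_count_preserved(self, make_sequence):
        seq = make_sequence(np.arange(25) * 0.35, duration=0.01)
        train = binarize_onsets(seq, 20.0)
        assert train.n_onsets == 25

    def test_collision_raises(self, make_sequence):
        seq = make_sequence([0.0, 0.02, 1.0], duration=0.005)
        with pytest.raises(ResolutionError, match="higher"):
            binarize_onsets(seq, 20.0)

    def test_below_minimum_rejected(self, make_sequence):
        with pytest.raises(InsufficientDataError):
            binarize_onsets(make_sequence([0.0, 1.0], duration=0.01), 20.0)

    def test_time_reference_is_first_onset(self, make_sequence):
        a = binarize_onsets(make_sequence([0.0, 0.5, 1.0], duration=0.01), 20.0)
        b = binarize_onsets(make_sequence([100.0, 100.5, 101.0], duration=0.01), 20.0)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert b.t0 == 100.0


class TestFourierBeat:
    def test_five_elements_per_second_gives_5hz(self, isochronous_sequence):
        train = binarize_onsets(isochronous_sequence, 20.0)
        estimate = fourier_beat(train)
        assert estimate.fft_beat_hz == pytest.approx(5.0, abs=0.01)

    def test_slow_isochronous_train(self, make_sequence):
        # IOIs of 2.5 s -> 0.4 Hz, resolvable below the nominal 1 Hz window edge
        seq = make_sequence(np.arange(20) * 2.5, duration=0.1)
        estimate = fourier_beat(binarize_onsets(seq, 20.0))
        assert estimate.fft_beat_hz == pytest.approx(0.4, abs=0.01)

    def test_beat_bounded_by_window_and_nyquist(self, rng, make_sequence):
        onsets = np.cumsum(rng.uniform(0.15, 3.0, size=30))
        estimate = fourier_beat(binarize_onsets(make_sequence(onsets, duration=0.01), 20.0))
        low, high = estimate.search_window_hz
        assert low < estimate.fft_beat_hz <= high <= 10.0
        assert np.all(estimate.fft_spectrum[:, 1] >= 0)

    def test_window_above_nyquist_rejected(self, isochronous_sequence):
        train = binarize_onsets(isochronous_sequence, 20.0)
        with pytest.raises(ValidationError, match="Nyquist"):
            fourier_beat(train, window_hz=(1.0, 11.0))

    def test_nominal_1_10_window_selectable(self, isochronous_sequence):
        train = binarize_onsets(isochronous_sequence, 20.0)
        estimate = fourier_beat(train, window_hz=(1.0, 10.0))
        assert estimate.search_window_hz == (1.0, 10.0)
        assert estimate.fft_beat_hz == pytest.approx(5.0, abs=0.01)

    def test_short_train_warns_low_resolution(self, make_sequence):
        seq = make_sequence([0.0, 0.2, 0.4], duration=0.01)  # spans 0.4 s
        with pytest.warns(UserWarning, match="resolution"):
            estimate = fourier_beat(binarize_onsets(seq, 20.0))
        assert "low_frequency_resolution" in estimate.warnings


class TestClassifyIsochrony:
    def test_signal_isochrony(self):
        assert classify_isochrony(np.array([0.5, 0.5, 0.5]), 2.0) is IsochronyType.SIGNAL

    def test_induced_isochrony_with_silent_beats(self):
        # at a 2 Hz grid, a 2.0 s IOI spans 4 periods: 3 silent beats
        iois = np.array([0.5, 2.0, 0.5, 2.0])
        assert classify_isochrony(iois, 2.0) is IsochronyType.INDUCED

    def test_classification_matches_multiple_matching_oracle(self, rng):
        """Against a brute-force multiple-matching check, over random IOIs and beats."""

        def oracle(iois, f, tol=0.15):
            ks = []
            for d in iois:
                fits = [k for k in range(1, int(d * f) + 2)
                        if abs(d - k / f) <= tol * k / f]
                if not fits:
                    return IsochronyType.NONE
                ks.append(min(fits, key=lambda k: abs(d - k / f)))
            return IsochronyType.SIGNAL if all(k == 1 for k in ks) else IsochronyType.INDUCED

        for _ in range(50):
            iois = rng.uniform(1.0, 50.0, size=int(rng.integers(3, 12)))
            for f in rng.uniform(0.1, 10.0, size=5):
                assert classify_isochrony(iois, float(f)) is oracle(iois, float(f))

    def test_broad_random_iois_fit_no_constraining_beat(self):
        """Irregular IOIs spanning tens of seconds match no slow grid.

        The short IOIs constrain the fit: at these beats no integer
        multiple of the period lands within 15% of every IOI (verified by
        exhaustive multiple matching below).
        """
        iois = np.array([3.0, 41.0, 17.5, 29.0, 8.0, 47.0])
        for f in (0.11, 0.2, 0.3, 0.45, 0.5):
            period = 1.0 / f
            fits_all = True
            for d in iois:  # exhaustive multiple-matching oracle
                fits_all &= any(
                    abs(d - k * period) <= 0.15 * k * period
                    for k in range(1, int(d / period) + 2)
                )
            assert not fits_all
            assert classify_isochrony(iois, f) is IsochronyType.NONE

    def test_tolerance_bounds(self):
        with pytest.raises(ValidationError):
            classify_isochrony(np.array([0.5, 0.5]), 2.0, tolerance=0.6)


class TestEstimateBeat:
    def test_ioi_and_fft_agree_for_signal_isochrony(self, isochronous_sequence):
        estimate = estimate_beat(isochronous_sequence)
        assert estimate.ioi_beat_hz == pytest.approx(5.0)
        assert estimate.fft_beat_hz == pytest.approx(5.0, abs=0.01)
        assert estimate.isochrony_type is IsochronyType.SIGNAL

    def test_estimators_diverge_under_induced_isochrony(self, induced_sequence):
        """The IOI beat averages across silent beats; the FFT beat recovers the grid."""
        estimate = estimate_beat(induced_sequence)
        assert estimate.ioi_beat_hz == pytest.approx(0.8)  # 2 Hz / mean multiple 2.5
        assert estimate.fft_beat_hz == pytest.approx(2.0, abs=0.01)
        assert estimate.isochrony_type is IsochronyType.INDUCED
        assert estimate.fft_beat_hz > estimate.ioi_beat_hz

    def test_time_translation_invariance(self, make_sequence):
        onsets = np.array([0.0, 0.45, 1.0, 1.45, 2.0, 2.45, 3.0])
        a = estimate_beat(make_sequence(onsets, duration=0.01))
        b = estimate_beat(make_sequence(onsets + 37.0, duration=0.01))
        assert a.fft_beat_hz == b.fft_beat_hz
        assert a.ioi_beat_hz == pytest.approx(b.ioi_beat_hz)
        assert a.isochrony_type is b.isochrony_type


def test_parameter_recovery_over_beat_grid():
    """Both estimators recover the generator beat under mild jitter.

    FFT within one intrinsic resolution step (1/train duration), IOI beat
    within 2%, for beats spanning 0.3-8 Hz.
    """
    for i, f in enumerate([0.3, 0.5, 1.0, 2.0, 4.0, 8.0]):
        seq = generate_sequence(
            GeneratorSpec(
                archetype="isochronous", beat_hz=f, jitter_rel=0.02,
                n_elements=24, element_duration_s=min(0.01, 0.1 / f), seed=100 + i,
            )
        )
        estimate = estimate_beat(seq)
        duration = seq.onsets[-1] - seq.onsets[0]
        assert estimate.fft_beat_hz == pytest.approx(f, abs=1.0 / duration), f"fft at {f} Hz"
        assert estimate.ioi_beat_hz == pytest.approx(f, rel=0.02), f"ioi at {f} Hz"
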