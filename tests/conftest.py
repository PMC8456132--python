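import numpy as np
import pytest

from fishrhythm import Element, GeneratorSpec, SoundSequence, generate_sequence


@pytest.fixture
def make_sequence():
    """Build a SoundSequence from onsets with a fixed short element duration."""

    def _make(onsets, duration=0.05, sequence_id="seq"):
        elements = [Element(onset=t, offset=t + duration) for t in onsets]
        return SoundSequence(elements=elements, sequence_id=sequence_id)

    return _make


@pytest.fixture
def isochronous_sequence():
    """Noiseless 5 Hz sequence spanning 4 s (21 elements, IOIs of 0.2 s)."""
    return generate_sequence(
        GeneratorSpec(
            archetype="isochronous", beat_hz=5.0, jitter_rel=0.0,
            n_elements=21, element_duration_s=0.01, seed=0,
        )
    )


@pytest.fixture
def induced_sequence():
    """Noiseless induced-isochrony sequence: 2 Hz grid, IOIs alternating 0.5/2.0 s."""
    return generate_sequence(
        GeneratorSpec(
            archetype="induced_isochronous", beat_hz=2.0, multiple_pattern=(1, 4),
            jitter_rel=0.0, n_elements=11, element_duration_s=0.05, seed=0,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210494)
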