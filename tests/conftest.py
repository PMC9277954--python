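"""Shared fixtures: tone clips and small seeded synthetic sessions."""

import numpy as np
import pytest

from usvkit.audio_io import ANALYSIS_RATE, AudioClip
from usvkit.synthetic import (
    CallSpec,
    NoiseSpec,
    SessionSpec,
    amplitude_for_snr,
    synth_session,
)


@pytest.fixture
def tone_clip():
    """Factory for pure-tone clips at the analysis rate."""

    def make(
        freq: float,
        duration: float = 0.1,
        amplitude: float = 0.5,
        rate: int = ANALYSIS_RATE,
        clip_id: str = "tone",
    ) -> AudioClip:
        t = np.arange(round(duration * rate)) / rate
        return AudioClip(
            clip_id=clip_id, samples=amplitude * np.sin(2 * np.pi * freq * t), rate=rate
        )

    return make


@pytest.fixture
def small_session():
    """A 5-s session with three well-spaced 50-kHz calls at high SNR."""
    calls = [
        (0.5, CallSpec("flat", f0=50_000, duration=0.03, amplitude=amplitude_for_snr(25))),
        (2.0, CallSpec("flat", f0=50_000, duration=0.06, amplitude=amplitude_for_snr(25))),
        (4.0, CallSpec("sweep", f0=50_000, duration=0.05, amplitude=amplitude_for_snr(25), bandwidth=10_000)),
    ]
    spec = SessionSpec(duration=5.0, schedule=calls, seed=11, clip_id="small")
    return synth_session(spec)


@pytest.fixture
def noiseless_session():
    """A 2-s noise-free session with one 30-ms 50-kHz call."""
    calls = [(1.0, CallSpec("flat", f0=50_000, duration=0.03, amplitude=0.1))]
    spec = SessionSpec(
        duration=2.0,
        schedule=calls,
        noise=NoiseSpec(broadband_rms=0.0, burst_rate=0.0),
        seed=3,
        clip_id="clean",
    )
    return synth_session(spec)
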