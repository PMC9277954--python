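"""Reading, resampling and fragmenting ultrasonic audio recordings.

All downstream analysis operates on a common analysis rate (250 kHz by
default, high enough to represent the 15-100 kHz band of interest) and on
short non-overlapping fragments (6 ms by default) that tile each clip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: Default analysis sampling rate in samples/second.
ANALYSIS_RATE = 250_000

#: Default fragment duration in milliseconds.
FRAGMENT_MS = 6.0

# Full-scale value per integer PCM dtype, used to normalize to [-1, 1].
_PCM_SCALE = {
    np.dtype(np.int16): 2**15,
    np.dtype(np.int32): 2**31,
    np.dtype(np.uint8): 2**7,
}


@dataclass
class AudioClip:
    """A mono waveform with identity/group metadata.

    ``samples`` are full-scale-normalized amplitudes in [-1, 1];
    ``rate`` is in samples/second.
    """

    clip_id: str
    samples: np.ndarray
    rate: int
    group: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise ValueError("AudioClip samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return len(self.samples) / self.rate


@dataclass
class Fragment:
    """One tile of a clip: ``start_time = index * fragment_duration``."""

    clip_id: str
    index: int
    start_time: float
    samples: np.ndarray = field(repr=False)


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Normalize PCM samples to full-scale [-1, 1] floats."""
    dtype = samples.dtype
    if dtype in _PCM_SCALE:
        scale = _PCM_SCALE[dtype]
        x = samples.astype(np.float64)
        if dtype == np.dtype(np.uint8):  # unsigned: midpoint at 128
            x -= 128.0
        return x / scale
    # 32/64-bit float WAV is already full-scale by convention
    return samples.astype(np.float64)


def load_clip(
    path: str | Path,
    analysis_rate: int = ANALYSIS_RATE,
    clip_id: str | None = None,
    group: str = "",
    session_id: str = "",
) -> AudioClip:
    """Read a WAV file, normalize amplitude and resample to ``analysis_rate``.

    Multichannel files are reduced to channel 0 with a warning.  Resampling
    uses a polyphase (windowed-sinc, anti-aliased) method and is skipped only
    when the source rate equals ``analysis_rate`` exactly.

    Raises
    ------
    ValueError
        If the file is unreadable, empty, or contains no audio.
    """
    path = Path(path)
    if clip_id is None:
        clip_id = path.stem
    try:
        rate, samples = wavfile.read(path)
    except Exception as exc:
        raise ValueError(f"unreadable WAV file {path}: {exc}") from exc
    if samples.size == 0:
        raise ValueError(f"zero-length audio in {path}")
    if samples.ndim > 1:
        logger.warning(
            "clip %s has %d channels; using channel 0", clip_id, samples.shape[1]
        )
        samples = samples[:, 0]
    x = _to_float(samples)
    if rate != analysis_rate:
        frac = Fraction(analysis_rate, int(rate))
        x = resample_poly(x, frac.numerator, frac.denominator)
    return AudioClip(
        clip_id=clip_id, samples=x, rate=analysis_rate, group=group,
        session_id=session_id or clip_id,
    )


def save_clip(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 32-bit float WAV."""
    wavfile.write(path, clip.rate, clip.samples.astype(np.float32))


def fragment_samples(rate: int, fragment_ms: float = FRAGMENT_MS) -> int:
    """Number of samples per fragment: round(fragment_ms/1000 * rate)."""
    return round(fragment_ms / 1000.0 * rate)


def fragment_clip(clip: AudioClip, fragment_ms: float = FRAGMENT_MS) -> list[Fragment]:
    """Tile a clip into non-overlapping, contiguous fragments.

    A trailing partial fragment is discarded.  Returns an empty list (with a
    warning) when the clip is shorter than one fragment.
    """
    if fragment_ms <= 0:
        raise ValueError(f"fragment_ms must be positive, got {fragment_ms}")
    n = fragment_samples(clip.rate, fragment_ms)
    n_frag = len(clip.samples) // n
    if n_frag == 0:
        logger.warning(
            "clip %s (%.1f ms) is shorter than one %g-ms fragment",
            clip.clip_id, 1000 * clip.duration, fragment_ms,
        )
        return []
    dt = fragment_ms / 1000.0
    return [
        Fragment(
            clip_id=clip.clip_id,
            index=i,
            start_time=i * dt,
            samples=clip.samples[i * n : (i + 1) * n],
        )
        for i in range(n_frag)
    ]


def fragment_matrix(clip: AudioClip, fragment_ms: float = FRAGMENT_MS) -> np.ndarray:
    """All full fragments of a clip as an (n_fragments, n_samples) array."""
    n = fragment_samples(clip.rate, fragment_ms)
    n_frag = len(clip.samples) // n
    return clip.samples[: n_frag * n].reshape(n_frag, n)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a clip manifest CSV with columns clip_id, path, group, session_id.

    ``group`` and ``session_id`` are optional; missing session ids default to
    the clip id.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"clip_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    if "session_id" not in df.columns:
        df["session_id"] = df["clip_id"]
    df["group"] = df["group"].fillna("")
    df["session_id"] = df["session_id"].fillna(df["clip_id"])
    return df
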