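"""High-pass filtering and power-threshold selection of ultrasonic fragments.

A clip is high-pass filtered (15 kHz default, removing the audible band),
tiled into 6-ms fragments, and every fragment whose RMS power exceeds a
threshold becomes an ultrasonic fragment (USF) — the atomic unit of all
downstream analysis.

The threshold can be absolute (RMS in full-scale units) or, by default,
relative to the clip's noise floor: ``k * median(fragment power)``.  The
median fragment power of a recording is dominated by silent fragments and so
estimates the noise floor robustly, which makes the multiplier ``k``
transferable across recording gains.  The ladder
:data:`DEFAULT_THRESHOLD_LADDER` spans permissive to conservative settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioClip, Fragment, FRAGMENT_MS, fragment_matrix

#: Noise-relative threshold multipliers from permissive to conservative.
#: k = 1 would sit exactly at the noise median (half of all silent fragments
#: would pass), so the permissive end starts just above the noise floor.
DEFAULT_THRESHOLD_LADDER = (1.2, 1.5, 2.2, 2.7, 3.5)


@dataclass
class DetectionConfig:
    """Parameters of USF detection.

    ``threshold`` is an RMS value in full-scale units in ``absolute`` mode,
    or a multiplier of the clip's median fragment power in ``noise_relative``
    mode (the default).
    """

    highpass_cutoff: float = 15_000.0
    threshold: float = 2.7
    threshold_mode: str = "noise_relative"
    filter_order: int = 4
    fragment_ms: float = FRAGMENT_MS

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.threshold_mode not in ("absolute", "noise_relative"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.highpass_cutoff <= 0:
            raise ValueError("highpass_cutoff must be positive")


@dataclass
class USF:
    """A detected ultrasonic fragment.

    ``samples`` holds the high-pass-filtered fragment waveform; ``feature``,
    ``embedding`` and ``cluster`` are filled by later pipeline stages
    (``cluster`` 0 means unassigned / density outlier).
    """

    clip_id: str
    index: int
    start_time: float
    power: float
    samples: np.ndarray = field(repr=False)
    session_id: str = ""
    group: str = ""
    feature: np.ndarray | None = field(default=None, repr=False)
    embedding: np.ndarray | None = field(default=None, repr=False)
    cluster: int = 0


def highpass(clip: AudioClip, cutoff: float = 15_000.0, order: int = 4) -> AudioClip:
    """Zero-phase Butterworth high-pass of a whole clip.

    Applied before fragmentation so that 6-ms tiles carry no filter edge
    transients.  Zero-phase (forward-backward) filtering doubles the nominal
    attenuation and leaves fragment timestamps unshifted.
    """
    nyquist = clip.rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    sos = butter(order, cutoff, btype="highpass", fs=clip.rate, output="sos")
    filtered = sosfiltfilt(sos, clip.samples)
    return AudioClip(
        clip_id=clip.clip_id, samples=filtered, rate=clip.rate,
        group=clip.group, session_id=clip.session_id,
    )


def fragment_power(fragment: Fragment | np.ndarray) -> float:
    """RMS amplitude of a fragment in full-scale units."""
    x = fragment.samples if isinstance(fragment, Fragment) else np.asarray(fragment)
    if x.size == 0:
        raise ValueError("fragment is empty")
    return float(np.sqrt(np.mean(np.square(x))))


def fragment_powers(fragments: np.ndarray) -> np.ndarray:
    """Row-wise RMS of an (n_fragments, n_samples) matrix."""
    return np.sqrt(np.mean(np.square(fragments), axis=1))


def resolve_threshold(powers: np.ndarray, config: DetectionConfig) -> float:
    """Threshold in absolute RMS units for a clip's fragment powers."""
    if config.threshold_mode == "absolute":
        return config.threshold
    return config.threshold * float(np.median(powers))


def _collect(
    clip: AudioClip, frags: np.ndarray, powers: np.ndarray, thr: float, dt: float
) -> list[USF]:
    keep = np.flatnonzero(powers > thr)
    return [
        USF(
            clip_id=clip.clip_id,
            index=int(i),
            start_time=float(i * dt),
            power=float(powers[i]),
            samples=frags[i],
            session_id=clip.session_id,
            group=clip.group,
        )
        for i in keep
    ]


def detect_usfs(clip: AudioClip, config: DetectionConfig | None = None) -> list[USF]:
    """Detect USFs: filter, fragment, and keep fragments above threshold.

    Returns USFs ordered by start time; an empty list is a valid result.
    """
    if config is None:
        config = DetectionConfig()
    filtered = highpass(clip, config.highpass_cutoff, config.filter_order)
    frags = fragment_matrix(filtered, config.fragment_ms)
    if frags.shape[0] == 0:
        return []
    powers = fragment_powers(frags)
    thr = resolve_threshold(powers, config)
    return _collect(clip, frags, powers, thr, config.fragment_ms / 1000.0)


def detect_usfs_at_thresholds(
    clip: AudioClip,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLD_LADDER,
    config: DetectionConfig | None = None,
) -> dict[float, list[USF]]:
    """Detect at several thresholds with one filter pass over the clip.

    Because each fragment's power is a fixed statistic, detections at a
    lower threshold are a superset of those at a higher one.
    """
    if config is None:
        config = DetectionConfig()
    filtered = highpass(clip, config.highpass_cutoff, config.filter_order)
    frags = fragment_matrix(filtered, config.fragment_ms)
    if frags.shape[0] == 0:
        return {float(t): [] for t in thresholds}
    powers = fragment_powers(frags)
    dt = config.fragment_ms / 1000.0
    out = {}
    for t in thresholds:
        cfg = DetectionConfig(
            highpass_cutoff=config.highpass_cutoff, threshold=t,
            threshold_mode=config.threshold_mode, filter_order=config.filter_order,
            fragment_ms=config.fragment_ms,
        )
        out[float(t)] = _collect(clip, frags, powers, resolve_threshold(powers, cfg), dt)
    return out
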