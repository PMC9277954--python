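"""Ground-truthed synthetic ultrasonic corpora emulating rodent calls.

Call families follow the rat vocal repertoire: "aversive" calls are low
pitch (20-30 kHz), flat and prolonged (150 ms to seconds); "appetitive"
calls are high pitch (40-80 kHz) and short (10-150 ms), either flat,
linearly swept, or trilled (sinusoidal frequency modulation).  Strain
presets ``mouse_low`` and ``mouse_high`` emulate strains whose call energy
concentrates near 40 and 60 kHz respectively.

The noise bed combines white broadband noise with Poisson-scheduled
impulsive low-frequency (2-8 kHz) bursts standing in for cage knocks and
movement artifacts; the 15-kHz high-pass of the detection stage must remove
these.  Call amplitudes are set from a target signal-to-noise ratio measured
against the broadband noise power inside the 15-100 kHz analysis band.

Every session is generated from one explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .audio_io import ANALYSIS_RATE, AudioClip, save_clip
from .validation import CallAnnotation, write_annotations

#: Raised-cosine onset/offset ramp applied to each call, in seconds.
RAMP_S = 0.002

#: Default broadband noise RMS in full-scale units.
BROADBAND_RMS = 0.005

CALL_TYPES = ("flat", "sweep", "trill", "aversive_like", "appetitive_like")


@dataclass
class CallSpec:
    """One synthetic call: carrier, modulation, duration, amplitude."""

    call_type: str
    f0: float
    duration: float
    amplitude: float
    bandwidth: float = 0.0
    fm_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call_type {self.call_type!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.f0 <= 0 or self.amplitude <= 0:
            raise ValueError("f0 and amplitude must be positive")


@dataclass
class NoiseSpec:
    """Broadband + impulsive low-frequency noise parameters."""

    broadband_rms: float = BROADBAND_RMS
    burst_rate: float = 0.5       # bursts per second (Poisson)
    burst_rms: float = 5 * BROADBAND_RMS
    burst_band: tuple[float, float] = (2_000.0, 8_000.0)
    burst_duration: float = 0.02  # seconds


@dataclass
class SessionSpec:
    """A session: scheduled calls in a noise bed, one seed."""

    duration: float
    schedule: list[tuple[float, CallSpec]] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    clip_id: str = "session"
    group: str = ""


def _instantaneous_frequency(spec: CallSpec, t: np.ndarray) -> np.ndarray:
    if spec.call_type in ("flat", "aversive_like"):
        return np.full_like(t, spec.f0)
    if spec.call_type in ("sweep", "appetitive_like"):
        # linear chirp across the bandwidth, centered on f0
        return spec.f0 - spec.bandwidth / 2 + spec.bandwidth * t / t[-1]
    if spec.call_type == "trill":
        return spec.f0 + (spec.bandwidth / 2) * np.sin(2 * np.pi * spec.fm_rate * t)
    raise ValueError(spec.call_type)


def synth_call(spec: CallSpec, rate: int = ANALYSIS_RATE) -> tuple[np.ndarray, dict]:
    """Synthesize one call; returns (waveform, band info).

    The waveform is phase-continuous with raised-cosine on/off ramps.  The
    band dict holds the emitted frequency extent (``f_low``/``f_high``) for
    the annotation.
    """
    n = round(spec.duration * rate)
    if n < 2:
        raise ValueError(f"duration {spec.duration}s too short at rate {rate}")
    t = np.arange(n) / rate
    f_inst = _instantaneous_frequency(spec, t)
    if f_inst.max() >= rate / 2:
        raise ValueError(
            f"call reaches {f_inst.max():.0f} Hz, above Nyquist {rate / 2:.0f} Hz"
        )
    if f_inst.min() <= 0:
        raise ValueError("instantaneous frequency must stay positive")
    phase = 2 * np.pi * np.cumsum(f_inst) / rate
    wave = spec.amplitude * np.sin(phase)
    ramp_n = min(round(RAMP_S * rate), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        wave[:ramp_n] *= ramp
        wave[-ramp_n:] *= ramp[::-1]
    # widen the emitted extent by the Fourier limit so pure tones get a
    # physically meaningful nonzero band
    df = 0.5 / spec.duration
    return wave, {"f_low": float(f_inst.min() - df), "f_high": float(f_inst.max() + df)}


def inband_noise_rms(
    broadband_rms: float,
    rate: int = ANALYSIS_RATE,
    f_low: float = 15_000.0,
    f_high: float = 100_000.0,
) -> float:
    """RMS of white noise restricted to [f_low, f_high] (flat-spectrum law)."""
    return broadband_rms * math.sqrt((f_high - f_low) / (rate / 2))


def amplitude_for_snr(
    snr_db: float, broadband_rms: float = BROADBAND_RMS, rate: int = ANALYSIS_RATE
) -> float:
    """Sinusoid amplitude giving ``snr_db`` against in-band noise power."""
    return math.sqrt(2.0) * inband_noise_rms(broadband_rms, rate) * 10 ** (snr_db / 20)


def synth_session(
    spec: SessionSpec, rate: int = ANALYSIS_RATE
) -> tuple[AudioClip, list[CallAnnotation]]:
    """Render a session: noise bed plus scheduled calls, with annotations."""
    n = round(spec.duration * rate)
    rng = np.random.default_rng(spec.seed)
    if spec.noise.broadband_rms > 0:
        samples = rng.normal(0.0, spec.noise.broadband_rms, n)
    else:
        samples = np.zeros(n)
    # impulsive low-frequency bursts (Poisson schedule)
    if spec.noise.burst_rate > 0 and spec.noise.burst_rms > 0:
        n_bursts = rng.poisson(spec.noise.burst_rate * spec.duration)
        burst_n = round(spec.noise.burst_duration * rate)
        sos = butter(4, spec.noise.burst_band, btype="bandpass", fs=rate, output="sos")
        for start in np.sort(rng.uniform(0, spec.duration - spec.noise.burst_duration,
                                         n_bursts)):
            burst = sosfiltfilt(sos, rng.normal(0.0, 1.0, burst_n))
            burst *= spec.noise.burst_rms / max(np.sqrt(np.mean(burst**2)), 1e-12)
            burst *= np.hanning(burst_n)
            i = round(start * rate)
            samples[i : i + burst_n] += burst

    annotations = []
    for start, call in spec.schedule:
        wave, band = synth_call(call, rate)
        i = round(start * rate)
        if i < 0 or i + wave.size > n:
            raise ValueError(
                f"call at {start:.3f}s (duration {call.duration:.3f}s) exceeds "
                f"session bounds [0, {spec.duration}]"
            )
        samples[i : i + wave.size] += wave
        annotations.append(
            CallAnnotation(
                clip_id=spec.clip_id,
                onset=start,
                offset=start + call.duration,
                f_low=band["f_low"],
                f_high=band["f_high"],
                call_type=call.call_type,
            )
        )
    clip = AudioClip(
        clip_id=spec.clip_id, samples=samples, rate=rate,
        group=spec.group, session_id=spec.clip_id,
    )
    return clip, annotations


# ---------------------------------------------------------------------------
# Random call families and corpus builders


def random_call(
    rng: np.random.Generator,
    family: str,
    snr_db: float = 20.0,
    broadband_rms: float = BROADBAND_RMS,
    snr_jitter_db: float = 2.0,
) -> CallSpec:
    """Draw one call from a family with realistic parameter spreads.

    Families: ``aversive`` (flat 20-30 kHz, 150-800 ms), ``appetitive``
    (40-80 kHz, 10-150 ms; flat, swept or trilled).
    """
    snr = snr_db + rng.uniform(-snr_jitter_db, snr_jitter_db)
    amp = amplitude_for_snr(snr, broadband_rms)
    if family == "aversive":
        return CallSpec(
            call_type="flat",
            f0=rng.uniform(20_000, 30_000),
            duration=rng.uniform(0.15, 0.8),
            amplitude=amp,
        )
    if family == "appetitive":
        subtype = rng.choice(["flat", "sweep", "trill"], p=[0.4, 0.3, 0.3])
        f0 = rng.uniform(40_000, 80_000)
        duration = rng.uniform(0.01, 0.15)
        if subtype == "flat":
            return CallSpec("flat", f0=f0, duration=duration, amplitude=amp)
        if subtype == "sweep":
            return CallSpec(
                "sweep", f0=f0, duration=duration, amplitude=amp,
                bandwidth=rng.uniform(5_000, 15_000),
            )
        return CallSpec(
            "trill", f0=f0, duration=max(duration, 0.03), amplitude=amp,
            bandwidth=10_000, fm_rate=rng.uniform(30, 80),
        )
    raise ValueError(f"unknown family {family!r}")


def preset_call(
    rng: np.random.Generator,
    preset: str,
    snr_db: float = 20.0,
    broadband_rms: float = BROADBAND_RMS,
) -> CallSpec:
    """Strain presets: short calls centered at 40 (mouse_low) / 60 kHz (mouse_high)."""
    centers = {"mouse_low": 40_000.0, "mouse_high": 60_000.0}
    if preset not in centers:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(centers)}")
    amp = amplitude_for_snr(snr_db + rng.uniform(-2, 2), broadband_rms)
    f0 = rng.normal(centers[preset], 2_000.0)
    subtype = rng.choice(["flat", "sweep", "trill"], p=[0.5, 0.25, 0.25])
    duration = rng.uniform(0.02, 0.1)
    if subtype == "flat":
        return CallSpec("flat", f0=f0, duration=duration, amplitude=amp)
    if subtype == "sweep":
        return CallSpec("sweep", f0=f0, duration=duration, amplitude=amp,
                        bandwidth=6_000.0)
    return CallSpec("trill", f0=f0, duration=max(duration, 0.03), amplitude=amp,
                    bandwidth=6_000.0, fm_rate=rng.uniform(40, 70))


def schedule_calls(
    rng: np.random.Generator,
    calls: list[CallSpec],
    duration: float,
    min_gap: float = 0.05,
    max_tries: int = 10_000,
) -> list[tuple[float, CallSpec]]:
    """Place calls at random non-overlapping onsets within a session."""
    placed: list[tuple[float, CallSpec]] = []
    occupied: list[tuple[float, float]] = []
    for call in calls:
        for _ in range(max_tries):
            t = rng.uniform(0, duration - call.duration - min_gap)
            lo, hi = t - min_gap, t + call.duration + min_gap
            if all(hi <= o_lo or lo >= o_hi for o_lo, o_hi in occupied):
                placed.append((t, call))
                occupied.append((lo, hi))
                break
        else:
            raise ValueError("could not place all calls without overlap")
    return sorted(placed, key=lambda x: x[0])


def _session_seeds(seed: int, n: int) -> list[int]:
    # independent per-session seeds below 2**31
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def mixed_corpus(
    n_sessions: int = 6,
    duration: float = 60.0,
    snr_db: float = 20.0,
    seed: int = 0,
    calls_per_session: tuple[int, int] = (20, 50),
    group: str = "mixed",
) -> list[tuple[AudioClip, list[CallAnnotation]]]:
    """Sessions mixing aversive and appetitive (flat/sweep/trill) calls."""
    out = []
    for i, s in enumerate(_session_seeds(seed, n_sessions)):
        rng = np.random.default_rng(s)
        n_calls = int(rng.integers(calls_per_session[0], calls_per_session[1] + 1))
        calls = [
            random_call(rng, "aversive" if rng.random() < 0.4 else "appetitive",
                        snr_db=snr_db)
            for _ in range(n_calls)
        ]
        spec = SessionSpec(
            duration=duration,
            schedule=schedule_calls(rng, calls, duration),
            seed=s,
            clip_id=f"{group}_{i:02d}",
            group=group,
        )
        out.append(synth_session(spec))
    return out


def preset_corpus(
    preset: str,
    n_calls: int = 100,
    n_sessions: int = 2,
    duration: float = 30.0,
    snr_db: float = 20.0,
    seed: int = 0,
) -> list[tuple[AudioClip, list[CallAnnotation]]]:
    """A strain-preset corpus with ``n_calls`` total calls across sessions."""
    per = [n_calls // n_sessions] * n_sessions
    per[-1] += n_calls - sum(per)
    out = []
    for i, (s, k) in enumerate(zip(_session_seeds(seed, n_sessions), per)):
        rng = np.random.default_rng(s)
        calls = [preset_call(rng, preset, snr_db=snr_db) for _ in range(k)]
        spec = SessionSpec(
            duration=duration,
            schedule=schedule_calls(rng, calls, duration),
            seed=s,
            clip_id=f"{preset}_{i:02d}",
            group=preset,
        )
        out.append(synth_session(spec))
    return out


#: Call types whose carrier frequency and duration are negatively coupled
#: (low-pitch calls are long, high-pitch calls are short), echoing the
#: aversive-to-appetitive continuum: (center Hz, duration s, calls/session).
COUPLED_TYPES = (
    (25_000.0, 0.24, 4),
    (40_000.0, 0.16, 8),
    (55_000.0, 0.08, 14),
    (70_000.0, 0.03, 24),
)


def coupled_corpus(
    seed: int = 0,
    n_sessions: int = 2,
    duration: float = 60.0,
    snr_db: float = 20.0,
) -> list[tuple[AudioClip, list[CallAnnotation]]]:
    """Sessions of flat calls with frequency negatively coupled to duration.

    Useful for probing whether the pipeline recovers the built-in negative
    relation between cluster peak frequency and repeatability half-width.
    """
    out = []
    for i, s in enumerate(_session_seeds(seed, n_sessions)):
        rng = np.random.default_rng(s)
        calls = []
        for f0, dur, n in COUPLED_TYPES:
            for _ in range(n):
                amp = amplitude_for_snr(snr_db + rng.uniform(-2, 2))
                calls.append(
                    CallSpec(
                        "flat",
                        f0=rng.normal(f0, 1_000.0),
                        duration=dur * rng.uniform(0.9, 1.1),
                        amplitude=amp,
                    )
                )
        spec = SessionSpec(
            duration=duration,
            schedule=schedule_calls(rng, calls, duration),
            seed=s,
            clip_id=f"coupled_{i:02d}",
            group="coupled",
        )
        out.append(synth_session(spec))
    return out


def rate_varying_corpus(
    n_clips: int = 12,
    duration: float = 30.0,
    snr_db: float = 20.0,
    seed: int = 0,
    call_range: tuple[int, int] = (3, 25),
) -> list[tuple[AudioClip, list[CallAnnotation]]]:
    """Clips whose call counts span ``call_range``, for count-correlation checks."""
    counts = np.round(np.linspace(call_range[0], call_range[1], n_clips)).astype(int)
    out = []
    for i, (s, k) in enumerate(zip(_session_seeds(seed, n_clips), counts)):
        rng = np.random.default_rng(s)
        calls = [random_call(rng, "appetitive", snr_db=snr_db) for _ in range(int(k))]
        spec = SessionSpec(
            duration=duration,
            schedule=schedule_calls(rng, calls, duration),
            seed=s,
            clip_id=f"rate_{i:02d}",
            group="rate",
        )
        out.append(synth_session(spec))
    return out


def write_corpus(
    corpus: list[tuple[AudioClip, list[CallAnnotation]]], outdir: str | Path
) -> tuple[Path, Path]:
    """Write WAVs, one pooled annotation CSV and a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    annotations: list[CallAnnotation] = []
    for clip, anns in corpus:
        wav = outdir / f"{clip.clip_id}.wav"
        save_clip(wav, clip)
        annotations.extend(anns)
        rows.append(
            {"clip_id": clip.clip_id, "path": str(wav), "group": clip.group,
             "session_id": clip.session_id}
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    ann_path = outdir / "annotations.csv"
    write_annotations(ann_path, annotations)
    return manifest, ann_path
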