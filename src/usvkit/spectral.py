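"""Spectrograms, per-fragment and per-cluster power spectral densities.

All spectral estimates share one parameterization: 512-sample Hann windows
with 50% overlap at the analysis rate (488.28-Hz bins at 250 kHz).  A
fragment's PSD is the Welch average of its overlapping windows; a cluster's
PSD is the mean over member fragments; a group's spectral profile is the sum
of cluster PSDs scaled by cluster occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .audio_io import AudioClip
from .detection import USF
from .embedding import ClusterModel


@dataclass
class SpectralConfig:
    window: int = 512
    overlap: float = 0.5
    rate: int = 250_000

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.window < 64:
            raise ValueError("window must be >= 64 samples")

    @property
    def noverlap(self) -> int:
        return int(self.window * self.overlap)

    @property
    def bin_spacing(self) -> float:
        """Frequency bin spacing in Hz (rate / window)."""
        return self.rate / self.window


@dataclass
class PSD:
    """A power spectral density with the number of fragments behind it."""

    freqs: np.ndarray
    density: np.ndarray
    n_usfs: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.freqs.shape != self.density.shape:
            raise ValueError("freqs and density must have the same length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def normalized(self, f_low: float = 15_000.0, f_high: float = 100_000.0) -> "PSD":
        """Copy scaled to unit maximum within [f_low, f_high] (for display)."""
        band = (self.freqs >= f_low) & (self.freqs <= f_high)
        peak = self.density[band].max() if band.any() else self.density.max()
        if peak <= 0:
            return PSD(self.freqs, self.density.copy(), self.n_usfs)
        return PSD(self.freqs, self.density / peak, self.n_usfs)


def spectrogram(
    clip: AudioClip, config: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Power spectrogram: (freqs, times, power) with power >= 0."""
    if config is None:
        config = SpectralConfig(rate=clip.rate)
    if len(clip.samples) < config.window:
        raise ValueError(
            f"clip {clip.clip_id} shorter than one {config.window}-sample window"
        )
    freqs, times, sxx = signal.spectrogram(
        clip.samples,
        fs=config.rate,
        window="hann",
        nperseg=config.window,
        noverlap=config.noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return freqs, times, sxx


def usf_psd(fragment_samples: np.ndarray, config: SpectralConfig | None = None) -> PSD:
    """Welch PSD of one fragment (overlapping sub-windows, averaged)."""
    return PSD(*_welch(np.atleast_2d(fragment_samples), config), n_usfs=1)


def _welch(
    fragments: np.ndarray, config: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    if config is None:
        config = SpectralConfig()
    fragments = np.asarray(fragments, dtype=np.float64)
    if fragments.shape[1] < config.window:
        raise ValueError(
            f"fragment length {fragments.shape[1]} < window {config.window}"
        )
    freqs, density = signal.welch(
        fragments,
        fs=config.rate,
        window="hann",
        nperseg=config.window,
        noverlap=config.noverlap,
        detrend=False,
        scaling="density",
        axis=1,
    )
    return freqs, density[0] if density.shape[0] == 1 else density


def usf_psd_matrix(
    usfs: list[USF], config: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(freqs, N x F density matrix) for a list of USFs."""
    if not usfs:
        raise ValueError("no USFs")
    freqs, density = _welch(np.stack([u.samples for u in usfs]), config)
    return freqs, np.atleast_2d(density)


def cluster_mean_psd(
    usfs: list[USF], label: int, config: SpectralConfig | None = None
) -> PSD:
    """Element-wise mean PSD over all USFs carrying ``label``."""
    members = [u for u in usfs if u.cluster == label]
    if not members:
        raise ValueError(f"cluster {label} has no USFs")
    freqs, density = usf_psd_matrix(members, config)
    return PSD(freqs, density.mean(axis=0), n_usfs=len(members))


def cluster_mean_psds(
    usfs: list[USF],
    model: ClusterModel,
    config: SpectralConfig | None = None,
    include_outliers: bool = False,
) -> dict[int, PSD]:
    """Mean PSD per cluster label (computed from one shared Welch pass)."""
    if not usfs:
        raise ValueError("no USFs")
    freqs, density = usf_psd_matrix(usfs, config)
    labels = np.array([u.cluster for u in usfs])
    out: dict[int, PSD] = {}
    wanted = model.cluster_labels + ([0] if include_outliers and (labels == 0).any() else [])
    for label in wanted:
        mask = labels == label
        if mask.any():
            out[label] = PSD(freqs, density[mask].mean(axis=0), n_usfs=int(mask.sum()))
    return out


def group_scaled_psd(cluster_psds: list[PSD], counts: list[int]) -> PSD:
    """Sum of cluster mean PSDs, each scaled by its USF count.

    This is a group's overall spectral profile: clusters contribute in
    proportion to how often their fragments occurred in that group.
    """
    if not cluster_psds:
        raise ValueError("no clusters to combine")
    if len(cluster_psds) != len(counts):
        raise ValueError("cluster_psds and counts length mismatch")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    freqs = cluster_psds[0].freqs
    total = np.zeros_like(cluster_psds[0].density)
    for psd, count in zip(cluster_psds, counts):
        if psd.freqs.shape != freqs.shape or not np.allclose(psd.freqs, freqs):
            raise ValueError("cluster PSDs are on different frequency grids")
        total = total + count * psd.density
    return PSD(freqs, total, n_usfs=int(sum(counts)))


def psd_peak_frequency(psd: PSD) -> float:
    """Frequency (Hz) of the global density maximum; ties break low."""
    if not np.any(psd.density > 0):
        raise ValueError("PSD is all zero; peak frequency undefined")
    return float(psd.freqs[int(np.argmax(psd.density))])


@dataclass
class Overlay:
    """A clip spectrogram plus per-USF time markers with cluster labels."""

    clip_id: str
    freqs: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    markers: pd.DataFrame = field(repr=False)


def overlay_usfs(
    clip: AudioClip,
    usfs: list[USF],
    model: ClusterModel | None = None,
    config: SpectralConfig | None = None,
) -> Overlay:
    """Spectrogram of a clip with each USF marked at (start_time, label)."""
    foreign = [u.clip_id for u in usfs if u.clip_id != clip.clip_id]
    if foreign:
        raise ValueError(f"USFs from other clips: {sorted(set(foreign))}")
    freqs, times, power = spectrogram(clip, config)
    markers = pd.DataFrame(
        {
            "start_time_s": [u.start_time for u in usfs],
            "cluster": [u.cluster for u in usfs],
        }
    )
    return Overlay(clip.clip_id, freqs, times, power, markers)


def plot_overlay(overlay: Overlay, path: str, f_max: float = 100_000.0) -> None:
    """Save an overlay as a PNG (log-power spectrogram + cluster markers)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    band = overlay.freqs <= f_max
    ax.pcolormesh(
        overlay.times,
        overlay.freqs[band] / 1000.0,
        10 * np.log10(overlay.power[band] + 1e-20),
        shading="auto",
        cmap="magma",
    )
    for _, row in overlay.markers.iterrows():
        ax.annotate(
            str(int(row["cluster"])),
            (row["start_time_s"], f_max / 1000.0 * 0.95),
            color="cyan",
            fontsize=7,
            ha="center",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (kHz)")
    ax.set_title(overlay.clip_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
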