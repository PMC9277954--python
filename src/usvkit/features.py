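"""Mel-frequency cepstral featurization of ultrasonic fragments.

Each detected fragment's 15-100 kHz spectrum is summarized by 16 cepstral
coefficients: Hann window -> magnitude spectrum -> triangular mel filterbank
-> log energies -> orthonormal DCT-II.  The mel scale
(mel(f) = 2595 log10(1 + f/700)) was designed for human hearing; here it
simply provides a smooth frequency warp over the ultrasonic band whose
band-limited cepstrum compactly encodes spectral shape.  Coefficient 0
carries overall log-amplitude; higher coefficients carry shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal.windows import hann

from .detection import USF

#: Log floor applied to filterbank energies, in full-scale units.
LOG_FLOOR = 1e-10


@dataclass
class FeatureConfig:
    f_low: float = 15_000.0
    f_high: float = 100_000.0
    n_coeffs: int = 16
    n_mel_filters: int = 32
    include_c0: bool = True
    rate: int = 250_000

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError("need 0 < f_low < f_high")
        if self.f_high > self.rate / 2:
            raise ValueError(
                f"f_high {self.f_high} exceeds Nyquist {self.rate / 2}"
            )
        if self.n_coeffs > self.n_mel_filters:
            raise ValueError("n_coeffs must be <= n_mel_filters")


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    f_low: float, f_high: float, n_filters: int, n_fft: int, rate: float
) -> np.ndarray:
    """Triangular mel filterbank as an (n_filters, n_fft//2 + 1) matrix.

    Filter centers are equally spaced on the mel scale between mel(f_low)
    and mel(f_high); the first filter's support starts at f_low and the last
    filter's support ends at f_high, with adjacent triangles meeting so the
    band is covered without gaps.
    """
    if n_filters < 2:
        raise ValueError("n_filters must be >= 2")
    if f_high > rate / 2:
        raise ValueError(f"f_high {f_high} exceeds Nyquist {rate / 2}")
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(f_low), hz_to_mel(f_high), n_filters + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((n_filters, bin_freqs.size))
    for k in range(n_filters):
        lo, center, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        rising = (bin_freqs - lo) / (center - lo)
        falling = (hi - bin_freqs) / (hi - center)
        fb[k] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def _n_fft_for(n_samples: int) -> int:
    """Next power of two >= n_samples (radix-2 FFT of the whole fragment)."""
    return 1 << max(6, (n_samples - 1).bit_length())


def compute_mfcc(fragment_samples: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Cepstral coefficients of a single fragment (length ``n_coeffs``)."""
    return compute_mfcc_batch(np.atleast_2d(np.asarray(fragment_samples)), config)[0]


def compute_mfcc_batch(
    fragments: np.ndarray, config: FeatureConfig | None = None
) -> np.ndarray:
    """Cepstral coefficients for an (n_fragments, n_samples) matrix.

    The whole 6-ms fragment is treated as one analysis frame (one feature
    vector per fragment).  All-zero fragments produce finite coefficients
    via the log floor.
    """
    if config is None:
        config = FeatureConfig()
    fragments = np.asarray(fragments, dtype=np.float64)
    if fragments.ndim != 2:
        raise ValueError("fragments must be a 2-D matrix")
    n = fragments.shape[1]
    if n < 64:
        raise ValueError(f"fragment length {n} < 64 samples")
    n_fft = _n_fft_for(n)
    window = hann(n, sym=False)
    spectrum = np.abs(rfft(fragments * window, n=n_fft, axis=1))
    fb = mel_filterbank(
        config.f_low, config.f_high, config.n_mel_filters, n_fft, config.rate
    )
    energies = spectrum @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    cepstra = dct(log_e, type=2, norm="ortho", axis=1)
    if config.include_c0:
        return cepstra[:, : config.n_coeffs]
    return cepstra[:, 1 : config.n_coeffs + 1]


def featurize_usfs(usfs: list[USF], config: FeatureConfig | None = None) -> np.ndarray:
    """Fill ``usf.feature`` for every USF; returns the (N, n_coeffs) matrix."""
    if config is None:
        config = FeatureConfig()
    if not usfs:
        return np.empty((0, config.n_coeffs))
    mat = compute_mfcc_batch(np.stack([u.samples for u in usfs]), config)
    for u, row in zip(usfs, mat):
        u.feature = row
    return mat


def features_matrix(usfs: list[USF]) -> np.ndarray:
    """Stack previously computed per-USF feature vectors."""
    if not usfs:
        raise ValueError("no USFs")
    if any(u.feature is None for u in usfs):
        raise ValueError("some USFs have no feature vector; run featurize_usfs")
    return np.stack([u.feature for u in usfs])
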