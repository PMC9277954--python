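"""Spectrograms, PSDs, cluster means, group scaling, peak frequencies."""

import numpy as np
import pytest

from usvkit.audio_io import AudioClip
from usvkit.detection import USF
from usvkit.embedding import ClusterModel, suggest_noise_clusters
from usvkit.spectral import (
    PSD,
    SpectralConfig,
    cluster_mean_psd,
    cluster_mean_psds,
    group_scaled_psd,
    overlay_usfs,
    psd_peak_frequency,
    spectrogram,
    usf_psd,
)

BIN_HZ = 250_000 / 512


def make_usf(samples, cluster=1, clip_id="c", index=0):
    return USF(
        clip_id=clip_id, index=index, start_time=0.006 * index,
        power=1.0, samples=np.asarray(samples, dtype=float), cluster=cluster,
    )


def tone(freq, n=1500, amplitude=0.5, rate=250_000):
    return amplitude * np.sin(2 * np.pi * freq * np.arange(n) / rate)


class TestSpectrogram:
    def test_bin_spacing_at_defaults(self):
        cfg = SpectralConfig()
        assert cfg.bin_spacing == pytest.approx(488.28, abs=0.01)
        freqs, _, _ = spectrogram(AudioClip("t", tone(40_000, 25_000), 250_000), cfg)
        assert np.diff(freqs)[0] == pytest.approx(cfg.bin_spacing)

    def test_tone_argmax_at_nearest_bin(self, tone_clip):
        clip = tone_clip(40_000)
        freqs, times, sxx = spectrogram(clip)
        nearest = freqs[np.argmin(np.abs(freqs - 40_000))]
        for col in range(sxx.shape[1]):
            assert freqs[np.argmax(sxx[:, col])] == pytest.approx(nearest)

    def test_silence_floor(self):
        clip = AudioClip("s", np.zeros(25_000), 250_000)
        _, _, sxx = spectrogram(clip)
        assert np.all(sxx == 0)

    def test_too_short_clip(self):
        with pytest.raises(ValueError, match="window"):
            spectrogram(AudioClip("s", np.zeros(100), 250_000))


class TestUsfPsd:
    def test_tone_peak_within_one_bin(self):
        psd = usf_psd(tone(60_000))
        assert abs(psd_peak_frequency(psd) - 60_000) <= BIN_HZ

    def test_zero_fragment_zero_density(self):
        psd = usf_psd(np.zeros(1500))
        assert np.all(psd.density == 0)

    def test_two_tone_local_maxima(self):
        psd = usf_psd(tone(30_000) + tone(70_000))
        d, f = psd.density, psd.freqs
        for target in (30_000, 70_000):
            window = (f > target - 3 * BIN_HZ) & (f < target + 3 * BIN_HZ)
            assert d[window].max() > 100 * np.median(d[(f > 15_000) & (f < 100_000)])

    def test_fragment_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            usf_psd(np.zeros(400))


class TestClusterMeanPsd:
    def test_identical_members_mean_equals_single(self):
        usfs = [make_usf(tone(50_000), index=i) for i in range(3)]
        mean = cluster_mean_psd(usfs, 1)
        single = usf_psd(usfs[0].samples)
        np.testing.assert_allclose(mean.density, single.density)
        assert mean.n_usfs == 3

    def test_linearity(self):
        x = tone(50_000)
        usfs = [make_usf(x, index=0), make_usf(np.sqrt(3) * x, index=1)]
        mean = cluster_mean_psd(usfs, 1)
        d = usf_psd(x).density
        np.testing.assert_allclose(mean.density, 2 * d, rtol=1e-9)

    def test_weighted_mean_identity(self):
        """Count-weighted mean of cluster means equals the grand mean."""
        rng = np.random.default_rng(8)
        usfs = [
            make_usf(rng.normal(0, 0.1, 1500), cluster=c, index=i)
            for i, c in enumerate([1] * 5 + [2] * 9)
        ]
        model = ClusterModel(labels=np.array([u.cluster for u in usfs]))
        psds = cluster_mean_psds(usfs, model)
        weighted = sum(p.density * p.n_usfs for p in psds.values()) / 14
        from usvkit.spectral import usf_psd_matrix

        _, all_d = usf_psd_matrix(usfs)
        np.testing.assert_allclose(weighted, all_d.mean(axis=0), rtol=1e-9)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="no USFs"):
            cluster_mean_psd([make_usf(tone(50_000))], 7)


class TestGroupScaledPsd:
    def test_single_cluster_identity(self):
        psd = usf_psd(tone(50_000))
        out = group_scaled_psd([psd], [1])
        np.testing.assert_allclose(out.density, psd.density)

    def test_zero_count_cluster_ignored(self):
        p1, p2 = usf_psd(tone(30_000)), usf_psd(tone(60_000))
        out = group_scaled_psd([p1, p2], [0, 5])
        np.testing.assert_allclose(out.density, 5 * p2.density)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            group_scaled_psd([], [])


class TestPsdPeakFrequency:
    def test_tone_47khz(self):
        peak = psd_peak_frequency(usf_psd(tone(47_000)))
        assert abs(peak - 47_000) <= BIN_HZ

    def test_flat_density_tie_breaks_low(self):
        psd = PSD(freqs=np.arange(10.0), density=np.ones(10))
        assert psd_peak_frequency(psd) == 0.0

    def test_scale_invariance(self):
        psd = usf_psd(tone(47_000))
        scaled = PSD(psd.freqs, 7.3 * psd.density)
        assert psd_peak_frequency(scaled) == psd_peak_frequency(psd)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            psd_peak_frequency(PSD(np.arange(4.0), np.zeros(4)))


class TestOverlay:
    def test_markers_match_usfs(self, tone_clip):
        clip = tone_clip(40_000, duration=0.5)
        usfs = [make_usf(tone(40_000), cluster=9, index=50, clip_id="tone")]
        ov = overlay_usfs(clip, usfs)
        assert len(ov.markers) == 1
        assert ov.markers.iloc[0]["start_time_s"] == pytest.approx(0.3)
        assert ov.markers.iloc[0]["cluster"] == 9

    def test_no_usfs_bare_spectrogram(self, tone_clip):
        ov = overlay_usfs(tone_clip(40_000), [])
        assert len(ov.markers) == 0
        assert ov.power.size > 0

    def test_foreign_clip_rejected(self, tone_clip):
        with pytest.raises(ValueError, match="other clips"):
            overlay_usfs(tone_clip(40_000), [make_usf(tone(40_000), clip_id="zzz")])


class TestNoiseHeuristic:
    def test_flat_noise_cluster_suggested_tonal_not(self):
        """Broadband clusters lack a prominent PSD peak; tonal ones have it."""
        rng = np.random.default_rng(9)
        tonal = [make_usf(tone(50_000) + rng.normal(0, 0.001, 1500), cluster=1, index=i)
                 for i in range(10)]
        noise = [make_usf(rng.normal(0, 0.05, 1500), cluster=2, index=10 + i)
                 for i in range(10)]
        usfs = tonal + noise
        model = ClusterModel(labels=np.array([u.cluster for u in usfs]))
        psds = cluster_mean_psds(usfs, model)
        suggested = suggest_noise_clusters(psds)
        assert 2 in suggested
        assert 1 not in suggested
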