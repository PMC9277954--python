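"""Vicinity curves, repeatability half-width, session counts, Pearson."""

import numpy as np
import pytest

from usvkit.detection import USF
from usvkit.temporal import (
    FRAGMENT_S,
    VicinityCurve,
    pearson,
    repeatability_halfwidth,
    session_counts,
    vicinity_curve,
)


def usf_at(index, cluster=1, session="s1", clip="c1"):
    return USF(
        clip_id=clip, index=index, start_time=index * FRAGMENT_S, power=1.0,
        samples=np.zeros(4), cluster=cluster, session_id=session,
    )


def vicinity_oracle(focal_indices, other_indices, same, n_bins=83):
    """Pairwise lag enumeration: prob[k] = fraction of focal with a partner."""
    lags = np.arange(-n_bins, n_bins + 1)
    prob = np.zeros(lags.size)
    others = set(other_indices)
    for i in focal_indices:
        for j, k in enumerate(lags):
            if same and k == 0:
                continue
            if i + k in others:
                prob[j] += 1
    return prob / len(focal_indices)


class TestVicinityCurve:
    def test_isolated_focal_all_zero(self):
        curve = vicinity_curve([usf_at(100)], 1, 1)
        assert np.all(curve.prob == 0)
        assert curve.n_focal == 1

    def test_pair_12ms_apart(self):
        """Two same-cluster USFs 12 ms apart light up only the +-12 ms bins.

        Each focal fragment sees its partner at one signed lag, so with two
        focal fragments the mean indicator is 0.5 at each of +-12 ms.
        """
        usfs = [usf_at(100), usf_at(102)]
        curve = vicinity_curve(usfs, 1, 1)
        hit = curve.prob > 0
        np.testing.assert_allclose(
            np.sort(curve.lags[hit]), [-0.012, 0.012], atol=1e-12
        )
        np.testing.assert_allclose(curve.prob[hit], [0.5, 0.5])

    def test_symmetry_same_cluster(self):
        rng = np.random.default_rng(10)
        usfs = [usf_at(int(i)) for i in rng.choice(500, 40, replace=False)]
        curve = vicinity_curve(usfs, 1, 1)
        np.testing.assert_allclose(curve.prob, curve.prob[::-1])

    def test_matches_pairwise_enumeration_oracle(self):
        """200-event stream: curve equals brute-force lag enumeration."""
        rng = np.random.default_rng(11)
        indices = np.sort(rng.choice(3000, 200, replace=False))
        clusters = rng.integers(1, 4, 200)
        usfs = [usf_at(int(i), cluster=int(c)) for i, c in zip(indices, clusters)]
        for focal in (1, 2, 3):
            for other in (1, 2, 3):
                curve = vicinity_curve(usfs, focal, other)
                expected = vicinity_oracle(
                    indices[clusters == focal],
                    indices[clusters == other],
                    same=focal == other,
                )
                np.testing.assert_allclose(curve.prob, expected)

    def test_missing_focal_label_rejected(self):
        with pytest.raises(ValueError, match="label 5"):
            vicinity_curve([usf_at(0)], 5, 1)

    def test_probabilities_bounded(self):
        usfs = [usf_at(i) for i in range(50)]
        curve = vicinity_curve(usfs, 1, 1)
        assert np.all((curve.prob >= 0) & (curve.prob <= 1))


class TestRepeatabilityHalfwidth:
    def make_curve(self, prob_by_lag):
        lags = np.arange(-83, 84) * FRAGMENT_S
        prob = np.zeros(lags.size)
        for k, p in prob_by_lag.items():
            prob[k + 83] = p
        return VicinityCurve(1, 1, lags, prob, n_focal=10)

    def test_single_bin_each_side_gives_12ms(self):
        curve = self.make_curve({-1: 1.0, 1: 1.0})
        assert repeatability_halfwidth(curve) == pytest.approx(12.0)

    def test_scale_invariance(self):
        a = self.make_curve({-2: 0.4, -1: 0.8, 1: 0.8, 2: 0.4})
        b = self.make_curve({-2: 0.2, -1: 0.4, 1: 0.4, 2: 0.2})
        assert repeatability_halfwidth(a) == pytest.approx(repeatability_halfwidth(b))

    def test_wider_peak_wider_halfwidth(self):
        narrow = self.make_curve({-1: 1.0, 1: 1.0})
        wide = self.make_curve({k: 1.0 for k in range(-10, 11) if k != 0})
        assert repeatability_halfwidth(wide) > repeatability_halfwidth(narrow)

    def test_long_calls_wider_than_short(self):
        """Calls spanning many fragments widen the repeatability peak."""

        def session(call_frag_count, n_calls, gap=100):
            usfs = []
            start = 0
            for _ in range(n_calls):
                usfs += [usf_at(start + j) for j in range(call_frag_count)]
                start += call_frag_count + gap
            return usfs

        long_curve = vicinity_curve(session(50, 6), 1, 1)   # 300-ms calls
        short_curve = vicinity_curve(session(5, 6), 1, 1)   # 30-ms calls
        hw_long = repeatability_halfwidth(long_curve)
        hw_short = repeatability_halfwidth(short_curve)
        assert hw_long > hw_short
        assert hw_short == pytest.approx(30.0, abs=12.0)
        assert hw_long == pytest.approx(300.0, abs=30.0)

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError, match="peak"):
            repeatability_halfwidth(self.make_curve({}))


class TestSessionCounts:
    def test_noise_only_session_total_zero(self):
        usfs = [usf_at(i, cluster=1) for i in range(5)]
        (summary,) = session_counts(usfs, noise_clusters={1})
        assert summary.total == 0
        assert summary.category_total == "low"

    def test_total_categorization(self):
        usfs = [usf_at(i, cluster=5) for i in range(300)] + [
            usf_at(1000 + i, cluster=9) for i in range(350)
        ]
        (summary,) = session_counts(usfs)
        assert summary.counts == {5: 300, 9: 350}
        assert summary.total == 650
        assert summary.category_total == "high"

    def test_boundary_600_is_low(self):
        usfs = [usf_at(i, cluster=1) for i in range(600)]
        (summary,) = session_counts(usfs)
        assert summary.category_total == "low"

    def test_cluster_category_strict_thresholds(self):
        usfs = [usf_at(i, cluster=1) for i in range(51)] + [
            usf_at(1000 + i, cluster=2) for i in range(10)
        ]
        (summary,) = session_counts(usfs)
        assert summary.category_per_cluster[1] == ">50"
        assert summary.category_per_cluster[2] == "<=10"

    def test_unassigned_excluded(self):
        usfs = [usf_at(i, cluster=0) for i in range(10)]
        (summary,) = session_counts(usfs)
        assert summary.total == 0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        xc = x - x.mean()
        y = np.array([1.0, -2.0, 1.0, 0.0])
        y = y - y.mean()
        y -= (y @ xc) / (xc @ xc) * xc
        assert pearson(x, y)["r"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 1.0, 7.0, 6.0, 5.0])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson(x, y)["r"] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])
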