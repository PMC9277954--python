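"""Temporal structure of fragment streams: vicinity, repeatability, counts.

A vicinity curve gives, for fragments of a focal cluster, the probability
that a fragment of another (or the same) cluster starts within each 6-ms lag
bin up to +-0.5 s.  The same-cluster ("repeatability") curve has a central
peak whose full width at half maximum tracks the duration of the underlying
calls: a call lasting n fragments contributes same-cluster neighbors at lags
up to +-(n-1) bins.

Session summaries count non-noise fragments per cluster and categorize
sessions and clusters with the conventional strict thresholds (600 total;
10 and 50 per cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detection import USF

#: Fragment (lag bin) duration in seconds.
FRAGMENT_S = 0.006

#: Lag bins per side: 83 bins of 6 ms cover +-498 ms (0.5 s is not an
#: integer bin multiple).
N_LAG_BINS = 83


@dataclass
class VicinityCurve:
    """Occurrence probability of ``other``-cluster fragments near focal ones.

    ``lags`` holds the exact bin lags in seconds (multiples of the fragment
    duration, symmetric about 0); ``prob[k]`` is the fraction of focal
    fragments with at least one ``other`` fragment at that lag.  The focal
    fragment itself is excluded from its own lag-0 bin.
    """

    focal_label: int
    other_label: int
    lags: np.ndarray
    prob: np.ndarray
    n_focal: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.float64)
        self.prob = np.asarray(self.prob, dtype=np.float64)
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SessionSummary:
    session_id: str
    group: str
    counts: dict[int, int]
    total: int
    category_total: str
    category_per_cluster: dict[int, str]


def vicinity_curve(
    usfs: list[USF],
    focal: int,
    other: int,
    fragment_s: float = FRAGMENT_S,
    n_bins: int = N_LAG_BINS,
) -> VicinityCurve:
    """Vicinity curve for one session's time-ordered labeled USFs."""
    focal_idx = [u.index for u in usfs if u.cluster == focal]
    if not focal_idx:
        raise ValueError(f"no USFs with focal label {focal}")
    other_idx = {u.index for u in usfs if u.cluster == other}
    lags = np.arange(-n_bins, n_bins + 1)
    hits = np.zeros(lags.size, dtype=np.float64)
    for i in focal_idx:
        for j, k in enumerate(lags):
            if k == 0 and focal == other:
                # self-exclusion: a co-occurring *different* fragment cannot
                # exist at the same index within one session
                continue
            if i + k in other_idx:
                hits[j] += 1.0
    prob = hits / len(focal_idx)
    return VicinityCurve(
        focal_label=focal,
        other_label=other,
        lags=lags * fragment_s,
        prob=prob,
        n_focal=len(focal_idx),
    )


def repeatability_halfwidth(curve: VicinityCurve) -> float:
    """Full width at half maximum of the central peak, in milliseconds.

    Each lag bin is treated as a 6-ms interval; the curve is linearly
    interpolated between bin interval centers (the bin at lag k*6 ms covers
    ((k-1)*6, k*6] ms and has its center at (k-0.5)*6 ms).  The peak is the
    larger of the two innermost bins; the width is the distance between the
    first half-maximum crossings on either side of zero.  A curve that is
    1 at +-6 ms only therefore has half-width 12 ms.
    """
    if curve.lags.size < 3:
        raise ValueError("curve too short")
    center = curve.lags.size // 2
    bin_ms = float(np.diff(curve.lags).mean()) * 1000.0
    p_pos = curve.prob[center + 1 :]
    p_neg = curve.prob[center - 1 :: -1]
    peak = max(p_pos[0], p_neg[0])
    if peak <= 0:
        raise ValueError("repeatability curve has no positive peak")
    half = peak / 2.0

    def crossing(p_side: np.ndarray) -> float:
        # virtual point at lag 0 with the peak value anchors the descent
        xs = np.concatenate([[0.0], (np.arange(1, p_side.size + 1) - 0.5) * bin_ms])
        ys = np.concatenate([[peak], p_side])
        below = np.flatnonzero(ys < half)
        if below.size == 0:
            return xs[-1]
        j = below[0]
        x0, x1, y0, y1 = xs[j - 1], xs[j], ys[j - 1], ys[j]
        return x0 + (y0 - half) / (y0 - y1) * (x1 - x0)

    return crossing(p_pos) + crossing(p_neg)


def repeatability_curves(
    usfs_by_session: dict[str, list[USF]], labels: list[int]
) -> dict[int, VicinityCurve]:
    """Pooled same-cluster vicinity curve per label across sessions.

    Sessions are pooled by averaging per-session curves weighted by their
    focal counts (equivalent to treating all focal fragments as one sample
    while never pairing fragments across sessions).
    """
    out: dict[int, VicinityCurve] = {}
    for label in labels:
        total_hits = None
        total_focal = 0
        lags = None
        for usfs in usfs_by_session.values():
            if not any(u.cluster == label for u in usfs):
                continue
            c = vicinity_curve(usfs, label, label)
            if total_hits is None:
                total_hits = c.prob * c.n_focal
                lags = c.lags
            else:
                total_hits += c.prob * c.n_focal
            total_focal += c.n_focal
        if total_focal > 0:
            out[label] = VicinityCurve(
                focal_label=label,
                other_label=label,
                lags=lags,
                prob=total_hits / total_focal,
                n_focal=total_focal,
            )
    return out


def _cluster_category(count: int, bins: tuple[int, int] = (10, 50)) -> str:
    lo, hi = bins
    if count > hi:
        return f">{hi}"
    if count > lo:
        return f"{lo + 1}-{hi}"
    return f"<={lo}"


def session_counts(
    usfs: list[USF],
    noise_clusters: set[int] | None = None,
    total_threshold: int = 600,
    cluster_bins: tuple[int, int] = (10, 50),
) -> list[SessionSummary]:
    """Per-session, per-cluster USF counts with categorical summaries.

    Noise clusters and unassigned fragments (label 0) are excluded.  The
    session total is categorized "high" strictly above ``total_threshold``
    and "low" otherwise (the boundary value falls in "low"); per-cluster
    counts are binned with the strict thresholds in ``cluster_bins``.
    """
    noise_clusters = noise_clusters or set()
    sessions: dict[str, list[USF]] = {}
    for u in usfs:
        sessions.setdefault(u.session_id, []).append(u)
    summaries = []
    for session_id in sorted(sessions):
        members = sessions[session_id]
        counts: dict[int, int] = {}
        for u in members:
            if u.cluster > 0 and u.cluster not in noise_clusters:
                counts[u.cluster] = counts.get(u.cluster, 0) + 1
        total = sum(counts.values())
        summaries.append(
            SessionSummary(
                session_id=session_id,
                group=members[0].group,
                counts=counts,
                total=total,
                category_total="high" if total > total_threshold else "low",
                category_per_cluster={
                    c: _cluster_category(n, cluster_bins) for c, n in counts.items()
                },
            )
        )
    return summaries


def pearson(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Pearson product-moment correlation with r^2 and two-sided p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "r_squared": float(r**2), "p": float(p)}


def sessions_frame(summaries: list[SessionSummary]) -> pd.DataFrame:
    """Tidy one-row-per-(session, cluster) DataFrame of SessionSummary data."""
    rows = []
    for s in summaries:
        if not s.counts:
            rows.append(
                {
                    "session_id": s.session_id, "group": s.group, "cluster": 0,
                    "count": 0, "total": s.total, "category_total": s.category_total,
                    "category_cluster": "",
                }
            )
        for c in sorted(s.counts):
            rows.append(
                {
                    "session_id": s.session_id, "group": s.group, "cluster": c,
                    "count": s.counts[c], "total": s.total,
                    "category_total": s.category_total,
                    "category_cluster": s.category_per_cluster[c],
                }
            )
    return pd.DataFrame(rows)
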