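"""3-D t-SNE embedding of pooled fragment features and cluster assignment.

Fragments from all clips of an experiment are embedded together so that
spectrally similar fragments land near each other; clusters are then cut out
of the embedding either by DBSCAN (density clustering with outlier label 0)
or by user-supplied convex regions.  Clusters judged to contain non-vocal
signal (cage noise, impacts) can be flagged and are excluded from every
downstream count, spectral and temporal analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """Barnes-Hut t-SNE settings; ``out_dims`` is fixed at 3."""

    perplexity: float = 500.0
    theta: float = 0.5
    seed: int = 0
    out_dims: int = 3


@dataclass
class ClusterConfig:
    """DBSCAN settings in embedding space (Euclidean distance)."""

    eps: float = 1.5
    min_pts: int = 50

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class ClusterModel:
    """Per-point labels plus bookkeeping.

    Label 0 marks density outliers / unassigned points; positive labels are
    renumbered 1..K by descending cluster size.  ``noise_clusters`` holds
    labels flagged as non-vocal noise, to be excluded downstream.
    """

    labels: np.ndarray
    noise_clusters: set[int] = field(default_factory=set)
    core_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        observed = set(np.unique(self.labels).tolist())
        unknown = self.noise_clusters - observed
        if unknown:
            raise ValueError(f"noise labels not observed: {sorted(unknown)}")

    @property
    def cluster_labels(self) -> list[int]:
        """Positive labels, ascending (i.e. descending size)."""
        return sorted(int(c) for c in np.unique(self.labels) if c > 0)

    @property
    def vocal_labels(self) -> list[int]:
        """Positive labels not flagged as noise."""
        return [c for c in self.cluster_labels if c not in self.noise_clusters]

    def sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}


def effective_perplexity(n_points: int, perplexity: float) -> float:
    """Auto-reduce perplexity to floor((N-1)/3) for small inputs."""
    if n_points <= 3 * perplexity + 1:
        reduced = float((n_points - 1) // 3)
        logger.warning(
            "perplexity %g too large for N=%d; reduced to %g",
            perplexity, n_points, reduced,
        )
        return reduced
    return perplexity


def embed_tsne(features: np.ndarray, config: EmbeddingConfig | None = None) -> np.ndarray:
    """Embed an (N, d) feature matrix into (N, 3) with Barnes-Hut t-SNE.

    Deterministic for a fixed ``config.seed``.  Requires N >= 10.
    """
    if config is None:
        config = EmbeddingConfig()
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 points for t-SNE, got {n}")
    perplexity = effective_perplexity(n, config.perplexity)
    tsne = TSNE(
        n_components=config.out_dims,
        perplexity=perplexity,
        method="barnes_hut",
        angle=config.theta,
        init="pca",
        random_state=config.seed,
    )
    coords = tsne.fit_transform(features)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return coords


def _renumber_by_size(raw: np.ndarray) -> np.ndarray:
    """Map raw non-negative labels (0 = outlier) to 1..K by descending size."""
    labels = np.zeros_like(raw)
    positive = [l for l in np.unique(raw) if l > 0]
    order = sorted(positive, key=lambda l: (-(raw == l).sum(), l))
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    return labels


def cluster_dbscan(
    embedding: np.ndarray, config: ClusterConfig | None = None
) -> ClusterModel:
    """DBSCAN on embedding coordinates; outliers get label 0.

    Core-point labels are order-invariant; border points may flip between
    adjacent clusters under permutation (standard DBSCAN behavior).
    """
    if config is None:
        config = ClusterConfig()
    embedding = np.asarray(embedding, dtype=np.float64)
    db = DBSCAN(eps=config.eps, min_samples=config.min_pts).fit(embedding)
    raw = db.labels_ + 1  # sklearn outliers are -1
    labels = _renumber_by_size(raw)
    core = np.zeros(len(labels), dtype=bool)
    core[db.core_sample_indices_] = True
    return ClusterModel(labels=labels, core_mask=core)


def assign_manual_regions(
    embedding: np.ndarray, regions: list[tuple[int, np.ndarray]]
) -> ClusterModel:
    """Label points by membership in convex regions (vertex lists).

    ``regions`` is an ordered list of (label, vertices) pairs; a point inside
    several regions takes the first matching region's label; points in no
    region get label 0.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.zeros(embedding.shape[0], dtype=int)
    unassigned = np.ones(embedding.shape[0], dtype=bool)
    for label, vertices in regions:
        if label <= 0:
            raise ValueError(f"region labels must be positive, got {label}")
        vertices = np.asarray(vertices, dtype=np.float64)
        if vertices.ndim != 2 or vertices.shape[1] != embedding.shape[1]:
            raise ValueError("region vertices must match embedding dimension")
        try:
            hull = Delaunay(vertices)
        except Exception as exc:
            raise ValueError(f"malformed region geometry for label {label}: {exc}")
        inside = hull.find_simplex(embedding) >= 0
        take = inside & unassigned
        labels[take] = label
        unassigned &= ~take
    return ClusterModel(labels=labels)


def flag_noise(model: ClusterModel, labels: set[int]) -> ClusterModel:
    """Return a copy of the model with ``labels`` flagged as noise clusters."""
    observed = set(np.unique(model.labels).tolist())
    unknown = set(labels) - observed
    if unknown:
        raise ValueError(f"cannot flag unobserved labels: {sorted(unknown)}")
    return replace(model, noise_clusters=model.noise_clusters | set(labels))


def suggest_noise_clusters(
    cluster_psds: dict[int, "object"], min_peak_fraction: float = 0.05
) -> set[int]:
    """Advisory heuristic: clusters whose mean PSD lacks a well-defined peak.

    Vocal clusters concentrate power around a carrier frequency, so the
    maximal PSD bin holds a substantial fraction of total band power;
    broadband noise spreads power over hundreds of bins.  A cluster is
    suggested as noise when its peak bin holds less than
    ``min_peak_fraction`` of the total band power.  Advisory only —
    flagging remains the caller's decision.
    """
    suggested = set()
    for label, psd in cluster_psds.items():
        d = np.asarray(psd.density, dtype=float)
        total = d.sum()
        if total <= 0 or d.max() / total < min_peak_fraction:
            suggested.add(label)
    return suggested
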