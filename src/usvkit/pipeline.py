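"""End-to-end orchestration: clips in, tabular artifacts out.

``analyze_clips`` runs detection -> featurization -> pooled embedding ->
clustering -> spectral/temporal summaries on in-memory clips;
``run_pipeline`` wraps it with manifest reading, per-clip error handling and
CSV output.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .audio_io import AudioClip, load_clip, read_manifest
from .detection import DetectionConfig, USF, detect_usfs
from .embedding import (
    ClusterConfig,
    ClusterModel,
    EmbeddingConfig,
    assign_manual_regions,
    cluster_dbscan,
    embed_tsne,
    flag_noise,
)
from .features import FeatureConfig, featurize_usfs
from .spectral import PSD, SpectralConfig, cluster_mean_psds, group_scaled_psd
from .temporal import (
    SessionSummary,
    VicinityCurve,
    repeatability_curves,
    repeatability_halfwidth,
    session_counts,
    sessions_frame,
)
from .validation import CallAnnotation, ValidationReport, read_annotations, score

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage configurations plus the global seed.

    Defaults follow the standard parameterization: 6-ms fragments, 15-kHz
    high-pass, 16 coefficients over 15-100 kHz, perplexity 500, DBSCAN
    eps 1.5 / minPts 50, 512-sample windows at 50% overlap.
    """

    analysis_rate: int = 250_000
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    cluster_mode: str = "dbscan"
    manual_regions: list | None = None
    noise_clusters: set[int] = field(default_factory=set)
    total_threshold: int = 600
    cluster_bins: tuple[int, int] = (10, 50)

    def __post_init__(self) -> None:
        # the embedding seed follows the global seed unless set explicitly
        self.embedding.seed = self.seed if self.embedding.seed == 0 else self.embedding.seed
        if self.cluster_mode not in ("dbscan", "manual"):
            raise ValueError(f"unknown cluster_mode {self.cluster_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_clusters"] = sorted(self.noise_clusters)
        d["cluster_bins"] = list(self.cluster_bins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("detection", DetectionConfig),
            ("features", FeatureConfig),
            ("embedding", EmbeddingConfig),
            ("cluster", ClusterConfig),
            ("spectral", SpectralConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "noise_clusters" in d:
            d["noise_clusters"] = set(d["noise_clusters"])
        if "cluster_bins" in d:
            d["cluster_bins"] = tuple(d["cluster_bins"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    usfs: list[USF]
    model: ClusterModel | None
    features: np.ndarray
    embedding: np.ndarray | None
    cluster_psds: dict[int, PSD]
    group_psds: dict[str, PSD]
    summaries: list[SessionSummary]
    repeatability: dict[int, VicinityCurve]
    halfwidths: dict[int, float]
    validation: ValidationReport | None = None


def apply_labels(usfs: list[USF], model: ClusterModel) -> None:
    """Write cluster labels from a model back onto USFs (in model order)."""
    if len(usfs) != len(model.labels):
        raise ValueError("model label count does not match USF count")
    for u, l in zip(usfs, model.labels):
        u.cluster = int(l)


STAGES = ("detect", "features", "embed", "cluster", "all")


def _partial_result(usfs, feats=None, emb=None, model=None) -> "PipelineResult":
    return PipelineResult(
        usfs=usfs, model=model,
        features=feats if feats is not None else np.empty((len(usfs), 0)),
        embedding=emb, cluster_psds={}, group_psds={}, summaries=[],
        repeatability={}, halfwidths={},
    )


def analyze_clips(
    clips: list[AudioClip],
    config: PipelineConfig | None = None,
    annotations: list[CallAnnotation] | None = None,
    stage: str = "all",
) -> PipelineResult:
    """Run the analysis on in-memory clips, optionally stopping at a stage."""
    if config is None:
        config = PipelineConfig()
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    usfs: list[USF] = []
    for clip in clips:
        usfs.extend(detect_usfs(clip, config.detection))
    logger.info("detected %d USFs in %d clips", len(usfs), len(clips))
    if stage == "detect":
        return _partial_result(usfs)

    feats = featurize_usfs(usfs, config.features)
    if stage == "features":
        return _partial_result(usfs, feats)
    model = None
    emb = None
    if len(usfs) >= 10:
        emb = embed_tsne(feats, config.embedding)
        for u, e in zip(usfs, emb):
            u.embedding = e
        if stage == "embed":
            return _partial_result(usfs, feats, emb)
        if config.cluster_mode == "manual" and config.manual_regions:
            regions = [
                (int(label), np.asarray(verts, dtype=float))
                for label, verts in config.manual_regions
            ]
            model = assign_manual_regions(emb, regions)
        else:
            model = cluster_dbscan(emb, config.cluster)
        apply_labels(usfs, model)
        if config.noise_clusters:
            model = flag_noise(
                model, config.noise_clusters & set(np.unique(model.labels).tolist())
            )
    else:
        logger.warning("only %d USFs; skipping embedding and clustering", len(usfs))
    if stage == "cluster":
        return _partial_result(usfs, feats, emb, model)

    cluster_psds: dict[int, PSD] = {}
    group_psds: dict[str, PSD] = {}
    summaries: list[SessionSummary] = []
    curves: dict[int, VicinityCurve] = {}
    halfwidths: dict[int, float] = {}
    if model is not None and model.cluster_labels:
        cluster_psds = cluster_mean_psds(usfs, model, config.spectral)
        vocal = model.vocal_labels
        for group in sorted({u.group for u in usfs}):
            counts = [
                sum(1 for u in usfs if u.group == group and u.cluster == l)
                for l in vocal
            ]
            if vocal and sum(counts) > 0:
                group_psds[group] = group_scaled_psd(
                    [cluster_psds[l] for l in vocal], counts
                )
        summaries = session_counts(
            usfs, model.noise_clusters, config.total_threshold, config.cluster_bins
        )
        by_session: dict[str, list[USF]] = {}
        for u in usfs:
            by_session.setdefault(u.session_id, []).append(u)
        curves = repeatability_curves(by_session, vocal)
        for l, c in curves.items():
            try:
                halfwidths[l] = repeatability_halfwidth(c)
            except ValueError:
                logger.warning("cluster %d has no repeatability peak", l)

    report = None
    if annotations is not None:
        noise = model.noise_clusters if model else set()
        vocal_usfs = [u for u in usfs if u.cluster not in noise]
        if annotations or vocal_usfs:
            report = score(vocal_usfs, annotations)

    return PipelineResult(
        usfs=usfs, model=model, features=feats, embedding=emb,
        cluster_psds=cluster_psds, group_psds=group_psds, summaries=summaries,
        repeatability=curves, halfwidths=halfwidths, validation=report,
    )


# ---------------------------------------------------------------------------
# CSV artifact writing


def _usf_key_frame(usfs: list[USF]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clip_id": [u.clip_id for u in usfs],
            "start_time_s": [u.start_time for u in usfs],
        }
    )


def write_artifacts(
    result: PipelineResult, outdir: str | Path, config: PipelineConfig
) -> list[Path]:
    """Write all tabular artifacts; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    usfs = result.usfs
    noise = result.model.noise_clusters if result.model else set()
    base = _usf_key_frame(usfs)
    emit(
        "usfs.csv",
        base.assign(
            session_id=[u.session_id for u in usfs],
            group=[u.group for u in usfs],
            power=[u.power for u in usfs],
            cluster=[u.cluster for u in usfs],
            is_noise=[u.cluster in noise for u in usfs],
        ),
    )
    if len(result.features):
        feat_cols = {f"c{i}": result.features[:, i] for i in range(result.features.shape[1])}
        emit("features.csv", base.assign(**feat_cols))
    if result.embedding is not None:
        emit(
            "embedding.csv",
            base.assign(
                x=result.embedding[:, 0],
                y=result.embedding[:, 1],
                z=result.embedding[:, 2],
            ),
        )
    if result.model is not None:
        sizes = result.model.sizes()
        from .spectral import psd_peak_frequency

        rows = []
        for l in result.model.cluster_labels:
            peak = np.nan
            if l in result.cluster_psds:
                try:
                    peak = psd_peak_frequency(result.cluster_psds[l])
                except ValueError:
                    pass
            rows.append(
                {
                    "label": l, "n_usfs": sizes.get(l, 0),
                    "is_noise": l in noise, "peak_freq_hz": peak,
                    "repeatability_halfwidth_ms": result.halfwidths.get(l, np.nan),
                }
            )
        emit("clusters.csv", pd.DataFrame(rows))
    if result.cluster_psds:
        rows = []
        for l, psd in result.cluster_psds.items():
            rows.append(
                pd.DataFrame(
                    {"label": l, "freq_hz": psd.freqs, "density": psd.density,
                     "n_usfs": psd.n_usfs}
                )
            )
        emit("psd_clusters.csv", pd.concat(rows, ignore_index=True))
    if result.group_psds:
        rows = [
            pd.DataFrame(
                {"group": g, "freq_hz": p.freqs, "density": p.density,
                 "n_usfs": p.n_usfs}
            )
            for g, p in result.group_psds.items()
        ]
        emit("group_psd.csv", pd.concat(rows, ignore_index=True))
    if result.summaries:
        emit("sessions.csv", sessions_frame(result.summaries))
    if result.repeatability:
        rows = [
            pd.DataFrame(
                {"focal": c.focal_label, "other": c.other_label,
                 "lag_s": c.lags, "prob": c.prob, "n_focal": c.n_focal}
            )
            for c in result.repeatability.values()
        ]
        emit("vicinity.csv", pd.concat(rows, ignore_index=True))
    if result.validation is not None:
        emit("validation.csv", pd.DataFrame([dataclasses.asdict(result.validation)]))
    config.to_yaml(outdir / "run_config.yaml")
    written.append(outdir / "run_config.yaml")
    return written


def run_pipeline(
    manifest_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    annotations_path: str | Path | None = None,
    stage: str = "all",
) -> int:
    """Run the whole pipeline from a manifest; returns a process exit code.

    0 = success, 1 = configuration error, 2 = completed with skipped clips.
    """
    if config is None:
        config = PipelineConfig()
    try:
        manifest = read_manifest(manifest_path)
    except (ValueError, FileNotFoundError) as exc:
        logger.error("%s", exc)
        return 1
    clips = []
    skipped = 0
    for row in manifest.itertuples():
        try:
            clips.append(
                load_clip(
                    row.path, config.analysis_rate, clip_id=row.clip_id,
                    group=row.group, session_id=row.session_id,
                )
            )
        except (ValueError, FileNotFoundError) as exc:
            logger.error("skipping clip %s: %s", row.clip_id, exc)
            skipped += 1
    if not clips:
        logger.error("no readable clips in manifest")
        return 1
    annotations = read_annotations(annotations_path) if annotations_path else None
    result = analyze_clips(clips, config, annotations, stage=stage)
    write_artifacts(result, outdir, config)
    return 2 if skipped else 0
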