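"""Scoring detections against ground-truth call annotations.

A call is "detected" when at least one fragment interval intersects it;
coverage is the fraction of annotated call time occupied by fragments; a
fragment is a false positive when its interval intersects no call.  Fragment
intervals are half-open, [start, start + 6 ms), so calls touching a
fragment only at the boundary instant do not count as overlapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import USF
from .temporal import FRAGMENT_S, pearson


@dataclass
class CallAnnotation:
    """A ground-truth call interval with its frequency band and type."""

    clip_id: str
    onset: float
    offset: float
    f_low: float
    f_high: float
    call_type: str = ""

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"onset {self.onset} must precede offset {self.offset}")
        if self.f_low <= 0 or self.f_high <= self.f_low:
            raise ValueError("need 0 < f_low < f_high")


@dataclass
class ValidationReport:
    pct_calls_detected: float
    pct_duration_covered: float
    pct_false_positive_usfs: float
    n_calls: int
    n_usfs: int


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _overlap_len(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> float:
    total = 0.0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def score(
    usfs: list[USF],
    annotations: list[CallAnnotation],
    fragment_s: float = FRAGMENT_S,
) -> ValidationReport:
    """Score non-noise USFs against annotated calls, per clip, pooled."""
    if not annotations and not usfs:
        raise ValueError("nothing to score: no USFs and no annotations")

    usf_by_clip: dict[str, list[tuple[float, float]]] = {}
    for u in usfs:
        usf_by_clip.setdefault(u.clip_id, []).append(
            (u.start_time, u.start_time + fragment_s)
        )
    call_by_clip: dict[str, list[CallAnnotation]] = {}
    for a in annotations:
        call_by_clip.setdefault(a.clip_id, []).append(a)

    n_detected = 0
    covered = 0.0
    call_duration = 0.0
    n_false = 0
    for clip_id in set(usf_by_clip) | set(call_by_clip):
        frags = sorted(usf_by_clip.get(clip_id, []))
        calls = call_by_clip.get(clip_id, [])
        call_iv = _merge_intervals([(a.onset, a.offset) for a in calls])
        for a in calls:
            if any(f_lo < a.offset and f_hi > a.onset for f_lo, f_hi in frags):
                n_detected += 1
        covered += _overlap_len(frags and _merge_intervals(frags) or [], call_iv)
        call_duration += sum(hi - lo for lo, hi in call_iv)
        for f_lo, f_hi in frags:
            if not any(f_lo < hi and f_hi > lo for lo, hi in call_iv):
                n_false += 1

    n_calls = len(annotations)
    n_usfs = len(usfs)
    return ValidationReport(
        pct_calls_detected=100.0 * n_detected / n_calls if n_calls else 0.0,
        pct_duration_covered=100.0 * covered / call_duration if call_duration else 0.0,
        pct_false_positive_usfs=100.0 * n_false / n_usfs if n_usfs else 0.0,
        n_calls=n_calls,
        n_usfs=n_usfs,
    )


def count_correlation(
    per_clip_usf_counts: np.ndarray, per_clip_call_counts: np.ndarray
) -> dict[str, float]:
    """Pearson correlation between per-clip USF and annotated-call counts."""
    if len(per_clip_usf_counts) < 3:
        raise ValueError("need at least 3 clips")
    return pearson(per_clip_call_counts, per_clip_usf_counts)


ANNOTATION_COLUMNS = ["clip_id", "onset_s", "offset_s", "f_low_hz", "f_high_hz", "call_type"]


def read_annotations(path: str | Path) -> list[CallAnnotation]:
    """Read a call-annotation CSV (clip_id, onset_s, offset_s, f_low_hz, f_high_hz, call_type)."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    if "call_type" not in df.columns:
        df["call_type"] = ""
    return [
        CallAnnotation(
            clip_id=str(r.clip_id), onset=float(r.onset_s), offset=float(r.offset_s),
            f_low=float(r.f_low_hz), f_high=float(r.f_high_hz),
            call_type=str(r.call_type),
        )
        for r in df.itertuples()
    ]


def write_annotations(path: str | Path, annotations: list[CallAnnotation]) -> None:
    pd.DataFrame(
        {
            "clip_id": [a.clip_id for a in annotations],
            "onset_s": [a.onset for a in annotations],
            "offset_s": [a.offset for a in annotations],
            "f_low_hz": [a.f_low for a in annotations],
            "f_high_hz": [a.f_high for a in annotations],
            "call_type": [a.call_type for a in annotations],
        }
    ).to_csv(path, index=False)
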