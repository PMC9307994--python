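"""Thin pyranges adapters for the interval arithmetic used internally.

Everything here takes and returns :class:`~regland.genome.GenomicInterval`
lists or plain numpy arrays; pyranges does the sweeping.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .genome import GenomicInterval

__all__ = [
    "to_pyranges",
    "merge_intervals",
    "overlaps_any",
    "aggregate_overlap_scores",
    "min_point_distance",
]


def to_pyranges(intervals: Sequence[GenomicInterval], **extra_cols) -> pr.PyRanges:
    df = pd.DataFrame(
        {
            "Chromosome": [iv.chrom for iv in intervals],
            "Start": [iv.start for iv in intervals],
            "End": [iv.end for iv in intervals],
            "_idx": np.arange(len(intervals)),
        }
    )
    for col, values in extra_cols.items():
        df[col] = values
    return pr.PyRanges(df)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals; overlapping or book-ended inputs are combined."""
    if not intervals:
        return []
    merged = to_pyranges(intervals).merge().df
    merged = merged.sort_values(["Chromosome", "Start"], kind="stable")
    return [
        GenomicInterval(row.Chromosome, int(row.Start), int(row.End))
        for row in merged.itertuples()
    ]


def overlaps_any(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-query flag: does it overlap any subject interval by >= 1 bp."""
    out = np.zeros(len(query), dtype=bool)
    if not len(query) or not len(subject):
        return out
    counts = to_pyranges(query).count_overlaps(to_pyranges(subject)).df
    hit = counts.loc[counts["NumberOverlaps"] > 0, "_idx"].to_numpy()
    out[hit] = True
    return out


def aggregate_overlap_scores(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    how: str = "max",
) -> np.ndarray:
    """Per-query aggregate (max or mean) of overlapping subject scores.

    Queries with no overlap get NaN.
    """
    out = np.full(len(query), np.nan)
    if not len(query) or not len(subject):
        return out
    scores = [iv.score if iv.score is not None else 0.0 for iv in subject]
    joined = to_pyranges(query).join(to_pyranges(subject, _score=scores)).df
    if joined.empty:
        return out
    agg = joined.groupby("_idx")["_score"].agg(how)
    out[agg.index.to_numpy()] = agg.to_numpy()
    return out


def min_point_distance(
    query: Sequence[GenomicInterval], points: dict[str, np.ndarray]
) -> np.ndarray:
    """Distance from each interval's nearest edge to the nearest point.

    Coordinate-gap convention: a point p against interval [s, e) is at
    distance ``max(s - p, p - e, 0)``. Queries on chromosomes with no
    points get +inf.
    """
    out = np.full(len(query), np.inf)
    sorted_points = {c: np.sort(np.asarray(p)) for c, p in points.items()}
    for i, iv in enumerate(query):
        pts = sorted_points.get(iv.chrom)
        if pts is None or len(pts) == 0:
            continue
        j = np.searchsorted(pts, iv.start)
        candidates = pts[max(0, j - 1) : j + 2]
        d = np.maximum.reduce(
            [iv.start - candidates, candidates - iv.end, np.zeros(len(candidates))]
        )
        # a point inside [start, end) gives 0 via the max with zero
        out[i] = d.min()
        inside = (pts >= iv.start) & (pts < iv.end)
        if inside.any():
            out[i] = 0.0
    return out
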