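"""The pCRE catalogue: pooled, extended, exon-filtered H3K27ac intervals
annotated for class, tissue activity, openness and conservation.

Construction mirrors the bedtools slop/merge/intersect recipe used for
the mouse and chicken catalogues: peaks from all tissues are extended
by 660 bp per side (nucleosome occupancy), pooled and merged; intervals
touching an exon are discarded; the rest are promoters when closer than
2 kb to a TSS and enhancers otherwise. A pCRE acetylated in a single
tissue is "specific", in several "pleiotropic"; an active pCRE is
"open" in a tissue when it also overlaps that tissue's ATAC peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._ranges import (
    aggregate_overlap_scores,
    merge_intervals,
    min_point_distance,
    overlaps_any,
)
from .genome import GenomeAssembly, GenomicInterval
from .io import PeakSet

__all__ = [
    "Gene",
    "GeneModel",
    "CREAnnotation",
    "extend_peaks",
    "pool_and_merge",
    "classify_pcres",
    "mark_open",
    "pleiotropy_table",
    "PleiotropyResult",
    "annotations_to_frame",
]

DEFAULT_PAD = 660
PROMOTER_TSS_DISTANCE = 2_000


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    tss: int  # transcriptional start, bp point
    strand: str = "+"
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"exon of {self.name} on wrong chromosome")


@dataclass
class GeneModel:
    """TSS points and exon intervals for one assembly."""

    genes: list[Gene]

    def tss_points(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g.tss)
        return {c: np.array(sorted(v)) for c, v in out.items()}

    def all_exons(self) -> list[GenomicInterval]:
        return [ex for g in self.genes for ex in g.exons]

    @classmethod
    def from_beds(
        cls, tss: Sequence[GenomicInterval], exons: Sequence[GenomicInterval]
    ) -> "GeneModel":
        """Build from a BED of TSS points (1 bp intervals) and a BED of exons.

        Exons are attached to the nearest TSS's gene purely for
        bookkeeping; classification only uses the pooled points/exons.
        """
        genes = [
            Gene(iv.name or f"gene_{i + 1}", iv.chrom, iv.start, iv.strand or "+")
            for i, iv in enumerate(tss)
        ]
        if exons:
            holder = Gene("_exons", exons[0].chrom, exons[0].start, exons=tuple(exons))
            genes.append(holder)
        return cls(genes)


@dataclass
class CREAnnotation:
    """One merged non-coding interval with its regulatory annotation."""

    interval: GenomicInterval
    cre_class: str  # {"enhancer", "promoter"}
    tss_distance: float
    activity: dict[str, tuple[bool, float]] = field(default_factory=dict)
    conserved: bool = False
    open: dict[str, bool] = field(default_factory=dict)

    @property
    def active_tissues(self) -> list[str]:
        return [t for t, (flag, _) in self.activity.items() if flag]

    @property
    def specificity(self) -> str:
        return "pleiotropic" if len(self.active_tissues) > 1 else "specific"


def extend_peaks(
    peaks: PeakSet, pad: int = DEFAULT_PAD, assembly: Optional[GenomeAssembly] = None
) -> PeakSet:
    """Widen every peak by *pad* bp per side, clipped to the chromosome."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    assembly = assembly or peaks.assembly
    out = []
    for pk in peaks:
        hi = assembly.size(pk.chrom) if assembly is not None else None
        end = pk.end + pad if hi is None else min(pk.end + pad, hi)
        out.append(replace(pk, start=max(0, pk.start - pad), end=end))
    return replace(peaks, peaks=out)


def pool_and_merge(
    peaksets: Sequence[PeakSet],
    pad: int = DEFAULT_PAD,
    assembly: Optional[GenomeAssembly] = None,
) -> list[GenomicInterval]:
    """Pool extended peaks from all tissues and merge into disjoint intervals."""
    assemblies = {ps.assembly.name for ps in peaksets if ps.assembly is not None}
    if assembly is not None:
        assemblies.add(assembly.name)
    if len(assemblies) > 1:
        raise ValueError(f"peak sets on mixed assemblies: {sorted(assemblies)}")
    pooled = [
        pk
        for ps in peaksets
        for pk in extend_peaks(ps, pad, assembly or ps.assembly)
    ]
    return merge_intervals(pooled)


def classify_pcres(
    merged: Sequence[GenomicInterval],
    genes: GeneModel,
    tissue_peaks: Mapping[str, PeakSet],
    cnes: Sequence[GenomicInterval] = (),
    tss_distance: int = PROMOTER_TSS_DISTANCE,
) -> list[CREAnnotation]:
    """Annotate merged intervals into the pCRE catalogue.

    Intervals overlapping any exon by >= 1 bp are discarded. Remaining
    intervals are promoters when their nearest edge lies closer than
    *tss_distance* to a TSS point (0 when the TSS is contained) and
    enhancers at *tss_distance* or further. Per tissue, activity is a
    >= 1 bp overlap with that tissue's (extended) peak set and the
    activity score is the maximum overlapping peak score. ``conserved``
    flags overlap with any CNE interval.
    """
    merged = list(merged)
    if not genes.genes:
        warnings.warn("empty gene model: no exon filter, all intervals are enhancers")
    exon_hit = overlaps_any(merged, genes.all_exons())
    kept = [iv for iv, hit in zip(merged, exon_hit) if not hit]
    tss = genes.tss_points()
    dists = min_point_distance(kept, tss)
    conserved = overlaps_any(kept, list(cnes))
    per_tissue = {}
    for tissue, ps in tissue_peaks.items():
        flags = overlaps_any(kept, ps.peaks)
        scores = aggregate_overlap_scores(kept, ps.peaks, how="max")
        per_tissue[tissue] = (flags, scores)
    out = []
    for i, iv in enumerate(kept):
        activity = {
            t: (bool(flags[i]), float(scores[i]) if flags[i] else 0.0)
            for t, (flags, scores) in per_tissue.items()
        }
        out.append(
            CREAnnotation(
                interval=iv,
                cre_class="promoter" if dists[i] < tss_distance else "enhancer",
                tss_distance=float(dists[i]),
                activity=activity,
                conserved=bool(conserved[i]),
            )
        )
    return out


def mark_open(
    annotations: Sequence[CREAnnotation], atac_peaks: Mapping[str, PeakSet]
) -> list[CREAnnotation]:
    """Flag per-tissue openness: active and overlapping that tissue's
    ATAC peaks. Tissues without an ATAC set get no flag at all."""
    per_tissue = {
        tissue: overlaps_any([a.interval for a in annotations], ps.peaks)
        for tissue, ps in atac_peaks.items()
    }
    out = []
    for i, ann in enumerate(annotations):
        open_flags = {
            t: bool(ann.activity.get(t, (False, 0.0))[0] and per_tissue[t][i])
            for t in atac_peaks
            if t in ann.activity
        }
        out.append(replace(ann, open=open_flags))
    return out


@dataclass
class PleiotropyResult:
    """2x2 specificity-by-stratum counts with a Fisher exact test."""

    counts: pd.DataFrame  # rows: strata; columns: specific, pleiotropic
    odds_ratio: float
    p_value: float

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


def pleiotropy_table(
    annotations: Sequence[CREAnnotation], split_by: str = "cre_class"
) -> PleiotropyResult:
    """Test whether pleiotropy differs between two strata of pCREs.

    ``split_by`` is ``"cre_class"`` (enhancer vs promoter) or
    ``"conserved"`` (CNE-overlapping vs not). Uses the two-sided Fisher
    exact test on the 2x2 table of specific/pleiotropic counts.
    """
    if split_by == "cre_class":
        strata = [a.cre_class for a in annotations]
        levels = ["enhancer", "promoter"]
    elif split_by == "conserved":
        strata = ["conserved" if a.conserved else "non_conserved" for a in annotations]
        levels = ["conserved", "non_conserved"]
    else:
        raise ValueError(f"unknown split_by {split_by!r}")
    table = np.zeros((2, 2), dtype=np.int64)
    for stratum, ann in zip(strata, annotations):
        row = levels.index(stratum)
        col = 0 if ann.specificity == "specific" else 1
        table[row, col] += 1
    for lvl, row in zip(levels, table):
        if row.sum() == 0:
            raise ValueError(f"empty stratum {lvl!r}")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    counts = pd.DataFrame(table, index=levels, columns=["specific", "pleiotropic"])
    return PleiotropyResult(counts=counts, odds_ratio=float(odds), p_value=float(p))


def annotations_to_frame(annotations: Sequence[CREAnnotation]) -> pd.DataFrame:
    """Flatten annotations to a table (one row per pCRE) for TSV export."""
    tissues = sorted({t for a in annotations for t in a.activity})
    rows = []
    for a in annotations:
        row = {
            "chrom": a.interval.chrom,
            "start": a.interval.start,
            "end": a.interval.end,
            "cre_class": a.cre_class,
            "tss_distance": a.tss_distance,
            "specificity": a.specificity,
            "conserved": a.conserved,
        }
        for t in tissues:
            flag, score = a.activity.get(t, (False, 0.0))
            row[f"active_{t}"] = flag
            row[f"score_{t}"] = score
            if t in a.open:
                row[f"open_{t}"] = a.open[t]
        rows.append(row)
    return pd.DataFrame(rows)
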