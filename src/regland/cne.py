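"""Cross-species comparison of conserved non-coding element activity.

CNEs are aligned sequence blocks kept only when they overlap no exon in
either species. A CNE is an "enhancer-CNE" in a tissue when it lies at
least 2 kb from every TSS and overlaps that tissue's 660 bp-extended
H3K27ac (or open H3K27ac) peaks; its activity score is the mean of the
overlapping peak scores of that tissue. Per-tissue calls feed a
tissue x CNE activity matrix (the clustering input) and three-set
Euler counts that quantify how often enhancer activity is conserved in
the matching tissue versus redeployed elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._ranges import aggregate_overlap_scores, min_point_distance, overlaps_any
from .cre import DEFAULT_PAD, PROMOTER_TSS_DISTANCE, GeneModel, extend_peaks
from .fourc import RegionPartition
from .genome import GenomeAssembly, GenomicInterval
from .io import PeakSet

__all__ = [
    "CNEPair",
    "EulerCounts",
    "read_cne_pairs",
    "write_cne_pairs",
    "filter_noncoding",
    "call_enhancer_cnes",
    "build_activity_matrix",
    "euler_counts",
    "transpose_partition",
]


@dataclass(frozen=True)
class CNEPair:
    """One aligned non-coding block: linked intervals in two species."""

    id: str
    interval_a: GenomicInterval
    interval_b: GenomicInterval


def read_cne_pairs(path, assembly_a: GenomeAssembly, assembly_b: GenomeAssembly):
    """Read the 7-column pair TSV (id, chromA, startA, endA, chromB, startB, endB)."""
    pairs = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            pid = fields[0]
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate CNE id {pid!r}")
            seen.add(pid)
            iva = GenomicInterval(fields[1], int(fields[2]), int(fields[3]), name=pid)
            ivb = GenomicInterval(fields[4], int(fields[5]), int(fields[6]), name=pid)
            pairs.append(
                CNEPair(pid, iva.validate(assembly_a), ivb.validate(assembly_b))
            )
    return pairs


def write_cne_pairs(pairs: Sequence[CNEPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.interval_a, p.interval_b
            fh.write(
                f"{p.id}\t{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


def filter_noncoding(
    pairs: Sequence[CNEPair],
    exons_a: Sequence[GenomicInterval],
    exons_b: Sequence[GenomicInterval],
) -> list[CNEPair]:
    """Keep pairs overlapping no exon in either species (>= 1 bp discards)."""
    hit_a = overlaps_any([p.interval_a for p in pairs], list(exons_a))
    hit_b = overlaps_any([p.interval_b for p in pairs], list(exons_b))
    return [p for p, ha, hb in zip(pairs, hit_a, hit_b) if not (ha or hb)]


def call_enhancer_cnes(
    pairs: Sequence[CNEPair],
    species: str,
    tissue_peaks: Mapping[str, PeakSet],
    genes: GeneModel,
    pad: int = DEFAULT_PAD,
    tss_min_dist: int = PROMOTER_TSS_DISTANCE,
    assembly: Optional[GenomeAssembly] = None,
) -> dict[str, dict[str, float]]:
    """Per-tissue enhancer-CNE calls with activity scores.

    *species* selects which interval of each pair is tested ("A" or
    "B"). A CNE qualifies in a tissue when its own interval (peaks are
    extended by *pad*, CNEs are not) lies >= *tss_min_dist* from every
    TSS and overlaps >= 1 bp of the tissue's extended peaks; its score
    is the mean of the overlapping peak scores.

    Returns ``{tissue: {cne_id: score}}``.
    """
    if species not in ("A", "B"):
        raise ValueError("species must be 'A' or 'B'")
    ivs = [p.interval_a if species == "A" else p.interval_b for p in pairs]
    ids = [p.id for p in pairs]
    dists = min_point_distance(ivs, genes.tss_points())
    distal = dists >= tss_min_dist
    calls: dict[str, dict[str, float]] = {}
    for tissue, ps in tissue_peaks.items():
        extended = extend_peaks(ps, pad, assembly or ps.assembly)
        flags = overlaps_any(ivs, extended.peaks)
        scores = aggregate_overlap_scores(ivs, extended.peaks, how="mean")
        calls[tissue] = {
            cid: float(scores[i])
            for i, cid in enumerate(ids)
            if flags[i] and distal[i]
        }
    return calls


def build_activity_matrix(
    calls_a: Mapping[str, Mapping[str, float]],
    calls_b: Mapping[str, Mapping[str, float]],
    species_a: str = "mouse",
    species_b: str = "chicken",
) -> pd.DataFrame:
    """Tissue x enhancer-CNE score matrix, the clustering input.

    Rows are species-qualified tissues; one column per CNE active in at
    least one tissue of either species; zeros where inactive. Feed the
    frame directly to any standard agglomerative clustering.
    """
    active = sorted(
        {cid for calls in (calls_a, calls_b) for per in calls.values() for cid in per}
    )
    rows = {}
    for species, calls in ((species_a, calls_a), (species_b, calls_b)):
        for tissue, per in calls.items():
            rows[f"{species}:{tissue}"] = [per.get(cid, 0.0) for cid in active]
    return pd.DataFrame.from_dict(rows, orient="index", columns=active)


@dataclass
class EulerCounts:
    """Three-set overlap structure for one reference tissue.

    A: enhancer-CNEs in the reference tissue of species A;
    B: in the matching tissue of species B;
    C: in any other tissue of species B.
    """

    reference_tissue: str
    matched_tissue: str
    a: int
    b: int
    c: int
    ab: int
    ac: int
    bc: int
    abc: int

    def union(self) -> int:
        return self.a + self.b + self.c - self.ab - self.ac - self.bc + self.abc

    def as_dict(self) -> dict[str, int]:
        return {
            "A": self.a,
            "B": self.b,
            "C": self.c,
            "A&B": self.ab,
            "A&C": self.ac,
            "B&C": self.bc,
            "A&B&C": self.abc,
        }


def euler_counts(
    calls_a: Mapping[str, Mapping[str, float]],
    calls_b: Mapping[str, Mapping[str, float]],
    reference_tissue: str,
    tissue_matching: Mapping[str, str],
) -> EulerCounts:
    """Count enhancer-CNEs conserved in the matching tissue vs redeployed.

    All sets are id sets over the same retained CNE universe, so
    inclusion-exclusion identities hold exactly by construction; they
    are still asserted defensively.
    """
    if reference_tissue not in calls_a:
        raise ValueError(f"reference tissue {reference_tissue!r} absent in species A")
    if reference_tissue not in tissue_matching:
        raise ValueError(f"no tissue matching defined for {reference_tissue!r}")
    matched = tissue_matching[reference_tissue]
    if matched not in calls_b:
        raise ValueError(f"matched tissue {matched!r} absent in species B")
    set_a = set(calls_a[reference_tissue])
    set_b = set(calls_b[matched])
    set_c = set()
    for tissue, per in calls_b.items():
        if tissue != matched:
            set_c.update(per)
    out = EulerCounts(
        reference_tissue=reference_tissue,
        matched_tissue=matched,
        a=len(set_a),
        b=len(set_b),
        c=len(set_c),
        ab=len(set_a & set_b),
        ac=len(set_a & set_c),
        bc=len(set_b & set_c),
        abc=len(set_a & set_b & set_c),
    )
    assert out.union() == len(set_a | set_b | set_c)
    return out


def transpose_partition(
    partition: RegionPartition, pairs: Sequence[CNEPair]
) -> RegionPartition:
    """Lift a region partition to the second species via its anchor CNEs.

    Each anchor's boundary point on species B is the midpoint of the
    matched CNE interval. Anchor order along the landscape must be
    preserved (monotone in either direction; the chicken locus runs on
    an inverted axis relative to mouse).
    """
    by_id = {p.id: p for p in pairs}
    seq: list[str] = [partition.regions[0][2]]
    for _, _, _, right in partition.regions:
        seq.append(right)
    points = []
    for name in seq:
        if name not in by_id:
            raise KeyError(f"anchor CNE {name!r} has no cross-species pair")
        points.append(by_id[name].interval_b.midpoint)
    ascending = all(x < y for x, y in zip(points, points[1:]))
    descending = all(x > y for x, y in zip(points, points[1:]))
    if not (ascending or descending):
        raise ValueError("anchor order is not preserved on the target assembly")
    chrom = by_id[seq[0]].interval_b.chrom
    regions = []
    for i, (name, _, left, right) in enumerate(partition.regions):
        lo, hi = sorted((points[i], points[i + 1]))
        regions.append(
            (name, GenomicInterval(chrom, int(round(lo)), int(round(hi))), left, right)
        )
    return RegionPartition(regions)
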