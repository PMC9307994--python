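"""Fragment-level 4C-seq profile processing and promoter-preference
boundary calling.

A 4C-seq viewpoint profile is a vector of contact scores over the
ordered restriction fragments of a landscape. Processing follows a
fixed order: smooth over a centred window of 11 fragments, normalise
to the mean score within +/-5 Mb of the viewpoint, average biological
replicates, then either subtract two viewpoints or call a boundary.

The boundary between the preference domains of two viewpoints (e.g.
the D1/D4 switch between the Hoxd1 and Hoxd4 contact territories) is
the fragment at which the cumulative sum of the difference of the
within-region rescaled profiles reaches its minimum; the boundary is
then snapped to the nearest anchor CNE so it can be transposed across
species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, GenomicInterval

__all__ = [
    "FourCProfile",
    "AnchorSet",
    "RegionPartition",
    "BoundaryCall",
    "smooth_profile",
    "normalize_profile",
    "average_profiles",
    "subtract_profiles",
    "quantify_regions",
    "boundary_by_cumsum",
    "build_partition",
]

DEFAULT_SMOOTH_FRAGMENTS = 11
DEFAULT_NORM_FLANK = 5_000_000


@dataclass
class FourCProfile:
    """Ordered restriction-fragment scores for one 4C-seq viewpoint.

    ``fragments`` holds columns ``start``, ``end``, ``raw`` and, once
    the corresponding step has run, ``smoothed`` and ``normalized``.
    ``orientation`` states how genomic coordinates map onto the
    landscape: ``"forward"`` if increasing coordinate walks away from
    the gene cluster in reading order, ``"reverse"`` for a locus lying
    on the inverted axis (as the chicken HoxD landscape does).
    """

    viewpoint_name: str
    viewpoint_position: int
    chrom: str
    fragments: pd.DataFrame
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        df = self.fragments
        for col in ("start", "end", "raw"):
            if col not in df.columns:
                raise ValueError(f"fragments missing column {col!r}")
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("fragments must be sorted and non-overlapping")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def midpoints(self) -> np.ndarray:
        df = self.fragments
        return (df["start"].to_numpy() + df["end"].to_numpy()) / 2.0

    def same_grid(self, other: "FourCProfile") -> bool:
        return (
            self.chrom == other.chrom
            and self.n_fragments == other.n_fragments
            and np.array_equal(
                self.fragments["start"].to_numpy(), other.fragments["start"].to_numpy()
            )
            and np.array_equal(
                self.fragments["end"].to_numpy(), other.fragments["end"].to_numpy()
            )
        )

    def scores(self, which: str = "normalized") -> np.ndarray:
        if which not in self.fragments.columns:
            raise ValueError(
                f"profile {self.viewpoint_name!r} has no {which!r} scores yet"
            )
        return self.fragments[which].to_numpy()


@dataclass
class AnchorSet:
    """Named anchor CNEs delimiting candidate region borders."""

    anchors: dict[str, GenomicInterval]

    def __post_init__(self) -> None:
        items = sorted(self.anchors.items(), key=lambda kv: kv[1].start)
        self.anchors = dict(items)

    def __getitem__(self, name: str) -> GenomicInterval:
        return self.anchors[name]

    def __iter__(self):
        return iter(self.anchors)

    def midpoint(self, name: str) -> float:
        return self.anchors[name].midpoint

    def nearest(self, position: float, preference_order: Sequence[str]) -> str:
        """Anchor whose midpoint is closest to *position*.

        Exact distance ties go to the anchor occurring first in
        *preference_order* (the traversal order of the landscape).
        """
        best: Optional[str] = None
        best_d = np.inf
        for name in preference_order:
            d = abs(self.anchors[name].midpoint - position)
            if d < best_d:
                best, best_d = name, d
        assert best is not None
        return best


@dataclass
class RegionPartition:
    """Contiguous named promoter-preference regions between anchors."""

    regions: list[tuple[str, GenomicInterval, str, str]]
    # (name, interval, left_anchor, right_anchor), ordered along the landscape

    def __post_init__(self) -> None:
        ivs = [r[1] for r in self.regions]
        by_coord = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if a.end != b.start:
                raise ValueError(
                    f"regions not contiguous: {a.to_ucsc()} then {b.to_ucsc()}"
                )

    @property
    def names(self) -> list[str]:
        return [r[0] for r in self.regions]

    def interval(self, name: str) -> GenomicInterval:
        for r in self.regions:
            if r[0] == name:
                return r[1]
        raise KeyError(name)

    @property
    def span(self) -> GenomicInterval:
        ivs = [r[1] for r in self.regions]
        return GenomicInterval(
            ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
        )


@dataclass
class BoundaryCall:
    """The called switch point between two viewpoints' territories."""

    viewpoint_a: str
    viewpoint_b: str
    defined: bool
    argmin_fragment: Optional[GenomicInterval] = None
    cumsum_min: float = 0.0
    snapped_anchor: Optional[str] = None
    cumsum: Optional[np.ndarray] = None  # full curve, traversal order


# ---------------------------------------------------------------------------
# profile operations


def smooth_profile(
    p: FourCProfile, window_fragments: int = DEFAULT_SMOOTH_FRAGMENTS
) -> FourCProfile:
    """Running mean of raw scores over a centred fragment window.

    At the profile edges the window shrinks symmetrically (index i uses
    ``min(half, i, n-1-i)`` fragments on each side) so the smoothed
    value is always a mean of an odd, centred set of raw scores.
    """
    if window_fragments < 1 or window_fragments % 2 == 0:
        raise ValueError("window_fragments must be odd and >= 1")
    n = p.n_fragments
    if n < 1:
        raise ValueError("profile has no fragments")
    raw = p.fragments["raw"].to_numpy(dtype=float)
    half = (window_fragments - 1) // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    prefix = np.concatenate([[0.0], np.cumsum(raw)])
    smoothed = (prefix[idx + h + 1] - prefix[idx - h]) / (2 * h + 1)
    df = p.fragments.copy()
    df["smoothed"] = smoothed
    return replace(p, fragments=df)


def normalize_profile(
    p: FourCProfile, flank: int = DEFAULT_NORM_FLANK
) -> FourCProfile:
    """Divide smoothed scores by their mean within +/-*flank* of the
    viewpoint (fragment membership by midpoint)."""
    if "smoothed" not in p.fragments.columns:
        p = smooth_profile(p, 1)  # normalisation of an unsmoothed profile
    mids = p.midpoints
    mask = np.abs(mids - p.viewpoint_position) <= flank
    if not mask.any():
        raise ValueError(
            f"no fragment within {flank} bp of viewpoint {p.viewpoint_name!r}"
        )
    smoothed = p.fragments["smoothed"].to_numpy(dtype=float)
    mean = smoothed[mask].mean()
    if mean == 0:
        raise ValueError("zero mean score around viewpoint; cannot normalize")
    df = p.fragments.copy()
    df["normalized"] = smoothed / mean
    return replace(p, fragments=df)


def average_profiles(reps: Sequence[FourCProfile]) -> FourCProfile:
    """Value-wise mean of normalised replicate profiles."""
    if not reps:
        raise ValueError("no replicates")
    first = reps[0]
    for r in reps[1:]:
        if not first.same_grid(r) or r.viewpoint_position != first.viewpoint_position:
            raise ValueError(
                f"replicate grids differ for viewpoint {first.viewpoint_name!r}"
            )
    stack = np.vstack([r.scores("normalized") for r in reps])
    df = first.fragments.copy()
    df["normalized"] = stack.mean(axis=0)
    return replace(first, fragments=df)


def subtract_profiles(a: FourCProfile, b: FourCProfile) -> np.ndarray:
    """Per-fragment difference of normalised scores, ``a - b``."""
    if not a.same_grid(b):
        raise ValueError("profiles are on different fragment grids")
    return a.scores("normalized") - b.scores("normalized")


def quantify_regions(
    p: FourCProfile, partition: RegionPartition, which: str = "normalized"
) -> pd.DataFrame:
    """Per-region score density: summed fragment scores / region size in Mb.

    Fragments belong to the region containing their midpoint. Returns a
    frame with columns ``region``, ``score_sum``, ``size_mb``,
    ``density``.
    """
    mids = p.midpoints
    scores = p.scores(which)
    rows = []
    for name, iv, _, _ in partition.regions:
        if iv.chrom != p.chrom:
            raise ValueError("partition is on a different chromosome")
        inside = (mids >= iv.start) & (mids < iv.end)
        total = float(scores[inside].sum())
        if not inside.any():
            warnings.warn(f"region {name!r} contains no fragments")
        size_mb = iv.length / 1e6
        rows.append((name, total, size_mb, total / size_mb))
    return pd.DataFrame(rows, columns=["region", "score_sum", "size_mb", "density"])


# ---------------------------------------------------------------------------
# boundary calling


def boundary_by_cumsum(
    a: FourCProfile,
    b: FourCProfile,
    roi: GenomicInterval,
    anchors: AnchorSet,
    which: str = "normalized",
    tol: float = 1e-12,
) -> BoundaryCall:
    """Call the contact-preference switch point between viewpoints.

    Within *roi* each profile is rescaled to sum to one, giving the
    relative distribution of contacts across the region of interest.
    The cumulative sum of ``b' - a'`` in along-landscape order reaches
    its minimum at the last fragment where viewpoint *a* still
    dominates; that fragment is the boundary, snapped to the anchor CNE
    with the nearest midpoint. Identical rescaled profiles leave the
    curve at zero everywhere and the call undefined.
    """
    if not a.same_grid(b):
        raise ValueError("profiles are on different fragment grids")
    if a.orientation != b.orientation:
        raise ValueError("profiles disagree on landscape orientation")
    mids = a.midpoints
    mask = (mids >= roi.start) & (mids < roi.end) & (a.chrom == roi.chrom)
    if mask.sum() < 3:
        raise ValueError("region of interest spans fewer than 3 fragments")
    sa = a.scores(which)[mask]
    sb = b.scores(which)[mask]
    if sa.sum() == 0 or sb.sum() == 0:
        raise ValueError("a profile sums to zero within the region of interest")
    sa = sa / sa.sum()
    sb = sb / sb.sum()
    frag_idx = np.flatnonzero(mask)
    order = np.arange(len(frag_idx))
    if a.orientation == "reverse":
        order = order[::-1]
    d = sb[order] - sa[order]
    csum = np.cumsum(d)
    if np.all(np.abs(csum) <= tol):
        return BoundaryCall(a.viewpoint_name, b.viewpoint_name, defined=False,
                            cumsum=csum)
    k = int(np.argmin(csum))  # first minimum in traversal order
    frag_row = int(frag_idx[order[k]])
    fr = a.fragments.iloc[frag_row]
    frag = GenomicInterval(a.chrom, int(fr["start"]), int(fr["end"]))
    anchor_order = list(anchors)
    if a.orientation == "reverse":
        anchor_order = anchor_order[::-1]
    snapped = anchors.nearest(frag.midpoint, anchor_order)
    return BoundaryCall(
        viewpoint_a=a.viewpoint_name,
        viewpoint_b=b.viewpoint_name,
        defined=True,
        argmin_fragment=frag,
        cumsum_min=float(csum[k]),
        snapped_anchor=snapped,
        cumsum=csum,
    )


def build_partition(
    anchors: AnchorSet,
    boundary_calls: Sequence[BoundaryCall],
    outer_left: str,
    outer_right: str,
    names: Optional[Sequence[str]] = None,
) -> RegionPartition:
    """Assemble contiguous named regions between consecutive anchors.

    Region borders are the midpoints of: the outer left anchor, each
    boundary call's snapped anchor (in landscape order), and the outer
    right anchor. Region names default to ``R1..Rk``; the canonical
    D-region usage passes ``names=["D1", "D4", "D9"]``.
    """
    inner = []
    for call in boundary_calls:
        if not call.defined:
            raise ValueError(
                f"boundary {call.viewpoint_a}/{call.viewpoint_b} is undefined"
            )
        if call.snapped_anchor in (outer_left, outer_right):
            raise ValueError(
                f"boundary anchor {call.snapped_anchor!r} coincides with an "
                "outer anchor"
            )
        inner.append(call.snapped_anchor)
    if len(set(inner)) != len(inner):
        raise ValueError("boundaries snapped to the same anchor")
    seq = [outer_left] + inner + [outer_right]
    points = [anchors.midpoint(n) for n in seq]
    ascending = all(x < y for x, y in zip(points, points[1:]))
    descending = all(x > y for x, y in zip(points, points[1:]))
    if not (ascending or descending):
        raise ValueError(f"anchors are not ordered along the landscape: {seq}")
    chrom = anchors[outer_left].chrom
    if names is None:
        names = [f"R{i + 1}" for i in range(len(seq) - 1)]
    if len(names) != len(seq) - 1:
        raise ValueError("need one name per region")
    regions = []
    for i, name in enumerate(names):
        left, right = seq[i], seq[i + 1]
        lo, hi = sorted((anchors.midpoint(left), anchors.midpoint(right)))
        regions.append(
            (name, GenomicInterval(chrom, int(round(lo)), int(round(hi))), left, right)
        )
    return RegionPartition(regions)
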