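"""Readers and writers for BED-family formats, plus the coverage container.

Supported formats (all tab-separated, headerless):

* BED3-BED6 and narrowPeak (BED6+4) for intervals and peaks,
* bedGraph for coverage tracks,
* two-column ``chrom.sizes`` for assemblies.

Coverage is held as a per-chromosome step function (bedGraph semantics:
gaps are zero) with a precomputed running integral, so sums over
arbitrary intervals and sliding windows are O(log n) lookups instead of
per-base loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .genome import GenomeAssembly, GenomicInterval, sort_intervals

__all__ = [
    "CoverageTrack",
    "PeakSet",
    "BedFormatError",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "normalize_by_reads_in_peaks",
]

PathLike = Union[str, Path]


class BedFormatError(ValueError):
    """A malformed line in a BED-family file."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class _ChromSegments:
    """Sorted non-overlapping value segments on one chromosome."""

    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    values: np.ndarray  # float64
    cum: np.ndarray = field(init=False)  # running integral before segment i

    def __post_init__(self) -> None:
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("overlapping coverage segments")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite coverage value")
        areas = (self.ends - self.starts) * self.values
        self.cum = np.concatenate([[0.0], np.cumsum(areas)])

    def integral_to(self, pos: np.ndarray) -> np.ndarray:
        """Integral of the step function over [0, pos) for each pos."""
        pos = np.asarray(pos, dtype=np.int64)
        i = np.searchsorted(self.starts, pos, side="right") - 1
        i = np.clip(i, 0, len(self.starts) - 1)
        inside = (pos > self.starts[i]) & (pos <= self.ends[i])
        partial = np.where(
            inside,
            (np.minimum(pos, self.ends[i]) - self.starts[i]) * self.values[i],
            0.0,
        )
        full_before = np.where(pos >= self.ends[i], self.cum[i + 1], self.cum[i])
        return np.where(inside, self.cum[i] + partial, full_before)


@dataclass
class CoverageTrack:
    """Per-chromosome step function of float coverage (bedGraph semantics)."""

    assembly: GenomeAssembly
    chroms: dict[str, _ChromSegments] = field(default_factory=dict)

    @classmethod
    def from_segments(
        cls,
        assembly: GenomeAssembly,
        segments: Mapping[str, Sequence[tuple[int, int, float]]],
    ) -> "CoverageTrack":
        track = cls(assembly)
        for chrom, segs in segments.items():
            size = assembly.size(chrom)
            if not segs:
                continue
            arr = np.asarray(segs, dtype=float)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            starts = arr[:, 0].astype(np.int64)
            ends = arr[:, 1].astype(np.int64)
            if np.any(starts >= ends):
                raise ValueError(f"empty or inverted segment on {chrom}")
            if starts[0] < 0 or ends[-1] > size:
                raise ValueError(f"segment outside chromosome {chrom}")
            track.chroms[chrom] = _ChromSegments(starts, ends, arr[:, 2])
        return track

    def sum_in(self, interval: GenomicInterval) -> float:
        """Total signal (value x bp) within an interval."""
        seg = self.chroms.get(interval.chrom)
        if seg is None:
            return 0.0
        lo, hi = seg.integral_to(np.array([interval.start, interval.end]))
        return float(hi - lo)

    def window_sums(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorised signal sums over many windows of one chromosome."""
        seg = self.chroms.get(chrom)
        if seg is None:
            return np.zeros(len(starts))
        return seg.integral_to(ends) - seg.integral_to(starts)

    def total(self) -> float:
        return float(sum(seg.cum[-1] for seg in self.chroms.values()))

    def scale(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack(self.assembly)
        for chrom, seg in self.chroms.items():
            out.chroms[chrom] = _ChromSegments(
                seg.starts.copy(), seg.ends.copy(), seg.values * factor
            )
        return out

    def add(self, other: "CoverageTrack") -> "CoverageTrack":
        """Value-wise sum of two tracks (used for replicate averaging)."""
        out_segments: dict[str, list[tuple[int, int, float]]] = {}
        for chrom in set(self.chroms) | set(other.chroms):
            edges = set()
            for trk in (self, other):
                seg = trk.chroms.get(chrom)
                if seg is not None:
                    edges.update(seg.starts.tolist())
                    edges.update(seg.ends.tolist())
            cuts = np.array(sorted(edges), dtype=np.int64)
            starts, ends = cuts[:-1], cuts[1:]
            vals = np.zeros(len(starts))
            for trk in (self, other):
                seg = trk.chroms.get(chrom)
                if seg is not None:
                    vals += (seg.integral_to(ends) - seg.integral_to(starts)) / (
                        ends - starts
                    )
            keep = vals != 0.0
            out_segments[chrom] = list(
                zip(starts[keep].tolist(), ends[keep].tolist(), vals[keep].tolist())
            )
        return CoverageTrack.from_segments(self.assembly, out_segments)

    def to_values(self, interval: GenomicInterval, bin_size: int = 1) -> np.ndarray:
        """Dense per-bin mean values over an interval (mostly for tests/plots)."""
        edges = np.arange(interval.start, interval.end + bin_size, bin_size)
        edges[-1] = min(edges[-1], interval.end)
        sums = self.window_sums(interval.chrom, edges[:-1], edges[1:])
        return sums / (edges[1:] - edges[:-1])

    def iter_segments(self):
        for chrom in sorted(self.chroms):
            seg = self.chroms[chrom]
            for s, e, v in zip(seg.starts, seg.ends, seg.values):
                yield chrom, int(s), int(e), float(v)


@dataclass
class PeakSet:
    """A tissue's peak calls from one assay."""

    peaks: list[GenomicInterval]
    tissue: str = ""
    species: str = ""
    assay: str = "H3K27ac"
    assembly: Optional[GenomeAssembly] = None

    def __post_init__(self) -> None:
        for pk in self.peaks:
            if pk.score is not None and pk.score < 0:
                raise ValueError(f"negative peak score on {pk}")
        self.peaks = sort_intervals(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_lines(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_chrom_sizes(path: PathLike, name: Optional[str] = None) -> GenomeAssembly:
    """Read a two-column ``chrom.sizes`` file into a :class:`GenomeAssembly`."""
    sizes: dict[str, int] = {}
    for lineno, fields in _parse_lines(path):
        if len(fields) < 2:
            raise BedFormatError(f"{path}:{lineno}: expected 2 columns")
        chrom, size = fields[0], int(fields[1])
        if chrom in sizes:
            raise BedFormatError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        sizes[chrom] = size
    return GenomeAssembly(name or Path(path).stem, sizes)


def _interval_from_fields(
    fields: Sequence[str], lineno: int, path: PathLike, assembly: GenomeAssembly
) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
        iv = GenomicInterval(
            fields[0],
            start,
            end,
            name=fields[3] if len(fields) > 3 else None,
            score=float(fields[4]) if len(fields) > 4 else None,
            strand=fields[5] if len(fields) > 5 else None,
        )
    except (ValueError, IndexError) as exc:
        raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    if iv.chrom not in assembly:
        raise ValueError(
            f"{path}:{lineno}: chromosome {iv.chrom!r} not in assembly "
            f"{assembly.name!r}"
        )
    return iv.validate(assembly)


def read_bed(path: PathLike, assembly: GenomeAssembly) -> list[GenomicInterval]:
    """Read BED3-BED6 into validated intervals, preserving input order."""
    intervals = []
    for lineno, fields in _parse_lines(path):
        if not 3 <= len(fields) <= 6:
            raise BedFormatError(
                f"{path}:{lineno}: expected 3-6 tab-separated columns, "
                f"got {len(fields)}"
            )
        intervals.append(_interval_from_fields(fields, lineno, path, assembly))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            extra = (iv.name, iv.score, iv.strand)
            ncol = 3 + max(
                (i + 1 for i, v in enumerate(extra) if v is not None), default=0
            )
            defaults = (".", 0.0, ".")
            for i in range(ncol - 3):
                v = extra[i] if extra[i] is not None else defaults[i]
                fields.append(repr(v) if isinstance(v, float) else str(v))
            fh.write("\t".join(fields) + "\n")


def read_narrowpeak(
    path: PathLike,
    assembly: GenomeAssembly,
    tissue: str = "",
    species: str = "",
    assay: str = "H3K27ac",
) -> PeakSet:
    """Read a MACS2 narrowPeak (BED6+4) file.

    The peak score is taken from column 7 (signalValue); the summit
    offset in column 10 is ignored.
    """
    peaks = []
    prev: Optional[GenomicInterval] = None
    out_of_order = False
    for lineno, fields in _parse_lines(path):
        if len(fields) != 10:
            raise BedFormatError(
                f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
            )
        iv = _interval_from_fields(fields[:4], lineno, path, assembly)
        iv = replace(iv, score=float(fields[6]), strand=fields[5])
        if prev is not None and (iv.chrom, iv.start) < (prev.chrom, prev.start):
            out_of_order = True
        prev = iv
        peaks.append(iv)
    if out_of_order:
        warnings.warn(f"{path}: peaks out of order; returning them sorted")
    return PeakSet(peaks, tissue=tissue, species=species, assay=assay, assembly=assembly)


def write_narrowpeak(peaks: PeakSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks):
            fh.write(
                "\t".join(
                    [
                        pk.chrom,
                        str(pk.start),
                        str(pk.end),
                        pk.name or f"peak_{i + 1}",
                        "0",
                        pk.strand or ".",
                        repr(float(pk.score if pk.score is not None else 0.0)),
                        "-1",
                        "-1",
                        "-1",
                    ]
                )
                + "\n"
            )


def read_bedgraph(path: PathLike, assembly: GenomeAssembly) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`."""
    segments: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _parse_lines(path):
        if len(fields) != 4:
            raise BedFormatError(
                f"{path}:{lineno}: bedGraph requires 4 columns, got {len(fields)}"
            )
        chrom = fields[0]
        if chrom not in assembly:
            raise ValueError(
                f"{path}:{lineno}: chromosome {chrom!r} not in assembly "
                f"{assembly.name!r}"
            )
        try:
            seg = (int(fields[1]), int(fields[2]), float(fields[3]))
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
        segments.setdefault(chrom, []).append(seg)
    return CoverageTrack.from_segments(assembly, segments)


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued segments."""
    with open(path, "w") as fh:
        run: Optional[list] = None
        for chrom, start, end, value in track.iter_segments():
            if run is not None and run[0] == chrom and run[2] == start and run[3] == value:
                run[2] = end
                continue
            if run is not None:
                fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]!r}\n")
            run = [chrom, start, end, value]
        if run is not None:
            fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]!r}\n")


# ---------------------------------------------------------------------------
# in-peak normalisation


def _merged_peak_intervals(peaks: PeakSet) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for pk in peaks:  # already sorted
        if merged and merged[-1].chrom == pk.chrom and pk.start <= merged[-1].end:
            last = merged[-1]
            if pk.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, pk.end)
        else:
            merged.append(GenomicInterval(pk.chrom, pk.start, pk.end))
    return merged


def signal_in_peaks(track: CoverageTrack, peaks: PeakSet) -> float:
    """Total track signal inside the union of peak intervals."""
    return sum(track.sum_in(iv) for iv in _merged_peak_intervals(peaks))


def normalize_by_reads_in_peaks(track: CoverageTrack, peaks: PeakSet) -> CoverageTrack:
    """Scale a coverage track to one million units of in-peak signal.

    Mirrors the per-replicate depth normalisation used for ATAC
    coverage: every value is multiplied by ``1e6 / S`` where ``S`` is
    the total signal within the (unioned) peak intervals. Normalised
    replicates can then be averaged value-wise.
    """
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    total = signal_in_peaks(track, peaks)
    if total <= 0:
        raise ValueError("no signal within peaks; cannot normalize")
    return track.scale(1e6 / total)


def average_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Value-wise mean of replicate coverage tracks."""
    if not tracks:
        raise ValueError("no tracks to average")
    acc = tracks[0]
    for t in tracks[1:]:
        acc = acc.add(t)
    return acc.scale(1.0 / len(tracks))
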