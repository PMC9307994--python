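import numpy as np
import pytest

from regland.genome import GenomeAssembly, GenomicInterval
from regland.io import CoverageTrack


@pytest.fixture
def assembly():
    return GenomeAssembly("test", {"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_track(assembly, rng, chrom="chr1", n_segments=200, max_end=100_000):
    """Random non-overlapping value segments with gaps."""
    cuts = np.sort(rng.choice(max_end, size=2 * n_segments, replace=False))
    segments = []
    for lo, hi in zip(cuts[::2], cuts[1::2]):
        if hi > lo and rng.random() < 0.8:  # leave gaps
            segments.append((int(lo), int(hi), float(rng.normal(2.0, 1.0))))
    return CoverageTrack.from_segments(assembly, {chrom: segments})


def dense_values(track, chrom, length):
    """Per-base expansion of a track; the brute-force comparison substrate."""
    out = np.zeros(length)
    seg = track.chroms.get(chrom)
    if seg is not None:
        for s, e, v in zip(seg.starts, seg.ends, seg.values):
            out[s:e] = v
    return out


def brute_force_min_run(specific, fraction):
    """O(n^2) reference for the minimal consecutive-window run.

    Returns (first_index, length): shortest run with sum >= fraction of
    total; ties broken by larger sum, then leftmost.
    """
    total = specific.sum()
    threshold = fraction * total
    best = None  # (length, -sum, start)
    n = len(specific)
    for i in range(n):
        acc = 0.0
        for j in range(i, n):
            acc += specific[j]
            if acc >= threshold:
                cand = (j - i + 1, -acc, i)
                if best is None or cand < best:
                    best = cand
                break  # longer runs from i are never shorter
    assert best is not None
    return best[2], best[0]
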