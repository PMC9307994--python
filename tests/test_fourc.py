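"""4C profile processing and cumulative-sum boundary calling."""

import numpy as np
import pandas as pd
import pytest

from regland.fourc import (
    AnchorSet,
    FourCProfile,
    RegionPartition,
    average_profiles,
    boundary_by_cumsum,
    build_partition,
    normalize_profile,
    quantify_regions,
    smooth_profile,
    subtract_profiles,
)
from regland.genome import GenomicInterval


def make_profile(raw, frag_size=2_000, vp=0, name="vp", orientation="forward"):
    raw = np.asarray(raw, dtype=float)
    starts = np.arange(len(raw)) * frag_size
    df = pd.DataFrame({"start": starts, "end": starts + frag_size, "raw": raw})
    return FourCProfile(name, vp, "chr1", df, orientation=orientation)


def processed(raw, **kwargs):
    return normalize_profile(smooth_profile(make_profile(raw, **kwargs), 11),
                             flank=5_000_000)


class TestSmoothing:
    def test_constant_profile_is_fixed_point(self):
        p = smooth_profile(make_profile([4.0] * 30), 11)
        np.testing.assert_allclose(p.fragments["smoothed"], 4.0)

    def test_window_one_is_identity(self):
        raw = np.arange(20, dtype=float)
        p = smooth_profile(make_profile(raw), 1)
        np.testing.assert_array_equal(p.fragments["smoothed"], raw)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(make_profile([1.0] * 5), 4)

    def test_matches_per_index_mean_oracle(self, rng):
        raw = rng.lognormal(0, 1, 500)
        p = smooth_profile(make_profile(raw), 11)
        n = len(raw)
        for i in list(range(8)) + [250] + list(range(n - 8, n)):
            h = min(5, i, n - 1 - i)
            assert p.fragments["smoothed"][i] == pytest.approx(
                raw[i - h : i + h + 1].mean()
            )


class TestNormalization:
    def test_constant_smoothed_normalizes_to_one(self):
        p = processed([4.0] * 50)
        np.testing.assert_allclose(p.fragments["normalized"], 1.0)

    def test_scale_invariance(self, rng):
        raw = rng.lognormal(0, 0.5, 100)
        a = processed(raw)
        b = processed(2.0 * raw)
        np.testing.assert_allclose(
            a.fragments["normalized"], b.fragments["normalized"], rtol=1e-12
        )

    def test_flank_mean_is_one(self, rng):
        for _ in range(10):
            raw = rng.lognormal(0, 1, 400)
            p = normalize_profile(smooth_profile(make_profile(raw, vp=100_000), 11),
                                  flank=200_000)
            mids = p.midpoints
            mask = np.abs(mids - 100_000) <= 200_000
            assert p.fragments["normalized"][mask].mean() == pytest.approx(
                1.0, rel=1e-9
            )

    def test_empty_flank_errors(self):
        p = smooth_profile(make_profile([1.0] * 10), 1)
        with pytest.raises(ValueError, match="no fragment"):
            normalize_profile(p, flank=1)  # viewpoint far outside fragments


class TestAverageSubtract:
    def test_single_replicate_identity(self, rng):
        p = processed(rng.lognormal(0, 1, 50))
        np.testing.assert_array_equal(
            average_profiles([p]).fragments["normalized"], p.fragments["normalized"]
        )

    def test_mean_and_commutativity(self, rng):
        raw = rng.lognormal(0, 1, 50)
        a, b = processed(raw), processed(raw * 3.0)
        m1 = average_profiles([a, b]).fragments["normalized"]
        m2 = average_profiles([b, a]).fragments["normalized"]
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(
            m1, (a.fragments["normalized"] + b.fragments["normalized"]) / 2
        )

    def test_subtract_antisymmetry_and_zero(self, rng):
        a = processed(rng.lognormal(0, 1, 60))
        b = processed(rng.lognormal(0, 1, 60))
        np.testing.assert_allclose(subtract_profiles(a, b), -subtract_profiles(b, a))
        np.testing.assert_allclose(subtract_profiles(a, a), 0.0)

    def test_grid_mismatch_errors(self, rng):
        a = processed(rng.lognormal(0, 1, 60))
        b = processed(rng.lognormal(0, 1, 61))
        with pytest.raises(ValueError, match="grid"):
            subtract_profiles(a, b)


def partition_of(chrom, cuts, names):
    regions = []
    for i, name in enumerate(names):
        regions.append(
            (name, GenomicInterval(chrom, cuts[i], cuts[i + 1]), f"L{i}", f"L{i+1}")
        )
    return RegionPartition(regions)


class TestQuantifyRegions:
    def test_uniform_density(self):
        # normalized score 1 on a fragment every 2 kb -> 500 scores per Mb
        p = processed([1.0] * 500)
        part = partition_of("chr1", [0, 200_000, 1_000_000], ["A", "B"])
        table = quantify_regions(p, part)
        np.testing.assert_allclose(table["density"], 500.0, rtol=0.02)

    def test_conservation_of_total_score(self, rng):
        p = processed(rng.lognormal(0, 1, 500))
        part = partition_of("chr1", [0, 137_000, 400_000, 1_000_000], ["A", "B", "C"])
        table = quantify_regions(p, part)
        mids = p.midpoints
        inside = (mids >= 0) & (mids < 1_000_000)
        total = p.fragments["normalized"][inside].sum()
        assert (table["density"] * table["size_mb"]).sum() == pytest.approx(
            total, rel=1e-9
        )

    def test_empty_region_is_zero_with_warning(self):
        p = processed([1.0] * 10)  # fragments cover 0-20 kb only
        part = partition_of("chr1", [0, 20_000, 50_000], ["A", "B"])
        with pytest.warns(UserWarning, match="no fragments"):
            table = quantify_regions(p, part)
        assert table.set_index("region").loc["B", "density"] == 0.0


def step_profiles(n=40, split=20):
    """Two perfect step profiles switching dominance at *split*."""
    a = np.zeros(n)
    a[:split] = 1.0
    b = np.zeros(n)
    b[split:] = 1.0
    return a, b


class TestBoundaryByCumsum:
    def anchors(self, positions):
        return AnchorSet(
            {f"CNE{i}": GenomicInterval("chr1", p - 50, p + 50)
             for i, p in enumerate(positions)}
        )

    def test_perfect_step_profiles(self):
        # rescaled a' = [.5,.5,0,0], b' = [0,0,.5,.5] -> argmin at fragment 2
        a = make_profile([1.0, 1.0, 0.0, 0.0])
        b = make_profile([0.0, 0.0, 1.0, 1.0])
        for p in (a, b):
            p.fragments["normalized"] = p.fragments["raw"]
        roi = GenomicInterval("chr1", 0, 8_000)
        anchors = self.anchors([1_000, 3_000, 5_000, 7_000])
        call = boundary_by_cumsum(a, b, roi, anchors)
        assert call.defined
        np.testing.assert_allclose(call.cumsum, [-0.5, -1.0, -0.5, 0.0])
        assert call.argmin_fragment.start == 2_000  # second fragment
        assert call.snapped_anchor == "CNE1"

    def test_identical_profiles_are_undefined(self):
        a = processed([2.0] * 30)
        call = boundary_by_cumsum(a, a, GenomicInterval("chr1", 0, 60_000),
                                  self.anchors([10_000, 30_000]))
        assert not call.defined

    def test_scale_invariance_of_raw_profiles(self, rng):
        raw_a, raw_b = rng.lognormal(0, 1, 100), rng.lognormal(0, 1, 100)
        roi = GenomicInterval("chr1", 0, 200_000)
        anchors = self.anchors([50_000, 150_000])
        c1 = boundary_by_cumsum(processed(raw_a), processed(raw_b), roi, anchors)
        c2 = boundary_by_cumsum(processed(raw_a * 7.0), processed(raw_b * 0.3),
                                roi, anchors)
        assert c1.argmin_fragment == c2.argmin_fragment
        np.testing.assert_allclose(c1.cumsum, c2.cumsum, rtol=1e-9, atol=1e-12)

    def test_cumsum_closes_at_zero(self, rng):
        for _ in range(10):
            c = boundary_by_cumsum(
                processed(rng.lognormal(0, 1, 200)),
                processed(rng.lognormal(0, 1, 200)),
                GenomicInterval("chr1", 0, 400_000),
                self.anchors([100_000, 300_000]),
            )
            assert abs(c.cumsum[-1]) < 1e-9

    def test_mirrored_orientation_gives_mirrored_boundary(self):
        ra, rb = step_profiles(40, 17)
        fwd = boundary_by_cumsum(
            processed(ra + 0.05), processed(rb + 0.05),
            GenomicInterval("chr1", 0, 80_000), self.anchors([34_000, 60_000]),
        )
        rev_a = processed(rb + 0.05, orientation="reverse")
        rev_b = processed(ra + 0.05, orientation="reverse")
        rev = boundary_by_cumsum(
            rev_a, rev_b, GenomicInterval("chr1", 0, 80_000),
            self.anchors([34_000, 60_000]),
        )
        # traversed right-to-left with swapped roles, the switch is the
        # fragment adjacent to the forward call
        assert abs(rev.argmin_fragment.start - fwd.argmin_fragment.start) <= 2_000

    def test_zero_profile_errors(self):
        a = processed([1.0] * 30)
        b = make_profile([0.0] * 30)
        b.fragments["normalized"] = b.fragments["raw"]
        with pytest.raises(ValueError, match="zero"):
            boundary_by_cumsum(a, b, GenomicInterval("chr1", 0, 60_000),
                               self.anchors([30_000]))


class TestBuildPartition:
    def anchors(self):
        return AnchorSet(
            {
                "CNE331": GenomicInterval("chr1", 99_950, 100_050),
                "CNE346": GenomicInterval("chr1", 549_950, 550_050),
                "CNE364": GenomicInterval("chr1", 1_049_950, 1_050_050),
                "CNE382": GenomicInterval("chr1", 1_499_950, 1_500_050),
            }
        )

    def call(self, anchor):
        from regland.fourc import BoundaryCall

        return BoundaryCall("a", "b", defined=True, snapped_anchor=anchor)

    def test_three_regions_from_two_boundaries(self):
        part = build_partition(
            self.anchors(), [self.call("CNE346"), self.call("CNE364")],
            "CNE331", "CNE382", names=["D1", "D4", "D9"],
        )
        assert part.names == ["D1", "D4", "D9"]
        assert part.interval("D1").start == 100_000
        assert part.interval("D4") == GenomicInterval("chr1", 550_000, 1_050_000)
        assert part.interval("D9").end == 1_500_000

    def test_one_boundary_two_regions(self):
        part = build_partition(self.anchors(), [self.call("CNE346")],
                               "CNE331", "CNE382")
        assert len(part.regions) == 2

    def test_boundary_on_outer_anchor_errors(self):
        with pytest.raises(ValueError, match="outer"):
            build_partition(self.anchors(), [self.call("CNE331")],
                            "CNE331", "CNE382")
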