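import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmdep.chip import (
    BinTrack,
    RegionSet,
    TagTrack,
    bin_and_scale,
    consensus_and_merge,
    estimate_fragment_length,
    interval_jaccard,
    intersect_intervals,
    merge_intervals,
    region_density,
    sample_significant_intervals,
    significant_bins,
    significant_intervals,
)

from oracles import bh_stepup, brute_intersect, brute_merge

SIZES = {"chr1": 100_000}


def _track(positions, strands, sizes=SIZES, chrom="chr1", sample="t", role="chip",
           fragment_length=None):
    pos = np.asarray(positions, dtype=np.int64)
    return TagTrack(sample_id=sample, role=role, chrom_sizes=sizes,
                    positions={chrom: pos},
                    is_plus={chrom: np.asarray(strands, dtype=bool)},
                    fragment_length=fragment_length)


class TestFragmentLength:
    def test_identical_strand_profiles_peak_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 90_000, 3000)
        track = _track(np.concatenate([base, base]),
                       [True] * 3000 + [False] * 3000)
        assert estimate_fragment_length(track) == 0

    def test_simulated_fragments_recovered(self):
        # fragments cluster at binding sites, which is what makes the
        # plus/minus profiles correlate at the fragment-length lag
        rng = np.random.default_rng(1)
        peaks = rng.integers(2000, 98_000, 25)
        centers = np.concatenate(
            [p + rng.normal(0, 30, 200).astype(int) for p in peaks])
        plus = rng.random(centers.size) < 0.5
        five = np.clip(np.where(plus, centers - 100, centers + 100), 0, 99_999)
        track = _track(five, plus)
        assert abs(estimate_fragment_length(track) - 200) <= 20

    def test_uniform_tags_warn_unreliable(self):
        rng = np.random.default_rng(2)
        track = _track(rng.integers(0, 100_000, 4000), rng.random(4000) < 0.5)
        with pytest.warns(UserWarning, match="unreliable"):
            estimate_fragment_length(track)

    def test_single_strand_data_rejected(self):
        track = _track([10, 20, 30], [True, True, True])
        with pytest.raises(ValueError):
            estimate_fragment_length(track)


class TestBinning:
    def test_empty_track_scales_to_pseudocount(self):
        track = _track([], [])
        bt = bin_and_scale(track, 500, 0)
        assert np.allclose(bt.scaled("chr1"), np.log2(30.0))

    def test_single_tag_increments_one_bin_per_phase(self):
        track = _track([740], [True], fragment_length=0)
        for offset in (0, 250):
            bt = bin_and_scale(track, 500, offset)
            counts = bt.counts["chr1"]
            assert counts.sum() == 1
            starts, ends = bt.bin_bounds("chr1")
            (j,) = np.flatnonzero(counts)
            assert starts[j] <= 740 < ends[j]

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(3)
        track = _track(rng.integers(0, 100_000, 5000), rng.random(5000) < 0.5,
                       fragment_length=200)
        for offset in (0, 250):
            bt = bin_and_scale(track, 500, offset)
            assert bt.counts["chr1"].sum() == track.total_tags

    def test_shift_moves_strands_toward_center(self):
        track = _track([1000, 2000], [True, False], fragment_length=200)
        shifted = track.shifted_positions()
        assert list(shifted["chr1"]) == [1100, 1900]


class TestSignificantBins:
    def test_chip_equal_input_yields_nothing(self):
        rng = np.random.default_rng(4)
        pos = rng.integers(0, 100_000, 20_000)
        strands = rng.random(20_000) < 0.5
        chip = _track(pos, strands, fragment_length=0)
        inp = _track(pos, strands, role="input", fragment_length=0)
        table = significant_bins(bin_and_scale(chip, 500, 0),
                                 bin_and_scale(inp, 500, 0), fdr=0.5)
        assert not table["significant"].any()

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(5)
        bg = rng.integers(0, 100_000, 10_000)
        peak = rng.integers(40_000, 41_000, 2_000)  # 20x local pile-up
        chip = _track(np.concatenate([bg, peak]),
                      rng.random(12_000) < 0.5, fragment_length=0)
        inp = _track(rng.integers(0, 100_000, 10_000),
                     rng.random(10_000) < 0.5, role="input", fragment_length=0)
        table = significant_bins(bin_and_scale(chip, 500, 0),
                                 bin_and_scale(inp, 500, 0))
        sig = table[table["significant"]]
        assert len(sig) >= 2
        assert (sig["start"] >= 39_500).all() and (sig["end"] <= 41_500).all()

    def test_bh_adjustment_matches_stepup_oracle(self):
        rng = np.random.default_rng(6)
        chip = _track(rng.integers(0, 100_000, 5000), rng.random(5000) < 0.5,
                      fragment_length=0)
        inp = _track(rng.integers(0, 100_000, 4000), rng.random(4000) < 0.5,
                     role="input", fragment_length=0)
        table = significant_bins(bin_and_scale(chip, 500, 0),
                                 bin_and_scale(inp, 500, 0))
        assert np.allclose(table["q"], bh_stepup(table["p"].to_numpy()))

    def test_mismatched_grids_rejected(self):
        track = _track([10], [True], fragment_length=0)
        with pytest.raises(ValueError):
            significant_bins(bin_and_scale(track, 500, 0),
                             bin_and_scale(track, 500, 250))


intervals_strategy = st.lists(
    st.tuples(st.sampled_from(["chr1", "chr2"]),
              st.integers(0, 5_000), st.integers(1, 800)),
    min_size=0, max_size=25,
).map(lambda ivs: [(c, s, s + w) for c, s, w in ivs])


class TestIntervalAlgebra:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(intervals_strategy, st.sampled_from([1, 100, 500]))
    def test_merge_matches_per_bp_oracle(self, ivs, gap):
        assert merge_intervals(ivs, max_gap=gap) == brute_merge(ivs, max_gap=gap)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(intervals_strategy, intervals_strategy)
    def test_intersection_matches_per_bp_oracle(self, a, b):
        assert intersect_intervals(a, b) == brute_intersect(a, b)

    def test_sub_500_gap_merges(self):
        merged = merge_intervals(
            [("chr1", 0, 500), ("chr1", 900, 1400)], max_gap=500)
        assert merged == [("chr1", 0, 1400)]  # 400 < 500 joins

    def test_exact_500_gap_stays_split(self):
        merged = merge_intervals(
            [("chr1", 0, 500), ("chr1", 1000, 1500)], max_gap=500)
        assert len(merged) == 2


class TestConsensus:
    def test_single_replicate_support_is_dropped(self):
        per_sample = {
            "c_r1": [("chr1", 0, 500), ("chr1", 2000, 2500)],
            "c_r2": [("chr1", 0, 500)],
        }
        regions = consensus_and_merge(per_sample, {"c_r1": "c", "c_r2": "c"})
        assert regions.regions == (("chr1", 0, 500),)

    def test_cross_condition_union(self):
        per_sample = {
            "a_r1": [("chr1", 0, 500)], "a_r2": [("chr1", 0, 500)],
            "b_r1": [("chr1", 5000, 5500)], "b_r2": [("chr1", 5000, 5500)],
        }
        cond = {s: s.split("_")[0] for s in per_sample}
        regions = consensus_and_merge(per_sample, cond)
        assert len(regions) == 2

    def test_chromosome_processing_order_irrelevant(self):
        ivs = [("chr2", 0, 500), ("chr1", 100, 600), ("chr1", 900, 1300)]
        a = consensus_and_merge({"s_r1": ivs, "s_r2": list(reversed(ivs))},
                                {"s_r1": "s", "s_r2": "s"})
        b = consensus_and_merge({"s_r1": list(reversed(ivs)), "s_r2": ivs},
                                {"s_r1": "s", "s_r2": "s"})
        assert a.regions == b.regions


class TestDensity:
    def test_region_without_tags_is_zero(self):
        track = _track([50_000], [True], fragment_length=0)
        regions = RegionSet(regions=(("chr1", 0, 1000),))
        assert region_density(regions, track)[0] == 0.0

    def test_uniform_doubling_leaves_density_unchanged(self):
        rng = np.random.default_rng(7)
        pos = rng.integers(0, 100_000, 3000)
        strands = rng.random(3000) < 0.5
        track1 = _track(pos, strands, fragment_length=0)
        track2 = _track(np.concatenate([pos, pos]),
                        np.concatenate([strands, strands]), fragment_length=0)
        regions = RegionSet(regions=(("chr1", 10_000, 12_000),
                                     ("chr1", 50_000, 50_400)))
        assert np.allclose(region_density(regions, track1),
                           region_density(regions, track2))

    def test_matches_naive_per_base_count(self):
        rng = np.random.default_rng(8)
        pos = rng.integers(0, 100_000, 2000)
        strands = rng.random(2000) < 0.5
        track = _track(pos, strands, fragment_length=100)
        regions = RegionSet(regions=(("chr1", 20_000, 21_000),
                                     ("chr1", 70_000, 70_250)))
        shifted = track.shifted_positions()["chr1"]
        for i, (_, s, e) in enumerate(regions.regions):
            naive = int(np.sum((shifted >= s) & (shifted < e)))
            expected = naive / (e - s) / track.total_tags * 1e9
            assert region_density(regions, track)[i] == pytest.approx(expected)


class TestEndToEnd:
    def test_planted_regions_recovered(self, chip_sim, chip_called):
        regions, density = chip_called
        jac = interval_jaccard(regions.regions, chip_sim.truth_regions.regions)
        assert jac >= 0.8
        # the bin-boundary-straddling region is covered
        straddler = min(chip_sim.truth_regions.regions, key=lambda r: r[2] - r[1])
        overlap = sum(e - s for _, s, e in
                      intersect_intervals([straddler], regions.regions))
        assert overlap >= 0.5 * (straddler[2] - straddler[1])
        assert density.shape[0] == len(regions)

    def test_chip_as_its_own_input_gives_empty_set(self, chip_sim):
        per_sample = {
            s: sample_significant_intervals(tr, tr, fragment_length=0)
            for s, tr in list(chip_sim.input_of.items())[:2]
        }
        regions = consensus_and_merge(per_sample, chip_sim.condition_of)
        assert len(regions) == 0

    def test_fragment_length_recovered(self, chip_sim):
        track = next(iter(chip_sim.chip_tracks.values()))
        est = estimate_fragment_length(track)
        assert abs(est - chip_sim.fragment_length) <= 20


def test_bed_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    track = _track(rng.integers(0, 100_000, 500), rng.random(500) < 0.5)
    path = tmp_path / "tags.bed"
    track.to_bed(path)
    back = TagTrack.from_bed(path, SIZES, sample_id="t")
    assert back.total_tags == track.total_tags
    assert np.array_equal(np.sort(back.positions["chr1"]),
                          np.sort(track.positions["chr1"]))
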