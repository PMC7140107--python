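"""Tiled differential methylation and hypomethylated-block assembly."""

import numpy as np
import pandas as pd
import pytest

from hypoblocks.block_calling import (
    BlockConfig,
    DMRConfig,
    bh_adjust,
    call_dmc,
    call_dmr,
    call_hypo_blocks,
    call_blocks,
    tile_differential,
    tile_genome,
)
from hypoblocks.genome_intervals import (
    GenomeModel,
    Interval,
    IntervalSet,
    intersect_bases,
    union_bases,
)
from hypoblocks.io_formats import MethylomeTable
from hypoblocks.synthetic_data import CASE_GROUP, REF_GROUP, SimConfig, simulate_methylome


def make_methylome(positions, ref_values, case_values, chrom="chr1"):
    """ref_values/case_values: arrays (n_sites, n_samples)."""
    ref_values = np.atleast_2d(np.asarray(ref_values, float))
    case_values = np.atleast_2d(np.asarray(case_values, float))
    beta = {}
    groups = {}
    for j in range(ref_values.shape[1]):
        beta[f"r{j}"] = ref_values[:, j]
        groups[f"r{j}"] = REF_GROUP
    for j in range(case_values.shape[1]):
        beta[f"c{j}"] = case_values[:, j]
        groups[f"c{j}"] = CASE_GROUP
    sites = pd.DataFrame({"chrom": chrom, "pos": positions})
    return MethylomeTable(sites, pd.DataFrame(beta), groups)


class TestTileGenome:
    def test_truncated_last_tile(self):
        g = GenomeModel((("chr1", 12_000),))
        tiles = tile_genome(g, 5000)
        assert tiles == [
            Interval("chr1", 0, 5000),
            Interval("chr1", 5000, 10_000),
            Interval("chr1", 10_000, 12_000),
        ]

    def test_exact_single_tile(self):
        assert tile_genome(GenomeModel((("chr1", 5000),)), 5000) == [
            Interval("chr1", 0, 5000)
        ]

    def test_tiles_cover_genome_exactly_once(self):
        g = GenomeModel((("chr1", 123_456), ("chr2", 5000), ("chr3", 4999)))
        tiles = IntervalSet(tile_genome(g, 5000)).normalize()
        assert tiles.bases() == g.total_size


class TestTileDifferential:
    def test_null_identical_groups(self):
        rng = np.random.default_rng(0)
        pos = np.arange(100) * 100
        vals = rng.uniform(0.6, 0.9, (100, 4))
        m = make_methylome(pos, vals, vals)
        tiles = tile_genome(GenomeModel((("chr1", 10_000),)), 5000)
        ts = tile_differential(m, (REF_GROUP, CASE_GROUP), tiles)
        assert np.allclose(ts["delta"], 0)
        assert (ts["p"] >= 0.99).all()

    def test_planted_tile_detected(self):
        rng = np.random.default_rng(1)
        n_tiles, per_tile = 40, 10
        pos = np.arange(n_tiles * per_tile) * 500
        ref = rng.normal(0.8, 0.02, (len(pos), 4))
        case = rng.normal(0.8, 0.02, (len(pos), 4))
        case[:per_tile] = rng.normal(0.4, 0.02, (per_tile, 4))  # tile 0 planted
        m = make_methylome(pos, ref, case)
        tiles = tile_genome(GenomeModel((("chr1", n_tiles * per_tile * 500),)), 5000)
        ts = tile_differential(m, (REF_GROUP, CASE_GROUP), tiles)
        planted = ts[ts["start"] == 0].iloc[0]
        assert planted["delta"] == pytest.approx(-0.4, abs=0.03)
        assert planted["q"] < 0.05

    def test_bh_hand_computation(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_small_group_requires_delta_only(self):
        m = make_methylome([10], [[0.8]], [[0.4]])
        tiles = tile_genome(GenomeModel((("chr1", 5000),)), 5000)
        with pytest.raises(ValueError, match="delta_only"):
            tile_differential(m, (REF_GROUP, CASE_GROUP), tiles)
        ts = tile_differential(m, (REF_GROUP, CASE_GROUP), tiles, delta_only=True)
        assert ts["delta"].iloc[0] == pytest.approx(-0.4)

    def test_min_tile_cpgs_filters(self):
        pos = [10, 20, 5001]
        m = make_methylome(pos, np.full((3, 2), 0.8), np.full((3, 2), 0.4))
        tiles = tile_genome(GenomeModel((("chr1", 10_000),)), 5000)
        ts = tile_differential(m, (REF_GROUP, CASE_GROUP), tiles, min_tile_cpgs=2)
        assert ts["start"].tolist() == [0]


def tilestats(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpgs", "mean_ref", "mean_case", "delta", "p", "q"]
    )


class TestCallHypoBlocks:
    def test_merge_trace(self):
        ts = tilestats(
            [
                ("chr1", 0, 5000, 3, 0.8, 0.4, -0.40, 0.001, 0.01),
                ("chr1", 5000, 10_000, 4, 0.8, 0.44, -0.36, 0.01, 0.04),
                ("chr1", 300_000, 305_000, 4, 0.9, 0.4, -0.50, 0.0001, 0.001),
            ]
        )
        blocks = call_hypo_blocks(ts, BlockConfig())
        # 290kb gap > 250kb keeps the distant tile separate; its block has 4 < 5 CpGs
        assert len(blocks) == 1
        row = blocks.stats.iloc[0]
        assert (row["start"], row["end"], row["n_cpgs"], row["n_tiles"]) == (0, 10_000, 7, 2)
        assert row["mean_delta"] == pytest.approx((3 * -0.40 + 4 * -0.36) / 7)

    def test_gap_within_merge_distance_spans_gap(self):
        ts = tilestats(
            [
                ("chr1", 0, 5000, 5, 0.8, 0.4, -0.4, 0.001, 0.01),
                ("chr1", 200_000, 205_000, 5, 0.8, 0.4, -0.4, 0.001, 0.01),
            ]
        )
        blocks = call_hypo_blocks(ts, BlockConfig())
        assert blocks.stats.iloc[0][["start", "end"]].tolist() == [0, 205_000]

    def test_no_passing_tiles_empty(self):
        ts = tilestats([("chr1", 0, 5000, 9, 0.8, 0.7, -0.1, 0.5, 0.8)])
        assert len(call_hypo_blocks(ts, BlockConfig())) == 0

    def test_empty_input_empty_output(self):
        assert len(call_hypo_blocks(tilestats([]), BlockConfig())) == 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            q = rng.uniform(0, 0.2)
            rows.append(("chr1", i * 5000, (i + 1) * 5000, 5, 0.8, 0.8 + rng.uniform(-0.6, 0), rng.uniform(-0.6, 0), q, q))
        ts = tilestats(rows)
        ts["delta"] = ts["mean_case"] - ts["mean_ref"]

        def kept(cfg):
            b = call_hypo_blocks(ts, cfg)
            return b.stats["n_tiles"].sum()

        loose = BlockConfig(fdr_threshold=0.1, min_delta=0.2, min_block_cpgs=1)
        tight = BlockConfig(fdr_threshold=0.05, min_delta=0.35, min_block_cpgs=1)
        assert kept(loose) >= kept(tight)

        small_gap = call_hypo_blocks(ts, BlockConfig(merge_gap=10_000, min_block_cpgs=1))
        big_gap = call_hypo_blocks(ts, BlockConfig(merge_gap=500_000, min_block_cpgs=1))
        assert len(big_gap) <= len(small_gap)
        assert big_gap.total_bases() >= small_gap.total_bases()

    def test_planted_block_recovered_with_high_jaccard(self):
        cfg = SimConfig(seed=11, n_chrom=1, chrom_length=5_000_000, block_fraction=0.12,
                        block_min_len=550_000, block_max_len=650_000)
        m, truth = simulate_methylome(cfg)
        blocks, _ = call_blocks(m, (REF_GROUP, CASE_GROUP), cfg.genome())
        inter = intersect_bases(blocks.blocks, truth.blocks)
        union = union_bases(blocks.blocks, truth.blocks)
        assert inter / union >= 0.8


class TestDMR:
    def test_hand_trace_single_hypo_region(self):
        # 3 CpGs 100 bp apart; only the first passes per-CpG delta and p
        ref = np.array([[0.80, 0.80, 0.80, 0.80], [0.50, 0.51, 0.49, 0.50], [0.50, 0.52, 0.48, 0.50]])
        case = np.array([[0.55, 0.55, 0.55, 0.55], [0.40, 0.41, 0.39, 0.40], [0.45, 0.47, 0.43, 0.45]])
        m = make_methylome([100, 200, 300], ref, case)
        dmrs = call_dmr(m, (REF_GROUP, CASE_GROUP), DMRConfig())
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert row["direction"] == "hypo"
        assert (row["n_cpgs"], row["n_passing"]) == (3, 1)
        assert (row["start"], row["end"]) == (100, 301)

    def test_all_zero_delta_empty(self):
        vals = np.full((5, 4), 0.7)
        m = make_methylome([100, 200, 300, 400, 500], vals, vals)
        assert len(call_dmr(m, (REF_GROUP, CASE_GROUP))) == 0

    def test_two_cpg_run_rejected(self):
        ref = np.full((2, 4), 0.8)
        case = np.full((2, 4), 0.4)
        m = make_methylome([100, 200], ref, case)
        assert len(call_dmr(m, (REF_GROUP, CASE_GROUP))) == 0

    def test_large_gap_splits_runs(self):
        ref = np.full((6, 4), 0.8) + np.random.default_rng(0).normal(0, 0.01, (6, 4))
        case = np.full((6, 4), 0.4) + np.random.default_rng(1).normal(0, 0.01, (6, 4))
        m = make_methylome([100, 200, 300, 5000, 5100, 5200], ref, case)
        dmrs = call_dmr(m, (REF_GROUP, CASE_GROUP))
        assert len(dmrs) == 2


class TestDMC:
    def test_null_counts_zero(self):
        vals = np.full((10, 4), 0.7)
        m = make_methylome([i * 100 for i in range(10)], vals, vals)
        ctx = {"genome": IntervalSet([Interval("chr1", 0, 10_000)]).normalize()}
        counts = call_dmc(m, (REF_GROUP, CASE_GROUP), ctx)
        assert counts.iloc[0][["n_hyper", "n_hypo"]].tolist() == [0, 0]

    def test_planted_island_hypo_only(self):
        rng = np.random.default_rng(2)
        pos = [i * 100 for i in range(60)]
        ref = rng.normal(0.8, 0.01, (60, 4))
        case = ref.copy() + rng.normal(0, 0.01, (60, 4))
        island = IntervalSet([Interval("chr1", 0, 2000)]).normalize()  # first 20 CpGs
        case[:20] -= 0.30
        m = make_methylome(pos, ref, np.clip(case, 0, 1))
        ctx = {"island": island, "open_sea": IntervalSet([Interval("chr1", 2000, 6000)]).normalize()}
        counts = call_dmc(m, (REF_GROUP, CASE_GROUP), ctx).set_index("context")
        assert counts.loc["island", "n_hypo"] == 20
        assert counts.loc["island", "n_hyper"] == 0
        assert counts.loc["open_sea", "n_hypo"] == 0

    def test_counts_match_brute_force_filter(self):
        rng = np.random.default_rng(3)
        n = 200
        pos = [i * 50 for i in range(n)]
        ref = rng.uniform(0.3, 0.9, (n, 4))
        case = np.clip(ref + rng.normal(0, 0.15, (n, 4)), 0, 1)
        m = make_methylome(pos, ref, case)
        ctx = {"all": IntervalSet([Interval("chr1", 0, 10_000)]).normalize()}
        counts = call_dmc(m, (REF_GROUP, CASE_GROUP), ctx).iloc[0]

        # brute-force oracle: per-CpG Welch t + BH over the context
        from scipy import stats as ss
        from statsmodels.stats.multitest import multipletests

        delta = case.mean(axis=1) - ref.mean(axis=1)
        p = np.array([ss.ttest_ind(case[i], ref[i], equal_var=False).pvalue for i in range(n)])
        q = multipletests(p, method="fdr_bh")[1]
        sig = (np.abs(delta) > 0.20) & (q <= 0.05)
        assert counts["n_hyper"] == int((sig & (delta > 0)).sum())
        assert counts["n_hypo"] == int((sig & (delta < 0)).sum())

    def test_unknown_context_handling(self):
        vals = np.full((3, 4), 0.7)
        m = make_methylome([100, 200, 300], vals, vals)
        with pytest.raises(ValueError):
            call_dmc(m, (REF_GROUP, CASE_GROUP), {})
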