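"""Tiled differential methylation, hypomethylated-block assembly, DMR/DMC calling.

The block caller follows the tiling recipe used for tumor methylomes: the
genome is cut into fixed tiles (default 5 kb), each tile is summarized per
sample as the mean methylation fraction of its observed CpGs, tiles are
tested for a case-vs-reference decrease (Welch t on per-sample tile means,
Benjamini-Hochberg FDR across testable tiles), significant tiles with a
large enough decrease (default >= 0.35) and within a merge distance
(default <= 250 kb) are combined into blocks, and blocks with too few CpGs
(default < 5) are dropped.

Because tumor-versus-normal methylome comparisons are often tiny (two
samples per group), a delta-only mode keeps tiles by methylation decrease
alone, with no significance filter.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_intervals import GenomeModel, Interval, IntervalSet, points_in_set
from .io_formats import MethylomeTable


@dataclass(frozen=True)
class BlockConfig:
    tile_size: int = 5000
    fdr_threshold: float = 0.05
    min_delta: float = 0.35
    merge_gap: int = 250_000
    min_block_cpgs: int = 5
    min_tile_cpgs: int = 1
    delta_only: bool = False

    def __post_init__(self) -> None:
        if self.tile_size <= 0 or self.merge_gap < 0:
            raise ValueError("tile_size must be positive, merge_gap non-negative")
        if not (0 < self.fdr_threshold < 1 and 0 < self.min_delta < 1):
            raise ValueError("fdr_threshold and min_delta must be in (0,1)")
        if self.min_block_cpgs < 1 or self.min_tile_cpgs < 1:
            raise ValueError("CpG count thresholds must be >= 1")


@dataclass(frozen=True)
class DMRConfig:
    min_region_cpgs: int = 3
    per_cpg_delta: float = 0.20
    per_cpg_p: float = 0.05
    max_cpg_gap: int = 1000

    def __post_init__(self) -> None:
        if self.min_region_cpgs < 1 or self.max_cpg_gap <= 0:
            raise ValueError("min_region_cpgs and max_cpg_gap must be positive")
        if not (0 < self.per_cpg_delta < 1 and 0 < self.per_cpg_p < 1):
            raise ValueError("per_cpg_delta and per_cpg_p must be in (0,1)")


@dataclass
class HypoBlockSet:
    """Called hypomethylated blocks with per-block summaries."""

    blocks: IntervalSet
    stats: pd.DataFrame  # chrom, start, end, n_cpgs, n_tiles, mean_delta

    def __len__(self) -> int:
        return len(self.blocks)

    def total_bases(self) -> int:
        return self.blocks.bases()


def tile_genome(genome: GenomeModel, tile_size: int) -> list[Interval]:
    """Non-overlapping tiles covering each chromosome; last tile truncated."""
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    tiles = []
    for chrom, length in genome.chromosomes:
        for start in range(0, length, tile_size):
            tiles.append(Interval(chrom, start, min(start + tile_size, length)))
    return tiles


def _group_matrices(methylome: MethylomeTable, groups: tuple[str, str]):
    ref_group, case_group = groups
    ref = methylome.samples_in_group(ref_group)
    case = methylome.samples_in_group(case_group)
    if not ref or not case:
        missing = ref_group if not ref else case_group
        raise ValueError(f"no samples labeled {missing!r} in methylome")
    return ref, case


def tile_differential(
    methylome: MethylomeTable,
    groups: tuple[str, str],
    tiles: list[Interval],
    min_tile_cpgs: int = 1,
    delta_only: bool = False,
) -> pd.DataFrame:
    """Per-tile group means, delta, Welch p and BH q.

    Returns one row per tile with >= ``min_tile_cpgs`` CpGs observed in at
    least one sample: columns chrom, start, end, n_cpgs, mean_ref, mean_case,
    delta, p, q.  A sample contributes its mean over CpGs it observed in the
    tile; the p-value is a two-sample Welch t on those per-sample means, and
    q is Benjamini-Hochberg over the emitted (testable) tiles.
    """
    ref, case = _group_matrices(methylome, groups)
    if not delta_only and (len(ref) < 2 or len(case) < 2):
        raise ValueError(
            "p-values need >= 2 samples per group; re-run with delta_only=True "
            "to keep tiles by methylation decrease alone"
        )

    # map each CpG to its tile via interval order
    tile_df = pd.DataFrame(
        {
            "chrom": [t.chrom for t in tiles],
            "start": [t.start for t in tiles],
            "end": [t.end for t in tiles],
        }
    )
    sites = methylome.sites
    tile_index = np.full(len(sites), -1, dtype=np.int64)
    for chrom, sub in tile_df.groupby("chrom", sort=False):
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = sites.loc[mask, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
        idx = sub.index.to_numpy()
        ti = np.where(ok, idx[np.clip(k, 0, len(idx) - 1)], -1)
        tile_index[mask] = ti

    in_tile = tile_index >= 0
    beta = methylome.beta.to_numpy()
    n_tiles = len(tiles)
    samples = methylome.samples
    sums = np.zeros((n_tiles, len(samples)))
    counts = np.zeros((n_tiles, len(samples)), dtype=np.int64)
    ti = tile_index[in_tile]
    b = beta[in_tile]
    obs = ~np.isnan(b)
    for j in range(len(samples)):
        oj = obs[:, j]
        sums[:, j] = np.bincount(ti[oj], weights=b[oj, j], minlength=n_tiles)
        counts[:, j] = np.bincount(ti[oj], minlength=n_tiles)
    with np.errstate(invalid="ignore"):
        tile_means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    # CpG observed in >=1 sample counts toward the tile
    cpg_any = np.bincount(ti[obs.any(axis=1)], minlength=n_tiles)
    testable = cpg_any >= min_tile_cpgs

    ref_idx = [samples.index(s) for s in ref]
    case_idx = [samples.index(s) for s in case]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tiles are expected
        mean_ref = np.nanmean(tile_means[:, ref_idx], axis=1)
        mean_case = np.nanmean(tile_means[:, case_idx], axis=1)
    delta = mean_case - mean_ref

    if delta_only:
        p = np.full(n_tiles, np.nan)
    else:
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant tiles are expected
            res = stats.ttest_ind(
                tile_means[:, case_idx],
                tile_means[:, ref_idx],
                axis=1,
                equal_var=False,
                nan_policy="omit",
            )
        p = np.asarray(res.pvalue, dtype=float)
        # identical or constant groups -> no evidence of difference
        p = np.where(np.isnan(p) & np.isfinite(delta), 1.0, p)

    out = tile_df.loc[testable & np.isfinite(delta)].copy()
    out["n_cpgs"] = cpg_any[out.index]
    out["mean_ref"] = mean_ref[out.index]
    out["mean_case"] = mean_case[out.index]
    out["delta"] = delta[out.index]
    out["p"] = p[out.index]
    if delta_only:
        out["q"] = np.nan
    else:
        out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([], dtype=float)
    return out.reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_hypo_blocks(tilestats: pd.DataFrame, config: BlockConfig) -> HypoBlockSet:
    """Assemble hypomethylated blocks from tile statistics.

    Keeps tiles with q <= fdr_threshold (or all tiles in delta-only mode) and
    delta <= -min_delta; merges kept tiles on the same chromosome whose gap is
    <= merge_gap into one block spanning first start to last end (intervening
    gaps included); drops blocks with fewer than min_block_cpgs CpGs summed
    over member tiles.  Block mean_delta is the CpG-count-weighted mean of
    member-tile deltas.
    """
    empty = HypoBlockSet(
        IntervalSet([], "hypo_blocks"),
        pd.DataFrame(columns=["chrom", "start", "end", "n_cpgs", "n_tiles", "mean_delta"]),
    )
    if len(tilestats) == 0:
        return empty
    keep = tilestats["delta"] <= -config.min_delta
    if not config.delta_only:
        keep &= tilestats["q"] <= config.fdr_threshold
    kept = tilestats.loc[keep].sort_values(["chrom", "start"], kind="stable")
    if len(kept) == 0:
        return empty

    rows = []
    for chrom, sub in kept.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        gaps = starts[1:] - ends[:-1]
        breaks = np.flatnonzero(gaps > config.merge_gap)
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            block = sub.iloc[a:b]
            n_cpgs = int(block["n_cpgs"].sum())
            if n_cpgs < config.min_block_cpgs:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[a]),
                    "end": int(ends[b - 1]),
                    "n_cpgs": n_cpgs,
                    "n_tiles": int(b - a),
                    "mean_delta": float(
                        np.average(block["delta"], weights=block["n_cpgs"])
                    ),
                }
            )
    stats_df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpgs", "n_tiles", "mean_delta"]
    )
    ivs = IntervalSet.from_arrays(
        stats_df["chrom"], stats_df["start"], stats_df["end"], "hypo_blocks"
    ).normalize()
    return HypoBlockSet(ivs, stats_df)


def call_blocks(
    methylome: MethylomeTable,
    groups: tuple[str, str],
    genome: GenomeModel,
    config: BlockConfig = BlockConfig(),
) -> tuple[HypoBlockSet, pd.DataFrame]:
    """Convenience: tile, test, and assemble in one call."""
    tiles = tile_genome(genome, config.tile_size)
    ts = tile_differential(
        methylome, groups, tiles, config.min_tile_cpgs, config.delta_only
    )
    return call_hypo_blocks(ts, config), ts


def _per_cpg_stats(
    methylome: MethylomeTable, groups: tuple[str, str]
) -> pd.DataFrame:
    """Per-CpG group means, delta and Welch p (NaN-tolerant)."""
    ref, case = _group_matrices(methylome, groups)
    beta = methylome.beta
    ref_m = beta[ref].to_numpy()
    case_m = beta[case].to_numpy()
    mean_ref = np.nanmean(ref_m, axis=1)
    mean_case = np.nanmean(case_m, axis=1)
    delta = mean_case - mean_ref
    if len(ref) >= 2 and len(case) >= 2:
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant CpGs are expected
            p = stats.ttest_ind(
                case_m, ref_m, axis=1, equal_var=False, nan_policy="omit"
            ).pvalue
        p = np.where(np.isnan(p) & np.isfinite(delta), 1.0, np.asarray(p, float))
    else:
        p = np.full(len(beta), np.nan)
    out = methylome.sites.copy()
    out["mean_ref"] = mean_ref
    out["mean_case"] = mean_case
    out["delta"] = delta
    out["p"] = p
    return out


def call_dmr(
    methylome: MethylomeTable,
    groups: tuple[str, str],
    config: DMRConfig = DMRConfig(),
) -> pd.DataFrame:
    """Differentially methylated regions.

    Candidate regions are maximal runs of consecutive CpGs with inter-CpG gap
    <= max_cpg_gap and a consistent sign of the group difference (zero
    differences break a run).  A region is emitted when it holds
    >= min_region_cpgs CpGs of which >= 1 has |delta| > per_cpg_delta at
    p <= per_cpg_p; direction is 'hypo' or 'hyper' by the shared sign.
    """
    cpg = _per_cpg_stats(methylome, groups)
    rows = []
    for chrom, sub in cpg.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        p = sub["p"].to_numpy()
        sign = np.sign(delta)
        n = len(sub)
        start = 0
        for i in range(1, n + 1):
            new_run = (
                i == n
                or sign[i] != sign[i - 1]
                or sign[i] == 0
                or pos[i] - pos[i - 1] > config.max_cpg_gap
            )
            if not new_run:
                continue
            run = slice(start, i)
            start = i
            if sign[run.start] == 0:
                continue
            n_cpgs = run.stop - run.start
            if n_cpgs < config.min_region_cpgs:
                continue
            passing = (
                (np.abs(delta[run]) > config.per_cpg_delta)
                & (p[run] <= config.per_cpg_p)
            )
            if not passing.any():
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[run.start]),
                    "end": int(pos[run.stop - 1]) + 1,
                    "n_cpgs": int(n_cpgs),
                    "n_passing": int(passing.sum()),
                    "mean_delta": float(delta[run].mean()),
                    "direction": "hypo" if sign[run.start] < 0 else "hyper",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_cpgs", "n_passing", "mean_delta", "direction"],
    )


def call_dmc(
    methylome: MethylomeTable,
    groups: tuple[str, str],
    context_tracks: dict[str, IntervalSet],
    per_cpg_delta: float = 0.20,
    per_cpg_q: float = 0.05,
) -> pd.DataFrame:
    """Per-context differentially methylated CpG counts.

    Within each context (genes, islands, shores, shelves, open seas, ...), a
    CpG is a DMC when |delta| > per_cpg_delta and its BH q (computed over the
    CpGs of that context) is <= per_cpg_q.  A CpG may belong to several
    contexts.  Returns columns context, n_cpgs, n_hyper, n_hypo.
    """
    if not context_tracks:
        raise ValueError("no context tracks given")
    cpg = _per_cpg_stats(methylome, groups)
    points = list(zip(cpg["chrom"], cpg["pos"]))
    rows = []
    for name, track in context_tracks.items():
        member = points_in_set(points, track.normalize())
        sub = cpg.loc[member & np.isfinite(cpg["p"])]
        if len(sub):
            q = bh_adjust(sub["p"].to_numpy())
            sig = (np.abs(sub["delta"].to_numpy()) > per_cpg_delta) & (q <= per_cpg_q)
            d = sub["delta"].to_numpy()
            n_hyper = int((sig & (d > 0)).sum())
            n_hypo = int((sig & (d < 0)).sum())
        else:
            n_hyper = n_hypo = 0
        rows.append(
            {"context": name, "n_cpgs": int(member.sum()), "n_hyper": n_hyper, "n_hypo": n_hypo}
        )
    return pd.DataFrame(rows, columns=["context", "n_cpgs", "n_hyper", "n_hypo"])
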