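"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the data layout of a tumor global-hypomethylation
study: two tumor groups plus a normal-epithelium reference, where the
hypomethylated ("case") group carries large contiguous blocks of 35-50%
methylation decrease covering a configurable fraction of the genome;
feature tracks placed with configurable enrichment inside those blocks;
per-sample copy-number segments concentrated in blocks by a configurable
factor; and a log2 expression matrix with planted proliferation-marker
effects, a chromosomal-instability signature shift, and inflated in-block
variability in case samples.

Every generator is deterministic under its seed, and every planted
parameter is recoverable by the matching pipeline stage (block caller,
enrichment tests, CNA densities, MAD contrast, signature score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_intervals import GenomeModel, Interval, IntervalSet
from .io_formats import CNASegmentTable, ExpressionTable, MethylomeTable
from .block_calling import HypoBlockSet

REF_GROUP = "NE"
CASE_GROUP = "GDHO+"
OTHER_GROUP = "GDHO-"


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: 2 x 25 Mb genome, CpG every ~500 bp, baseline
    methylation 0.8, blocks of 300-900 kb carrying a 0.40 decrease over 15%
    of the genome, 4 samples per group."""

    seed: int
    n_chrom: int = 2
    chrom_length: int = 25_000_000
    cpg_spacing: float = 500.0
    baseline_beta: float = 0.8
    baseline_sd: float = 0.05
    noise_sd: float = 0.05
    block_fraction: float = 0.15
    block_min_len: int = 300_000
    block_max_len: int = 900_000
    block_delta: float = 0.40
    n_ref: int = 4
    n_case: int = 4
    n_other: int = 0  # optional non-hypomethylated tumor group

    def __post_init__(self) -> None:
        for f in ("baseline_beta", "baseline_sd", "noise_sd", "block_fraction", "block_delta"):
            if not 0 <= getattr(self, f) <= 1:
                raise ValueError(f"{f} must be in [0,1]")
        if self.n_chrom < 1 or self.chrom_length <= 0 or self.cpg_spacing <= 0:
            raise ValueError("genome spec must be positive")

    def genome(self) -> GenomeModel:
        return GenomeModel(
            tuple((f"chr{i + 1}", self.chrom_length) for i in range(self.n_chrom))
        )

    def groups(self) -> dict[str, str]:
        g = {f"ne{i + 1}": REF_GROUP for i in range(self.n_ref)}
        g.update({f"case{i + 1}": CASE_GROUP for i in range(self.n_case)})
        g.update({f"neg{i + 1}": OTHER_GROUP for i in range(self.n_other)})
        return g


def plant_blocks(cfg: SimConfig, rng: np.random.Generator) -> IntervalSet:
    """Non-overlapping truth blocks covering ~block_fraction of the genome."""
    genome = cfg.genome()
    target = cfg.block_fraction * genome.total_size
    if cfg.block_max_len > cfg.chrom_length:
        raise ValueError("block length exceeds chromosome length")
    placed: list[Interval] = []
    covered = 0
    guard = 0
    while covered < target and guard < 10_000:
        guard += 1
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        length = int(rng.integers(cfg.block_min_len, cfg.block_max_len + 1))
        start = int(rng.integers(0, cfg.chrom_length - length + 1))
        cand = Interval(chrom, start, start + length)
        # keep blocks separated so the caller sees them as distinct
        if any(
            iv.chrom == cand.chrom and cand.start < iv.end + 600_000 and iv.start < cand.end + 600_000
            for iv in placed
        ):
            continue
        placed.append(cand)
        covered += length
    return IntervalSet(placed, "truth_blocks").normalize()


def simulate_methylome(
    cfg: SimConfig, truth_blocks: IntervalSet | None = None
) -> tuple[MethylomeTable, HypoBlockSet]:
    """Methylation fractions per CpG per sample, plus the planted truth.

    CpG positions follow exponential spacing; every sample fluctuates around
    a shared per-CpG baseline (truncated-normal noise, clipped to [0,1]);
    case samples are additionally decreased by ``block_delta`` inside truth
    blocks.
    """
    rng = np.random.default_rng(cfg.seed)
    if truth_blocks is None:
        truth_blocks = plant_blocks(cfg, rng)
    genome = cfg.genome()
    truth_blocks.validate(genome)

    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for name, length in genome.chromosomes:
        gaps = rng.exponential(cfg.cpg_spacing, int(2.5 * length / cfg.cpg_spacing))
        pos = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
        pos = pos[pos < length]
        chroms.extend([name] * len(pos))
        positions.append(pos)
    pos_all = np.concatenate(positions)
    sites = pd.DataFrame({"chrom": chroms, "pos": pos_all})

    from .genome_intervals import points_in_set

    in_block = points_in_set(zip(sites["chrom"], sites["pos"]), truth_blocks)
    base = np.clip(
        rng.normal(cfg.baseline_beta, cfg.baseline_sd, len(sites)), 0.0, 1.0
    )
    groups = cfg.groups()
    cols = {}
    for sample, group in groups.items():
        mu = base - (cfg.block_delta * in_block if group == CASE_GROUP else 0.0)
        cols[sample] = np.clip(rng.normal(mu, cfg.noise_sd), 0.0, 1.0)
    beta = pd.DataFrame(cols)
    table = MethylomeTable(sites, beta, groups)
    truth = HypoBlockSet(
        truth_blocks,
        pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in truth_blocks],
                "start": [iv.start for iv in truth_blocks],
                "end": [iv.end for iv in truth_blocks],
                "n_cpgs": [
                    int(points_in_set(zip(sites["chrom"], sites["pos"]), IntervalSet([iv]).normalize()).sum())
                    for iv in truth_blocks
                ],
                "n_tiles": np.nan,
                "mean_delta": -cfg.block_delta,
            }
        ),
    )
    return table, truth


@dataclass(frozen=True)
class TrackSpec:
    n_features: int
    feature_length: int = 500
    enrichment: float = 1.0  # in-block placement factor; 1 = uniform


def simulate_tracks(
    cfg: SimConfig,
    truth_blocks: IntervalSet,
    specs: dict[str, TrackSpec],
    seed: int | None = None,
) -> dict[str, IntervalSet]:
    """Feature tracks with configurable in-block enrichment.

    The enrichment factor f is the target midpoint fold enrichment: a
    feature midpoint lands inside blocks with probability f*B (B = block
    genome fraction), so factor 1 reproduces uniform placement and the
    fold-enrichment statistic recovers f in expectation.  Requires f*B <= 1.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = cfg.genome()
    B = truth_blocks.bases() / genome.total_size
    block_arr = [(iv.chrom, iv.start, iv.end) for iv in truth_blocks]
    block_lens = np.array([e - s for _, s, e in block_arr], dtype=float)
    lengths = genome.lengths
    tracks: dict[str, IntervalSet] = {}
    for name, spec in specs.items():
        ivs = []
        p_in = spec.enrichment * B if block_arr else 0.0
        if p_in > 1:
            raise ValueError(
                f"track {name!r}: enrichment {spec.enrichment} x block fraction "
                f"{B:.3f} exceeds 1; no placement satisfies it"
            )
        for _ in range(spec.n_features):
            if rng.random() < p_in:
                k = int(rng.choice(len(block_arr), p=block_lens / block_lens.sum()))
                chrom, s, e = block_arr[k]
                mid = int(rng.integers(s, e))
            else:
                # rejection-sample a uniform midpoint outside blocks
                while True:
                    chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
                    mid = int(rng.integers(0, lengths[chrom]))
                    if not any(
                        c == chrom and s <= mid < e for c, s, e in block_arr
                    ):
                        break
            half = spec.feature_length // 2
            start = max(0, mid - half)
            end = min(lengths[chrom], mid + half + (spec.feature_length % 2 or 1))
            ivs.append(Interval(chrom, start, max(end, start + 1)))
        tracks[name] = IntervalSet(ivs, name)
    return tracks


@dataclass(frozen=True)
class CNASpec:
    altered_fraction: float = 0.10  # of the genome, per sample
    segment_length: int = 200_000
    concentration: float = 1.0  # target in-block/out-block density ratio
    n_samples: int = 10
    group: str = CASE_GROUP


def _compartment_pieces(
    truth_blocks: IntervalSet, genome: GenomeModel
) -> tuple[list[Interval], list[Interval]]:
    from .genome_intervals import complement

    inside = list(truth_blocks)
    outside = list(complement(truth_blocks, genome))
    return inside, outside


def _place_in_pieces(
    pieces: list[Interval], length: int, rng: np.random.Generator
) -> Interval:
    lens = np.array([len(p) for p in pieces], dtype=float)
    piece = pieces[int(rng.choice(len(pieces), p=lens / lens.sum()))]
    if len(piece) > length:
        start = int(rng.integers(piece.start, piece.end - length + 1))
        return Interval(piece.chrom, start, start + length)
    return piece  # piece shorter than segment: truncate to it


def simulate_cna(
    cfg: SimConfig,
    truth_blocks: IntervalSet,
    spec: CNASpec,
    seed: int | None = None,
) -> CNASegmentTable:
    """Per-sample gain/loss segments concentrated in blocks.

    Each segment is placed wholly inside the block compartment with
    probability c*B / (c*B + 1 - B) and wholly outside otherwise, so the
    expected in/out CNA density ratio equals the concentration c exactly
    (c = 1 is a uniform null).  Calls are gain or loss at random.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genome = cfg.genome()
    inside, outside = _compartment_pieces(truth_blocks, genome)
    B = truth_blocks.bases() / genome.total_size
    c = spec.concentration
    p_in = c * B / (c * B + (1 - B)) if inside else 0.0
    n_segments = max(1, round(spec.altered_fraction * genome.total_size / spec.segment_length))
    rows = []
    for i in range(spec.n_samples):
        sample = f"{spec.group}_s{i + 1}"
        placed: list[Interval] = []
        for _ in range(n_segments):
            pieces = inside if (inside and rng.random() < p_in) else outside
            # non-overlapping within a sample so planted densities are exact
            for _attempt in range(200):
                cand = _place_in_pieces(pieces, spec.segment_length, rng)
                if not any(
                    iv.chrom == cand.chrom and cand.start < iv.end and iv.start < cand.end
                    for iv in placed
                ):
                    break
            placed.append(cand)
        merged = IntervalSet(placed, sample).normalize()
        for iv in merged:
            rows.append(
                {
                    "sample": sample,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "call": "gain" if rng.random() < 0.5 else "loss",
                }
            )
    return CNASegmentTable(
        pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "call"])
    )


@dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 400
    base_mean: float = 7.0
    base_sd: float = 1.0
    noise_sd: float = 0.4
    inblock_var_multiplier: float = 2.0  # case-sample noise factor for in-block genes
    proliferation_markers: tuple[str, ...] = ("MKI67", "PLK1", "BUB1")
    proliferation_effect: float = 1.5  # case-group log2 shift of markers
    maintenance_genes: tuple[str, ...] = ("DNMT1", "DNMT3A", "DNMT3B", "DNMT3L", "UHRF1")
    signature_genes: tuple[str, ...] = tuple(f"CIN{i + 1}" for i in range(25))
    signature_effect: float = 0.8  # mean case-group log2 shift of signature genes
    n_deg: int = 0
    deg_effect: float = 1.0


def simulate_expression(
    cfg: SimConfig,
    truth_blocks: IntervalSet,
    spec: ExpressionSpec = ExpressionSpec(),
    seed: int | None = None,
) -> tuple[ExpressionTable, dict[str, Interval]]:
    """Log2 expression with planted group effects and in-block variability.

    Named proliferation markers are shifted up in case samples while
    maintenance-methylation genes stay flat (so marker-normalized ratios
    drop in the case group); signature genes get N(effect, 0.1) shifts;
    genes whose midpoint falls in a truth block have their case-sample noise
    scaled by ``inblock_var_multiplier``.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    genome = cfg.genome()
    named = (
        list(spec.proliferation_markers)
        + list(spec.maintenance_genes)
        + list(spec.signature_genes)
    )
    n_anon = max(spec.n_genes - len(named), 0)
    genes = named + [f"G{i + 1}" for i in range(n_anon)]

    lengths = genome.lengths
    coords: dict[str, Interval] = {}
    for g in genes:
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        start = int(rng.integers(0, lengths[chrom] - 10_000))
        coords[g] = Interval(chrom, start, start + 10_000)

    from .genome_intervals import points_in_set

    pts = [(coords[g].chrom, coords[g].midpoint) for g in genes]
    in_block = points_in_set(pts, truth_blocks)

    groups = cfg.groups()
    base = rng.normal(spec.base_mean, spec.base_sd, len(genes))
    shift = np.zeros(len(genes))
    for i, g in enumerate(genes):
        if g in spec.proliferation_markers:
            shift[i] = spec.proliferation_effect
        elif g in spec.signature_genes:
            shift[i] = rng.normal(spec.signature_effect, 0.1)
    # optional generic DEGs among anonymous genes, alternating direction
    anon_idx = [i for i, g in enumerate(genes) if g.startswith("G")]
    for j, i in enumerate(anon_idx[: spec.n_deg]):
        shift[i] = spec.deg_effect * (1 if j % 2 == 0 else -1)

    cols = {}
    for sample, group in groups.items():
        is_case = group == CASE_GROUP
        sd = np.where(
            in_block & is_case, spec.noise_sd * spec.inblock_var_multiplier, spec.noise_sd
        )
        mu = base + (shift if is_case else 0.0)
        cols[sample] = rng.normal(mu, sd)
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return ExpressionTable(values, coords, groups), coords
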