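"""Copy-number alteration burden and its spatial relationship to blocks.

The CNA index of a sample is the fraction of the genome covered by the
union of its gained and lost segments (gains and losses pooled).  Group
comparisons use the two-sided Mann-Whitney U.  Block overlap is reported
as coverage-normalized densities: CNA base pairs inside blocks per block
base pair versus CNA base pairs outside blocks per non-block base pair,
compared across samples by a Wilcoxon signed-rank on the paired per-sample
densities (a repeated-measures ANOVA on the same layout is also offered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_intervals import GenomeModel, IntervalSet, complement, intersect_bases
from .io_formats import CNASegmentTable
from .feature_enrichment import _blocks_intervals


@dataclass
class CNAIndex:
    sample: str
    fraction_altered: float
    bases_gain: int
    bases_loss: int


@dataclass
class BlockOverlapResult:
    bases_in_blocks: int
    bases_outside: int
    density_in: float
    density_out: float
    p: float
    per_sample: pd.DataFrame = field(repr=False, default=None)


def cna_index(segments: CNASegmentTable, genome: GenomeModel) -> list[CNAIndex]:
    """Per-sample fraction of the genome gained or lost (union, no double count)."""
    out = []
    for sample in segments.samples:
        gain = segments.sample_intervals(sample, calls=("gain",))
        loss = segments.sample_intervals(sample, calls=("loss",))
        altered = segments.sample_intervals(sample, calls=("gain", "loss"))
        altered.validate(genome)
        out.append(
            CNAIndex(
                sample=sample,
                fraction_altered=altered.bases() / genome.total_size,
                bases_gain=gain.bases(),
                bases_loss=loss.bases(),
            )
        )
    return out


def compare_groups(
    indices: list[CNAIndex], labels: dict[str, str], groups: tuple[str, str]
) -> dict:
    """Median per group plus two-sided Mann-Whitney U between the two groups."""
    a_name, b_name = groups
    a = [ix.fraction_altered for ix in indices if labels.get(ix.sample) == a_name]
    b = [ix.fraction_altered for ix in indices if labels.get(ix.sample) == b_name]
    if not a or not b:
        empty = a_name if not a else b_name
        raise ValueError(f"group {empty!r} has no samples with a CNA index")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "groups": groups,
        "median": {a_name: float(np.median(a)), b_name: float(np.median(b))},
        "n": {a_name: len(a), b_name: len(b)},
        "U": float(res.statistic),
        "p": float(res.pvalue),
    }


def cna_block_overlap(
    segments: CNASegmentTable,
    blocks,
    genome: GenomeModel,
    test: str = "wilcoxon",
) -> BlockOverlapResult:
    """Coverage-normalized CNA density inside vs outside hypomethylated blocks.

    density_in = (CNA bp inside blocks) / (block bp); density_out likewise on
    the block complement.  Pooled across samples for the headline densities;
    the p-value compares the paired per-sample densities (Wilcoxon signed-rank
    by default, ``test='anova'`` for a repeated-measures F on the same pairs).
    """
    block_ivs = _blocks_intervals(blocks).normalize()
    block_bases = block_ivs.bases()
    total = genome.total_size
    if block_bases == 0 or block_bases == total:
        raise ValueError("blocks cover 0% or 100% of the genome; densities undefined")
    outside_ivs = complement(block_ivs, genome)
    out_bases = outside_ivs.bases()

    rows = []
    for sample in segments.samples:
        altered = segments.sample_intervals(sample, calls=("gain", "loss"))
        inb = intersect_bases(altered, block_ivs)
        outb = altered.bases() - inb
        rows.append(
            {
                "sample": sample,
                "bases_in": inb,
                "bases_out": outb,
                "density_in": inb / block_bases,
                "density_out": outb / out_bases,
            }
        )
    per_sample = pd.DataFrame(rows)
    tot_in = int(per_sample["bases_in"].sum())
    tot_out = int(per_sample["bases_out"].sum())

    d_in = per_sample["density_in"].to_numpy()
    d_out = per_sample["density_out"].to_numpy()
    if len(per_sample) < 2 or np.allclose(d_in, d_out):
        p = 1.0
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(d_in, d_out).pvalue)
    elif test == "anova":
        # paired one-way layout: equivalent to a paired t on the differences
        p = float(stats.ttest_rel(d_in, d_out).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}; use 'wilcoxon' or 'anova'")

    return BlockOverlapResult(
        bases_in_blocks=tot_in,
        bases_outside=tot_out,
        density_in=tot_in / block_bases / max(len(per_sample), 1),
        density_out=tot_out / out_bases / max(len(per_sample), 1),
        p=p,
        per_sample=per_sample,
    )
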