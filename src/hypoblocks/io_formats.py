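"""Readers and writers for every on-disk table the pipeline touches.

All formats are plain TSV with fixed, documented column orders so that
outputs are diff-able:

* methylome — header ``chrom  pos  <sample1>  <sample2> ...``; methylation
  fractions in [0, 1], missing encoded ``NA``; positions strictly increasing
  within each chromosome.
* CNA segments — SEG-like header ``sample  chrom  start  end  call`` with
  call in {gain, loss, neutral}.
* expression — header ``gene  <sample1> ...`` of finite log2 values.
* sample groups — header ``sample  group``.
* gene coordinates — BED4: chrom, start, end, gene.

Every parse error names the file, line and offending field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_intervals import GenomeModel, Interval, IntervalSet

CNA_CALLS = ("gain", "loss", "neutral")


class ParseError(ValueError):
    pass


@dataclass
class MethylomeTable:
    """Per-CpG methylation fractions across samples.

    ``sites`` holds columns chrom (str), pos (int); ``beta`` is a float
    DataFrame (same row order) with one column per sample, NaN = missing.
    """

    sites: pd.DataFrame
    beta: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]


@dataclass
class CNASegmentTable:
    """Per-sample copy-number segments with gain/loss/neutral calls."""

    segments: pd.DataFrame  # sample, chrom, start, end, call

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.segments["sample"]))

    def sample_intervals(self, sample: str, calls=("gain", "loss")) -> IntervalSet:
        sub = self.segments[
            (self.segments["sample"] == sample) & self.segments["call"].isin(calls)
        ]
        return IntervalSet.from_arrays(
            sub["chrom"], sub["start"], sub["end"], name=sample
        ).normalize()


@dataclass
class ExpressionTable:
    """Genes x samples matrix of log2 expression, with optional gene coordinates."""

    values: pd.DataFrame  # index gene, columns samples
    gene_coords: dict[str, Interval] | None = None
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]


def read_methylome(path, genome: GenomeModel | None = None) -> MethylomeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[:2] != ["chrom", "pos"]:
            raise ParseError(f"{path}:1: header must start with 'chrom\\tpos'")
        samples = header[2:]
        chroms: list[str] = []
        positions: list[int] = []
        rows: list[list[float]] = []
        last: dict[str, int] = {}
        lengths = genome.lengths if genome is not None else None
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields")
            chrom, pos_s = parts[0], parts[1]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            if chrom in last and pos <= last[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: positions not strictly increasing on {chrom}"
                )
            last[chrom] = pos
            if lengths is not None:
                if chrom not in lengths or not (0 <= pos < lengths[chrom]):
                    raise ParseError(f"{path}:{lineno}: {chrom}:{pos} outside genome")
            vals: list[float] = []
            for sample, tok in zip(samples, parts[2:]):
                if tok == "NA":
                    vals.append(np.nan)
                    continue
                try:
                    v = float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric fraction {tok!r} for {sample}"
                    ) from None
                if not 0.0 <= v <= 1.0:
                    raise ParseError(
                        f"{path}:{lineno}: fraction {v} for {sample} outside [0,1]"
                    )
                vals.append(v)
            chroms.append(chrom)
            positions.append(pos)
            rows.append(vals)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions})
    beta = pd.DataFrame(rows, columns=samples, dtype=float)
    return MethylomeTable(sites, beta)


def write_methylome(table: MethylomeTable, path) -> None:
    """Canonical format: fractions to 4 decimals, missing as NA."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(table.samples) + "\n")
        beta = table.beta.to_numpy()
        for i in range(table.n_sites):
            cells = [
                "NA" if np.isnan(v) else format(v, ".4f") for v in beta[i]
            ]
            fh.write(
                f"{table.sites['chrom'].iat[i]}\t{table.sites['pos'].iat[i]}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_segments(path, genome: GenomeModel | None = None) -> CNASegmentTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample": str, "chrom": str, "start": int, "end": int, "call": str}
    )
    required = ["sample", "chrom", "start", "end", "call"]
    if list(df.columns[:5]) != required:
        raise ParseError(f"{path}: header must be {required}")
    bad = ~df["call"].isin(CNA_CALLS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: line {i + 2}: unknown call {df['call'].iat[i]!r}; "
            f"allowed: {', '.join(CNA_CALLS)}"
        )
    if genome is not None:
        lengths = genome.lengths
        for i, row in df.iterrows():
            if row["chrom"] not in lengths or not (
                0 <= row["start"] < row["end"] <= lengths[row["chrom"]]
            ):
                raise ParseError(
                    f"{path}: line {i + 2}: segment "
                    f"{row['chrom']}:{row['start']}-{row['end']} outside genome"
                )
    return CNASegmentTable(_resolve_segment_overlaps(df, path))


def _resolve_segment_overlaps(df: pd.DataFrame, path) -> pd.DataFrame:
    """Within a sample, later-read segments take precedence over earlier ones.

    ChAS-style callers emit disjoint segments; overlaps are user error but must
    resolve deterministically, so earlier segments are trimmed around later ones
    and a warning is emitted.
    """
    out_rows = []
    for sample, sub in df.groupby("sample", sort=False):
        kept: list[dict] = []
        clipped = False
        for _, row in sub.iterrows():
            new = {c: row[c] for c in ("sample", "chrom", "start", "end", "call")}
            next_kept = []
            for old in kept:
                if old["chrom"] != new["chrom"] or old["end"] <= new["start"] or old["start"] >= new["end"]:
                    next_kept.append(old)
                    continue
                clipped = True
                if old["start"] < new["start"]:
                    next_kept.append({**old, "end": new["start"]})
                if old["end"] > new["end"]:
                    next_kept.append({**old, "start": new["end"]})
            kept = next_kept + [new]
        if clipped:
            warnings.warn(
                f"{path}: overlapping segments for sample {sample!r}; "
                "kept latest-read call in conflicting regions"
            )
        out_rows.extend(kept)
    out = pd.DataFrame(out_rows, columns=["sample", "chrom", "start", "end", "call"])
    return out.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(drop=True)


def write_segments(table: CNASegmentTable, path) -> None:
    table.segments.to_csv(path, sep="\t", index=False)


def read_expression(path, coords_bed=None) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ParseError(f"{path}: first column must be 'gene'")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate gene identifier {dup!r}")
    values = df.set_index("gene").astype(float)
    if not np.isfinite(values.to_numpy()).all():
        raise ParseError(f"{path}: expression values must be finite")
    coords = read_gene_coords(coords_bed) if coords_bed is not None else None
    return ExpressionTable(values, coords)


def write_expression(table: ExpressionTable, path) -> None:
    table.values.round(6).to_csv(path, sep="\t", index_label="gene")


def read_gene_coords(path) -> dict[str, Interval]:
    coords: dict[str, Interval] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: gene BED needs 4 columns")
            coords[parts[3]] = Interval(parts[0], int(parts[1]), int(parts[2]))
    return coords


def write_gene_coords(coords: dict[str, Interval], path) -> None:
    with open(path, "w") as fh:
        for gene, iv in coords.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\n")


def read_groups(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ParseError(f"{path}: header must be 'sample\\tgroup'")
    return dict(zip(df["sample"], df["group"]))


def write_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")
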