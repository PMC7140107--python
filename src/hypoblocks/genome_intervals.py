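"""Genome model and exact interval algebra.

All coordinates are 0-based half-open (BED convention).  An
:class:`IntervalSet` is kept *normalized*: intervals sorted by
(chromosome, start) with overlapping or touching intervals merged, so that
base-pair arithmetic (intersection, union, coverage) is exact set algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np


class Interval(NamedTuple):
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:  # number of bases covered
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeBoundsError(ValueError):
    """Interval coordinates fall outside the genome model."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths; the denominator of every genome fraction."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome model")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total_size(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def check(self, iv: Interval) -> None:
        lengths = self.lengths
        if iv.chrom not in lengths:
            raise GenomeBoundsError(f"unknown chromosome {iv.chrom!r}")
        if iv.start < 0 or iv.end > lengths[iv.chrom]:
            raise GenomeBoundsError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {lengths[iv.chrom]}"
            )

    @classmethod
    def from_tsv(cls, path) -> "GenomeModel":
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                chroms.append((name, int(length)))
        return cls(tuple(chroms))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


@dataclass
class IntervalSet:
    """A named collection of intervals; call :meth:`normalize` before set algebra."""

    intervals: list[Interval] = field(default_factory=list)
    name: str = ""

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def validate(self, genome: GenomeModel) -> None:
        for iv in self.intervals:
            if iv.end <= iv.start or iv.start < 0:
                raise ValueError(f"invalid interval {iv.chrom}:{iv.start}-{iv.end}")
            genome.check(iv)

    def normalize(self) -> "IntervalSet":
        """Sorted, with overlapping and touching intervals merged.

        Idempotent; conserves the set of covered bases.
        """
        for iv in self.intervals:
            if iv.end <= iv.start or iv.start < 0:
                raise ValueError(f"invalid interval {iv.chrom}:{iv.start}-{iv.end}")
        merged: list[Interval] = []
        for iv in sorted(self.intervals, key=lambda x: (x.chrom, x.start, x.end)):
            if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
                prev = merged[-1]
                merged[-1] = Interval(prev.chrom, prev.start, max(prev.end, iv.end))
            else:
                merged.append(iv)
        return IntervalSet(merged, self.name)

    def bases(self) -> int:
        """Total covered base pairs (assumes normalized)."""
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Chromosome -> (n, 2) array of [start, end) rows, in order."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(rows, dtype=np.int64) for c, rows in out.items()}

    @classmethod
    def from_arrays(
        cls, chroms: Iterable[str], starts: Iterable[int], ends: Iterable[int], name: str = ""
    ) -> "IntervalSet":
        return cls(
            [Interval(c, int(s), int(e)) for c, s, e in zip(chroms, starts, ends)], name
        )


def normalize(intervals: IntervalSet) -> IntervalSet:
    return intervals.normalize()


def intersect_bases(a: IntervalSet, b: IntervalSet) -> int:
    """Base pairs covered by both sets (both must be normalized)."""
    total = 0
    b_by = b.by_chrom()
    for chrom, arr_a in a.by_chrom().items():
        if chrom not in b_by:
            continue
        arr_b = b_by[chrom]
        i = j = 0
        while i < len(arr_a) and j < len(arr_b):
            lo = max(arr_a[i, 0], arr_b[j, 0])
            hi = min(arr_a[i, 1], arr_b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if arr_a[i, 1] < arr_b[j, 1]:
                i += 1
            else:
                j += 1
    return total


def union_bases(a: IntervalSet, b: IntervalSet) -> int:
    return a.bases() + b.bases() - intersect_bases(a, b)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of `a` not covered by `b` (both normalized)."""
    out: list[Interval] = []
    b_by = b.by_chrom()
    for iv in a:
        cuts = b_by.get(iv.chrom)
        pos = iv.start
        if cuts is not None:
            for s, e in cuts:
                if e <= pos or s >= iv.end:
                    continue
                if s > pos:
                    out.append(Interval(iv.chrom, pos, int(s)))
                pos = max(pos, int(e))
                if pos >= iv.end:
                    break
        if pos < iv.end:
            out.append(Interval(iv.chrom, pos, iv.end))
    return IntervalSet(out, a.name)


def complement(a: IntervalSet, genome: GenomeModel) -> IntervalSet:
    whole = IntervalSet([Interval(c, 0, L) for c, L in genome.chromosomes])
    return subtract(whole, a.normalize())


def coverage_fraction(intervals: IntervalSet, genome: GenomeModel) -> float:
    """Fraction of the genome covered by the (normalized) set."""
    intervals.validate(genome)
    return intervals.bases() / genome.total_size


def midpoints(intervals: IntervalSet) -> list[tuple[str, int]]:
    """One point per interval: floor((start+end)/2)."""
    return [(iv.chrom, iv.midpoint) for iv in intervals]


def points_in_set(
    points: Iterable[tuple[str, int]], intervals: IntervalSet
) -> np.ndarray:
    """Boolean membership of each (chrom, pos) point in the normalized set."""
    by = intervals.by_chrom()
    flags = []
    for chrom, pos in points:
        arr = by.get(chrom)
        if arr is None or len(arr) == 0:
            flags.append(False)
            continue
        k = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        flags.append(k >= 0 and pos < arr[k, 1])
    return np.asarray(flags, dtype=bool)


def read_bed(path, name: str | None = None) -> IntervalSet:
    """Read BED3+ (tab-separated, no header; ``track``/``browser``/# lines ignored)."""
    ivs: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if (
                not line
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            ivs.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    import os

    return IntervalSet(ivs, name if name is not None else os.path.basename(str(path)))


def write_bed(intervals: IntervalSet, path, scores: Iterable[float] | None = None) -> None:
    """Write BED3, or BED6 (name=set name, score, strand '.') when scores given."""
    with open(path, "w") as fh:
        if scores is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for i, (iv, sc) in enumerate(zip(intervals, scores)):
                nm = f"{intervals.name or 'region'}_{i + 1}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t{sc:g}\t.\n")
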