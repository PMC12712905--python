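"""Typed genomic primitives and plain-text readers/writers.

Coordinate convention is 0-based half-open throughout (BED/BEDPE style);
1-based inputs are *not* auto-detected. Parsers validate and raise
:class:`ParseError` naming the offending line rather than coercing.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomicInterval",
    "Interaction",
    "Gene",
    "SampleSheet",
    "CountMatrix",
    "IntervalIndex",
    "overlaps",
    "span",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_counts",
    "write_counts",
    "read_genes",
    "write_genes",
    "read_sample_sheet",
    "write_sample_sheet",
]


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interaction:
    """Ordered pair of anchors; anchors are stored in coordinate order."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    id: str = ""

    def __post_init__(self) -> None:
        a, b = self.anchor1, self.anchor2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)

    @property
    def intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for gene {self.id}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for gene {self.id}")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share >=1 bp under half-open semantics."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def span(interaction: Interaction) -> int:
    """Midpoint-to-midpoint distance in bp (floor).

    Midpoints make the span invariant to anchor width, which matters for the
    >5 kb confidence filter. Inter-chromosomal pairs have no defined span.
    """
    if not interaction.intra:
        raise ValueError(
            f"span undefined for inter-chromosomal interaction {interaction.id!r}"
        )
    return abs(interaction.anchor2.midpoint - interaction.anchor1.midpoint)


class IntervalIndex:
    """Existence-of-overlap queries against a fixed interval set.

    Per chromosome, intervals are sorted by start and a running maximum of
    ends is kept, so ``any_overlap`` is O(log n).
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: x.start)
            starts = [iv.start for iv in ivs]
            maxend: list[int] = []
            running = -1
            for iv in ivs:
                running = max(running, iv.end)
                maxend.append(running)
            self._starts[chrom] = starts
            self._maxend[chrom] = maxend

    def any_overlap(self, query: GenomicInterval) -> bool:
        starts = self._starts.get(query.chrom)
        if not starts:
            return False
        # candidates: intervals with start < query.end
        i = bisect.bisect_left(starts, query.end)
        if i == 0:
            return False
        return self._maxend[query.chrom][i - 1] > query.start


@dataclass
class SampleSheet:
    """Sample metadata; (strain, assay, replicate) must be unique."""

    table: pd.DataFrame

    REQUIRED = ("sample", "strain", "assay", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ParseError(f"sample sheet missing columns: {missing}")
        key = self.table[["strain", "assay", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ParseError(f"duplicate (strain, assay, replicate): {dup}")
        if self.table["sample"].duplicated().any():
            raise ParseError("duplicate sample ids in sample sheet")

    def samples_for(self, *, strain: str | None = None, assay: str | None = None) -> list[str]:
        t = self.table
        if strain is not None:
            t = t[t["strain"] == strain]
        if assay is not None:
            t = t[t["assay"] == assay]
        return t["sample"].tolist()

    @property
    def strains(self) -> list[str]:
        return sorted(self.table["strain"].unique())


@dataclass
class CountMatrix:
    """Non-negative integer counts, features x samples."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.df.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        if not self.df.index.is_unique:
            raise ValueError("feature ids are not unique")
        values = self.df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("count matrix contains non-integer values")
            self.df = self.df.round().astype(np.int64)
        if (self.df.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.df.columns]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing}")
        return CountMatrix(self.df[list(samples)].copy())


# ---------------------------------------------------------------------------
# readers / writers


def _parse_int(token: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path} line {lineno}: non-integer {what} {token!r}") from None


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    path = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: expected >=3 BED fields")
            chrom = fields[0]
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
            if start < 0:
                raise ParseError(f"{path} line {lineno}: negative start {start}")
            if start >= end:
                raise ParseError(f"{path} line {lineno}: start {start} >= end {end}")
            intervals.append(GenomicInterval(chrom, start, end, name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_bedpe(path: str | Path) -> list[Interaction]:
    interactions = []
    path = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path} line {lineno}: expected >=6 BEDPE fields")
            coords = []
            for i, what in ((1, "start1"), (2, "end1"), (4, "start2"), (5, "end2")):
                coords.append(_parse_int(fields[i], what, path, lineno))
            s1, e1, s2, e2 = coords
            for s, e, tag in ((s1, e1, "anchor1"), (s2, e2, "anchor2")):
                if s < 0:
                    raise ParseError(f"{path} line {lineno}: negative {tag} start {s}")
                if s >= e:
                    raise ParseError(f"{path} line {lineno}: {tag} start {s} >= end {e}")
            name = fields[6] if len(fields) > 6 else f"ixn_{lineno}"
            interactions.append(
                Interaction(
                    GenomicInterval(fields[0], s1, e1),
                    GenomicInterval(fields[3], s2, e2),
                    id=name,
                )
            )
    return interactions


def write_bedpe(interactions: Iterable[Interaction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ixn in interactions:
            a, b = ixn.anchor1, ixn.anchor2
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{ixn.id}\n"
            )


def read_counts(path: str | Path) -> CountMatrix:
    path = str(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ParseError(f"{path}: empty counts table")
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna()
            row = df.index[bad.argmax()]
            raise ParseError(f"{path}: non-numeric count at row {row!r}, column {col!r}")
        vals = df[col].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            row = df.index[int(np.argmax(vals != np.round(vals)))]
            raise ParseError(f"{path}: non-integer count at row {row!r}, column {col!r}")
    try:
        return CountMatrix(df.astype(np.int64))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="feature_id")


def read_genes(path: str | Path) -> list[Gene]:
    path = str(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: genes table missing columns {sorted(missing)}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            genes.append(Gene(str(row.gene_id), str(row.chrom), int(row.tss), str(row.strand)))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from None
    return genes


def write_genes(genes: Iterable[Gene], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id if hasattr(g, "gene_id") else g.id, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "strain": str, "assay": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)
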