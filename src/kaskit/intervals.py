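"""Coordinate conventions, interval algebra, and BED / chrom.sizes I/O.

All coordinates are 0-based half-open, matching the BED standard, both
internally and in every emitted file.  Chromosome names are matched by exact
string equality; no "chr" aliasing is performed, so an annotation/genome
mismatch surfaces immediately instead of being silently papered over.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomicInterval",
    "ReadTag",
    "ChromSizes",
    "GeneModel",
    "Shore",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_gene_bed",
    "interval_subtract",
    "interval_merge",
    "make_shores",
]

_STRANDS = frozenset({"+", "-", "."})


class BedParseError(ValueError):
    """Raised for malformed BED / chrom.sizes input, naming the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally named and stranded."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    extra: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# A ReadTag is one deduplicated, strand-aware mapped fragment.  It shares the
# interval representation; code that requires strand information validates
# strand in {+, -} at the point of use.
ReadTag = GenomicInterval


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp (positive int)."""

    def __init__(self, sizes: dict[str, int] | None = None):
        super().__init__()
        if sizes:
            for name, length in sizes.items():
                self.add(name, length)

    def add(self, name: str, length: int) -> None:
        if name in self:
            raise ValueError(f"duplicate chromosome {name!r}")
        if not isinstance(length, int) or length <= 0:
            raise ValueError(f"chromosome {name!r} length must be a positive int")
        self[name] = length

    def length_of(self, chrom: str) -> int:
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not in chrom.sizes")
        return self[chrom]


@dataclass(frozen=True)
class GeneModel:
    """Transcription span of a gene; TSS/TES are strand-derived."""

    interval: GenomicInterval
    name: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r} must be stranded (+ or -)")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class Shore:
    """A flanking region of nominal width equal to its source element.

    ``usable`` is False when clipping at a chromosome boundary removed 50% or
    more of the nominal width (a degenerate shore makes density ratios
    unstable); ``interval`` is None when the shore clipped away entirely.
    """

    interval: GenomicInterval | None
    usable: bool


# ---------------------------------------------------------------------------
# I/O


def _parse_bed_line(line: str, lineno: int, min_columns: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < max(3, min_columns):
        raise BedParseError(
            f"line {lineno}: expected >= {max(3, min_columns)} columns, got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: malformed coordinate: {exc}") from None
    if start >= end or start < 0:
        raise BedParseError(
            f"line {lineno}: invalid interval {chrom}:{start}-{end} (start >= end)"
        )
    name = fields[3] if len(fields) > 3 else "."
    score = 0.0
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise BedParseError(f"line {lineno}: malformed score {fields[4]!r}") from None
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in _STRANDS:
        raise BedParseError(f"line {lineno}: unknown strand symbol {strand!r}")
    return GenomicInterval(
        chrom, start, end, name=name, score=score, strand=strand,
        extra=tuple(fields[6:]),
    )


def read_bed(path, expected_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED file; browser/track headers are skipped; order preserved."""
    records: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("track", "browser", "#")):
                continue
            records.append(_parse_bed_line(line, lineno, expected_columns))
    return records


def write_bed(records, path, columns: int = 6) -> None:
    """Write BED3 or BED6; deterministic formatting, no header."""
    if columns not in (3, 6):
        raise ValueError("columns must be 3 or 6")
    with open(path, "w") as fh:
        for rec in records:
            if columns == 3:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
            else:
                score = rec.score
                score_str = str(int(score)) if float(score).is_integer() else repr(score)
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t"
                    f"{score_str}\t{rec.strand}\n"
                )


def read_chrom_sizes(path) -> ChromSizes:
    """Read a UCSC two-column chrom.sizes file."""
    sizes = ChromSizes()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"line {lineno}: expected two tab-separated columns")
            try:
                length = int(fields[1])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer chromosome length {fields[1]!r}"
                ) from None
            try:
                sizes.add(fields[0], length)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
    return sizes


def read_gene_bed(path) -> list[GeneModel]:
    """Read gene models from BED6 (transcription span only)."""
    genes = []
    for i, rec in enumerate(read_bed(path, expected_columns=6)):
        name = rec.name if rec.name != "." else f"gene_{i}"
        genes.append(GeneModel(interval=rec, name=name))
    return genes


# ---------------------------------------------------------------------------
# Interval algebra


def _by_chrom(xs):
    key = lambda iv: iv.chrom
    return {c: sorted(g, key=lambda iv: (iv.start, iv.end))
            for c, g in itertools.groupby(sorted(xs, key=key), key=key)}


def interval_merge(xs, max_gap: int = 0) -> list[GenomicInterval]:
    """Union intervals on the same chromosome whose gap is <= ``max_gap``.

    Output is sorted by (chrom, start) and pairwise disjoint per chromosome.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(xs)):
        cur_start = cur_end = None
        for iv in _by_chrom(xs)[chrom]:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def interval_subtract(a, b) -> list[GenomicInterval]:
    """bedtools-subtract semantics: for each interval in ``a``, the maximal
    sub-intervals not covered by any interval in ``b``.

    Metadata (name/score/strand) of the source interval is carried onto its
    surviving fragments.
    """
    b_merged = _by_chrom(interval_merge(b, max_gap=0))
    out: list[GenomicInterval] = []
    for iv in a:
        blockers = [x for x in b_merged.get(iv.chrom, [])
                    if x.start < iv.end and x.end > iv.start]
        pos = iv.start
        for blk in blockers:
            if blk.start > pos:
                out.append(replace(iv, start=pos, end=blk.start))
            pos = max(pos, blk.end)
        if pos < iv.end:
            out.append(replace(iv, start=pos, end=iv.end))
    return out


def make_shores(x: GenomicInterval, sizes: ChromSizes) -> tuple[Shore, Shore]:
    """Flanking regions of width equal to ``x``, clipped at chromosome bounds.

    A shore retaining less than 50% of the nominal width after clipping is
    flagged unusable.
    """
    chrom_len = sizes.length_of(x.chrom)
    width = x.width

    def build(lo: int, hi: int) -> Shore:
        lo_c, hi_c = max(0, lo), min(chrom_len, hi)
        if hi_c <= lo_c:
            return Shore(None, False)
        iv = GenomicInterval(x.chrom, lo_c, hi_c)
        return Shore(iv, iv.width * 2 >= width)

    left = build(x.start - width, x.start)
    right = build(x.end, x.end + width)
    return left, right
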