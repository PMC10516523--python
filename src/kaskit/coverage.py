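"""Read-tag densities: binned tracks, RPKM normalization, region densities,
metagene profiles, and bedGraph output.

Counting semantics follow deepTools ``bamCoverage`` read-count mode: a tag
counts once in every bin it touches (not base-pair coverage).  RPKM for a bin
or region of width *w* bp with *c* overlapping tags out of a library of *N*
tags is ``c * 1e9 / (w * N)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .intervals import ChromSizes, GeneModel, GenomicInterval, ReadTag

__all__ = [
    "CoverageTrack",
    "RegionDensity",
    "TagIndex",
    "extend_reads",
    "pair_to_fragment",
    "bin_counts",
    "rpkm_normalize",
    "region_density",
    "metagene_profile",
    "strand_split",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass
class CoverageTrack:
    """Fixed-bin-width per-chromosome density (raw counts or RPKM)."""

    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"  # "raw" | "RPKM"
    total_tags: int = 0

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])


@dataclass(frozen=True)
class RegionDensity:
    region: GenomicInterval
    value: float      # RPKM
    tag_count: int    # raw overlapping-tag count


class TagIndex:
    """Sorted per-chromosome tag coordinates for O(log n) overlap counting.

    A tag overlaps [start, end) iff tag.start < end and tag.end > start; with
    starts and ends sorted independently the overlap count is
    ``#(starts < end) - #(ends <= start)``.
    """

    def __init__(self, tags):
        self.n_tags = 0
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list] = {}
        for t in tags:
            by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
            self.n_tags += 1
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            self._starts[chrom] = np.sort(arr[:, 0])
            self._ends[chrom] = np.sort(arr[:, 1])

    def count(self, region: GenomicInterval) -> int:
        starts = self._starts.get(region.chrom)
        if starts is None:
            return 0
        ends = self._ends[region.chrom]
        return int(
            np.searchsorted(starts, region.end, side="left")
            - np.searchsorted(ends, region.start, side="right")
        )

    def count_many(self, regions) -> np.ndarray:
        return np.array([self.count(r) for r in regions], dtype=np.int64)


def extend_reads(tags, sizes: ChromSizes, target_length: int = 150):
    """Extend each tag shorter than ``target_length`` to that length from its
    5' end in the direction of its strand; longer tags are left unchanged.
    Results are clipped to [0, chromosome length)."""
    if target_length <= 0:
        raise ValueError("target_length must be > 0")
    out = []
    for t in tags:
        chrom_len = sizes.length_of(t.chrom)
        if t.width >= target_length:
            out.append(t)
            continue
        if t.strand == "-":
            start, end = max(0, t.end - target_length), t.end
        else:
            start, end = t.start, min(chrom_len, t.start + target_length)
        out.append(replace(t, start=start, end=end))
    return out


def pair_to_fragment(mate1: GenomicInterval, mate2: GenomicInterval) -> ReadTag:
    """Combine a properly paired mate pair into one fragment interval."""
    if mate1.chrom != mate2.chrom:
        raise ValueError("mates on different chromosomes")
    left, right = (mate1, mate2) if mate1.start <= mate2.start else (mate2, mate1)
    if left.strand == "-" or right.strand == "+":
        raise ValueError("improperly oriented pair (leftmost mate must be +)")
    return GenomicInterval(
        mate1.chrom,
        min(mate1.start, mate2.start),
        max(mate1.end, mate2.end),
        name=mate1.name,
        strand=mate1.strand,
    )


def bin_counts(tags, sizes: ChromSizes, bin_size: int = 50) -> CoverageTrack:
    """Raw overlap counts per fixed-width bin; a tag increments every bin it
    overlaps by one.  The last bin of a chromosome may be short."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    values = {
        chrom: np.zeros(-(-length // bin_size), dtype=np.int64)
        for chrom, length in sizes.items()
    }
    n = 0
    for t in tags:
        if t.chrom not in values:
            raise KeyError(f"tag on unknown chromosome {t.chrom!r}")
        if t.end > sizes[t.chrom]:
            raise ValueError(
                f"tag {t.chrom}:{t.start}-{t.end} beyond chromosome end {sizes[t.chrom]}"
            )
        first, last = t.start // bin_size, (t.end - 1) // bin_size
        values[t.chrom][first : last + 1] += 1
        n += 1
    return CoverageTrack(bin_size=bin_size, values=values, normalization="raw", total_tags=n)


def rpkm_normalize(track: CoverageTrack, total_tags: int) -> CoverageTrack:
    """raw -> raw * 1e9 / (bin_size * total_tags), bin-wise."""
    if total_tags <= 0:
        raise ValueError("total_tags must be > 0")
    if track.normalization != "raw":
        raise ValueError("track already normalized")
    scale = 1e9 / (track.bin_size * total_tags)
    return CoverageTrack(
        bin_size=track.bin_size,
        values={c: v.astype(float) * scale for c, v in track.values.items()},
        normalization="RPKM",
        total_tags=total_tags,
    )


def region_density(tags, region: GenomicInterval, total_tags: int) -> RegionDensity:
    """RPKM density of a region from the count of >=1 bp-overlapping tags."""
    if region.width <= 0:
        raise ValueError("empty region")
    if total_tags <= 0:
        raise ValueError("total_tags must be > 0")
    index = tags if isinstance(tags, TagIndex) else TagIndex(tags)
    count = index.count(region)
    value = count * 1e9 / (region.width * total_tags)
    return RegionDensity(region=region, value=value, tag_count=count)


def strand_split(tags):
    """Partition tags by strand; '.' strands are rejected."""
    plus, minus = [], []
    for t in tags:
        if t.strand == "+":
            plus.append(t)
        elif t.strand == "-":
            minus.append(t)
        else:
            raise ValueError(f"unstranded tag {t.chrom}:{t.start}-{t.end}")
    return plus, minus


# ---------------------------------------------------------------------------
# Metagene profiles


class _BaseCumsum:
    """Per-base cumulative sums of a track, for exact interval means."""

    def __init__(self, track: CoverageTrack, sizes: ChromSizes):
        self._cums: dict[str, np.ndarray] = {}
        self.sizes = sizes
        for chrom, vals in track.values.items():
            per_base = np.repeat(np.asarray(vals, dtype=float), track.bin_size)
            per_base = per_base[: sizes[chrom]]
            self._cums[chrom] = np.concatenate([[0.0], np.cumsum(per_base)])

    def mean(self, chrom: str, start: int, end: int) -> float:
        cum = self._cums[chrom]
        return (cum[end] - cum[start]) / (end - start)


def metagene_profile(
    track: CoverageTrack,
    genes,
    sizes: ChromSizes,
    mode: str = "scale-regions",
    flank: int = 3000,
    body_bins: int = 100,
    bin_size: int = 50,
):
    """Per-gene profile matrix; column 0 is always 5'-most.

    scale-regions: ``flank/bin_size`` upstream bins, gene body resampled to
    ``body_bins`` by mean pooling, ``flank/bin_size`` downstream bins.
    reference-point: ``2*flank/bin_size`` bins centred on the TSS.
    Minus-strand rows are computed in plus orientation and reversed.  Genes
    with unusable geometry (body shorter than ``body_bins`` in scale-regions
    mode, or a window extending past a chromosome end) are skipped with a
    warning.  Returns (matrix, kept gene names).
    """
    if mode not in ("scale-regions", "reference-point"):
        raise ValueError(f"unknown mode {mode!r}")
    if not genes:
        raise ValueError("genes must be non-empty")
    flank_bins = flank // bin_size
    cums = _BaseCumsum(track, sizes)
    rows, names = [], []
    for gene in genes:
        iv = gene.interval if isinstance(gene, GeneModel) else gene
        name = gene.name if isinstance(gene, GeneModel) else iv.name
        chrom_len = sizes.length_of(iv.chrom)
        if mode == "scale-regions":
            if iv.width < body_bins:
                warnings.warn(f"gene {name}: body shorter than body_bins, skipped")
                continue
            lo, hi = iv.start - flank, iv.end + flank
            if lo < 0 or hi > chrom_len:
                warnings.warn(f"gene {name}: flank outside chromosome, skipped")
                continue
            row = np.empty(2 * flank_bins + body_bins)
            for j in range(flank_bins):
                row[j] = cums.mean(iv.chrom, lo + j * bin_size, lo + (j + 1) * bin_size)
            edges = iv.start + np.round(
                np.arange(body_bins + 1) * iv.width / body_bins
            ).astype(int)
            for j in range(body_bins):
                row[flank_bins + j] = cums.mean(iv.chrom, edges[j], edges[j + 1])
            for j in range(flank_bins):
                row[flank_bins + body_bins + j] = cums.mean(
                    iv.chrom, iv.end + j * bin_size, iv.end + (j + 1) * bin_size
                )
        else:
            anchor = iv.start if iv.strand != "-" else iv.end
            lo, hi = anchor - flank, anchor + flank
            if lo < 0 or hi > chrom_len:
                warnings.warn(f"gene {name}: window outside chromosome, skipped")
                continue
            row = np.array([
                cums.mean(iv.chrom, lo + j * bin_size, lo + (j + 1) * bin_size)
                for j in range(2 * flank_bins)
            ])
        if iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        names.append(name)
    if not rows:
        raise ValueError("no gene with usable geometry")
    return np.vstack(rows), names


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(track: CoverageTrack, path, suppress_zero: bool = False) -> None:
    """4-column UCSC bedGraph with runs of equal value collapsed."""
    sizes_hint = {c: len(v) * track.bin_size for c, v in track.values.items()}
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            if len(vals) == 0:
                continue
            run_start = 0
            run_val = vals[0]
            for i in range(1, len(vals) + 1):
                if i == len(vals) or vals[i] != run_val:
                    if not (suppress_zero and run_val == 0):
                        lo = run_start * track.bin_size
                        hi = min(i * track.bin_size, sizes_hint[chrom])
                        val = int(run_val) if float(run_val).is_integer() else repr(float(run_val))
                        fh.write(f"{chrom}\t{lo}\t{hi}\t{val}\n")
                    if i < len(vals):
                        run_start, run_val = i, vals[i]


def read_bedgraph(path, sizes: ChromSizes, bin_size: int = 50,
                  normalization: str = "RPKM") -> CoverageTrack:
    """Reconstruct a fixed-bin track from a bedGraph whose runs are
    bin-aligned (the dialect :func:`write_bedgraph` emits)."""
    values = {
        chrom: np.zeros(-(-length // bin_size), dtype=float)
        for chrom, length in sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "browser", "#")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, lo, hi, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in values:
                raise KeyError(f"line {lineno}: unknown chromosome {chrom!r}")
            first, last = lo // bin_size, (hi - 1) // bin_size
            values[chrom][first : last + 1] = val
    return CoverageTrack(bin_size=bin_size, values=values, normalization=normalization)
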