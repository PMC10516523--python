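"""Per-gene transcription-cycle metrics from ssDNA density.

For a gene with strand-aware TSS/TES the three scoring regions are:

* promoter-proximal — TSS +/- 500 bp,
* gene body — 500 bp downstream of the TSS to the TES,
* termination region — TES to 3 kb downstream of the TES.

With ssDNA(X) the RPKM read density in region X:

* pausing index      PI = ssDNA(promoter) / ssDNA(body)
* elongation index   EI = mean(ssDNA(promoter), ssDNA(body))
* termination index  TI = ssDNA(termination) / ssDNA(body)

The two ratio indices are null when the body density is zero; EI is always
defined.  Genes narrower than ``min_gene_width`` (default 1 kb) are excluded
(the +/-500 bp promoter would swallow the body) and reported with a reason
code instead of silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .coverage import TagIndex, region_density
from .intervals import ChromSizes, GeneModel, GenomicInterval

__all__ = ["GeneRegions", "TranscriptionIndices", "gene_regions",
           "compute_indices", "tertile_groups"]


@dataclass(frozen=True)
class GeneRegions:
    gene: GeneModel
    promoter: GenomicInterval | None
    body: GenomicInterval | None
    termination: GenomicInterval | None


@dataclass(frozen=True)
class TranscriptionIndices:
    gene: str
    d_promoter: float | None
    d_body: float | None
    d_termination: float | None
    pi: float | None
    ei: float | None
    ti: float | None
    reason: str = ""


def _clip_interval(chrom: str, lo: int, hi: int, chrom_len: int) -> GenomicInterval | None:
    lo_c, hi_c = max(0, lo), min(chrom_len, hi)
    if hi_c <= lo_c:
        return None
    return GenomicInterval(chrom, lo_c, hi_c)


def gene_regions(gene: GeneModel, sizes: ChromSizes,
                 promoter_flank: int = 500, term_flank: int = 3000) -> GeneRegions:
    """Strand-aware promoter / body / termination regions, clipped to the
    chromosome; a region clipping to zero width is None."""
    chrom_len = sizes.length_of(gene.chrom)
    s, e = gene.interval.start, gene.interval.end
    if gene.strand == "+":
        promoter = _clip_interval(gene.chrom, s - promoter_flank, s + promoter_flank, chrom_len)
        body = _clip_interval(gene.chrom, s + promoter_flank, e, chrom_len)
        term = _clip_interval(gene.chrom, e, e + term_flank, chrom_len)
    else:
        promoter = _clip_interval(gene.chrom, e - promoter_flank, e + promoter_flank, chrom_len)
        body = _clip_interval(gene.chrom, s, e - promoter_flank, chrom_len)
        term = _clip_interval(gene.chrom, s - term_flank, s, chrom_len)
    return GeneRegions(gene=gene, promoter=promoter, body=body, termination=term)


def compute_indices(tags, genes, sizes: ChromSizes, library_size: int,
                    min_gene_width: int = 1000,
                    promoter_flank: int = 500,
                    term_flank: int = 3000) -> list[TranscriptionIndices]:
    """PI/EI/TI per gene; region densities are computed independently."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    index = tags if isinstance(tags, TagIndex) else TagIndex(tags)
    out: list[TranscriptionIndices] = []
    for gene in genes:
        if gene.interval.width < min_gene_width:
            out.append(TranscriptionIndices(gene.name, None, None, None,
                                            None, None, None, reason="short_gene"))
            continue
        regions = gene_regions(gene, sizes, promoter_flank, term_flank)
        if regions.promoter is None or regions.body is None or regions.termination is None:
            out.append(TranscriptionIndices(gene.name, None, None, None,
                                            None, None, None, reason="clipped_region"))
            continue
        d_p = region_density(index, regions.promoter, library_size).value
        d_b = region_density(index, regions.body, library_size).value
        d_t = region_density(index, regions.termination, library_size).value
        pi = d_p / d_b if d_b > 0 else None
        ti = d_t / d_b if d_b > 0 else None
        ei = (d_p + d_b) / 2.0
        reason = "" if d_b > 0 else "zero_body_density"
        out.append(TranscriptionIndices(gene.name, d_p, d_b, d_t, pi, ei, ti, reason))
    return out


def tertile_groups(values: dict[str, float | None]) -> dict[str, set[str]]:
    """Split genes into low/medium/high tertiles of an index.

    Nulls are excluded; ties break by stable gene-name order; group sizes
    differ by at most one.  If every value is identical all genes land in
    'medium' with a warning.
    """
    usable = [(v, name) for name, v in values.items() if v is not None]
    if len(usable) < 3:
        raise ValueError("need >= 3 non-null values")
    vals = [v for v, _ in usable]
    if min(vals) == max(vals):
        warnings.warn("all index values identical; single 'medium' group")
        return {"low": set(), "medium": {n for _, n in usable}, "high": set()}
    ranked = [name for _, name in sorted(usable, key=lambda t: (t[0], t[1]))]
    parts = np.array_split(np.array(ranked, dtype=object), 3)
    return {"low": set(parts[0]), "medium": set(parts[1]), "high": set(parts[2])}
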