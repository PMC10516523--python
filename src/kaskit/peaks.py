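"""Integration of externally called sharp (MACS2-style) and broad
(epic2-style) candidate peaks into a unified KAS-seq peak set, plus genomic
feature annotation.

Sharp candidates are re-screened against two fold-change filters: >= 5x over
the Input library and >= 2x over the candidate's own shores (equal-width
flanks).  Broad peaks are derived by subtracting accepted sharp peaks from
the broad candidates.  Zero denominators are guarded by delta = the RPKM a
single fragment would contribute in that region for the relevant library,
which keeps the guard scale-aware rather than an arbitrary epsilon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .coverage import TagIndex, region_density
from .intervals import ChromSizes, GenomicInterval, interval_subtract, make_shores

__all__ = ["Peak", "FeatureDistribution", "filter_sharp", "derive_broad", "annotate_peaks"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    peak_class: str                  # "sharp" | "broad"
    fc_vs_input: float | None = None
    fc_vs_shores: float | None = None
    source: str = "derived"          # "macs-like" | "epic-like" | "derived"


@dataclass
class FeatureDistribution:
    counts: dict[str, int]
    percentages: dict[str, float]


def _single_fragment_rpkm(width: int, library_size: int) -> float:
    return 1e9 / (width * library_size)


def filter_sharp(
    candidates,
    case_tags,
    input_tags,
    sizes: ChromSizes,
    case_library: int | None = None,
    input_library: int | None = None,
    fc_input_min: float = 5.0,
    fc_shore_min: float = 2.0,
) -> list[Peak]:
    """Keep MACS2-style candidates with >= ``fc_input_min`` enrichment over
    Input and >= ``fc_shore_min`` over the mean usable-shore case density."""
    case_idx = case_tags if isinstance(case_tags, TagIndex) else TagIndex(case_tags)
    input_idx = input_tags if isinstance(input_tags, TagIndex) else TagIndex(input_tags)
    n_case = case_library if case_library is not None else case_idx.n_tags
    n_input = input_library if input_library is not None else input_idx.n_tags
    if n_case <= 0 or n_input <= 0:
        raise ValueError("case and input libraries must be non-empty")

    kept: list[Peak] = []
    for cand in candidates:
        iv = cand.interval if isinstance(cand, Peak) else cand
        d_case = region_density(case_idx, iv, n_case).value
        d_input = region_density(input_idx, iv, n_input).value
        fc_input = d_case / max(d_input, _single_fragment_rpkm(iv.width, n_input))

        left, right = make_shores(iv, sizes)
        usable = [s.interval for s in (left, right) if s.usable]
        if not usable:
            logger.info("candidate %s:%d-%d dropped: no usable shore",
                        iv.chrom, iv.start, iv.end)
            continue
        shore_densities = [region_density(case_idx, s, n_case).value for s in usable]
        shore_mean = sum(shore_densities) / len(shore_densities)
        shore_width = sum(s.width for s in usable) // len(usable)
        fc_shore = d_case / max(shore_mean, _single_fragment_rpkm(shore_width, n_case))

        if fc_input >= fc_input_min and fc_shore >= fc_shore_min:
            kept.append(Peak(interval=iv, peak_class="sharp",
                             fc_vs_input=fc_input, fc_vs_shores=fc_shore,
                             source="macs-like"))
    return kept


def derive_broad(epic_candidates, sharp, min_broad_width: int = 150) -> list[Peak]:
    """Subtract accepted sharp peaks from broad candidates; fragments shorter
    than ``min_broad_width`` (one read length) are discarded."""
    epic_ivs = [c.interval if isinstance(c, Peak) else c for c in epic_candidates]
    sharp_ivs = [p.interval if isinstance(p, Peak) else p for p in sharp]
    fragments = interval_subtract(epic_ivs, sharp_ivs)
    return [
        Peak(interval=f, peak_class="broad", source="derived")
        for f in fragments
        if f.width >= min_broad_width
    ]


_CATEGORIES = ("promoter", "gene_body", "terminator", "intergenic")


def annotate_peaks(peaks, genes, promoter_flank: int = 2000,
                   term_flank: int = 3000) -> FeatureDistribution:
    """Assign each peak by its midpoint with priority
    promoter (TSS +/- promoter_flank) > terminator (TES to TES+term_flank,
    strand-aware) > gene body (remaining transcribed span) > intergenic."""
    if not genes:
        raise ValueError("gene set must be non-empty")
    counts = {c: 0 for c in _CATEGORIES}
    for p in peaks:
        iv = p.interval if isinstance(p, Peak) else p
        mid = iv.midpoint
        category = "intergenic"
        in_term = in_body = False
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            if g.tss - promoter_flank <= mid < g.tss + promoter_flank:
                category = "promoter"
                break
            if g.strand == "+":
                term_lo, term_hi = g.tes, g.tes + term_flank
            else:
                term_lo, term_hi = g.tes - term_flank, g.tes
            if term_lo <= mid < term_hi:
                in_term = True
            if g.interval.start <= mid < g.interval.end:
                in_body = True
        if category != "promoter":
            category = "terminator" if in_term else ("gene_body" if in_body else "intergenic")
        counts[category] += 1
    total = sum(counts.values())
    percentages = {c: (100.0 * n / total if total else 0.0) for c, n in counts.items()}
    return FeatureDistribution(counts=counts, percentages=percentages)
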