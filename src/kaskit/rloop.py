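"""Strand-imbalance R-loop detection from spKAS-seq tags.

An R-loop exposes one DNA strand, so strand-specific ssDNA reads pile up
asymmetrically.  Candidate peaks are tiled into 500 bp windows, plus/minus
read counts are collected per replicate, and each window is tested for
strand imbalance: a negative-binomial Wald test (median-of-ratios size
factors, method-of-moments dispersion with mean-trend shrinkage) with >= 2
replicates per strand, or an exact binomial test on pooled counts with a
single replicate.  Windows significant at BH-adjusted p <= 0.05 are merged
per dominant strand into R-loop regions.  The companion density track is the
per-50 bp-bin absolute difference of plus and minus RPKM, and regions losing
>= 1.5-fold of that density after RNase H treatment are labelled sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageTrack, TagIndex
from .intervals import GenomicInterval, interval_merge
from .nbstats import mom_dispersion, shrink_dispersion, size_factors

__all__ = [
    "StrandedWindow",
    "ImbalanceResult",
    "RLoopRegion",
    "tile_windows",
    "count_strands",
    "size_factors",
    "binomial_imbalance_test",
    "nb_imbalance_test",
    "bh_adjust",
    "call_rloops",
    "rloop_density_track",
    "rnaseh_filter",
]

LOG2 = np.log(2.0)


@dataclass(frozen=True)
class StrandedWindow:
    window: GenomicInterval
    plus_counts: tuple[int, ...]
    minus_counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.plus_counts) != len(self.minus_counts):
            raise ValueError("replicate count mismatch between strands")


@dataclass(frozen=True)
class ImbalanceResult:
    window: GenomicInterval
    log2fc: float
    p_value: float
    padj: float
    dominant_strand: str     # '+', '-', or '.' for exactly balanced
    significant: bool
    tested: bool = True


@dataclass(frozen=True)
class RLoopRegion:
    interval: GenomicInterval
    dominant_strand: str
    n_windows: int
    mean_density: float


def tile_windows(peaks, size: int = 500, step: int = 500) -> list[GenomicInterval]:
    """Tile each peak with windows of ``size`` at ``step``; a trailing
    truncated window survives iff it retains >= size/2; windows are
    deduplicated across overlapping peaks and sorted."""
    if size <= 0 or not (0 < step <= size):
        raise ValueError("require size > 0 and 0 < step <= size")
    seen: set[tuple[str, int, int]] = set()
    out: list[GenomicInterval] = []
    for p in peaks:
        iv = p if isinstance(p, GenomicInterval) else p.interval
        pos = iv.start
        while pos < iv.end:
            end = min(pos + size, iv.end)
            if end - pos >= size or (end - pos) * 2 >= size:
                key = (iv.chrom, pos, end)
                if key not in seen:
                    seen.add(key)
                    out.append(GenomicInterval(iv.chrom, pos, end))
            pos += step
    out.sort(key=lambda w: (w.chrom, w.start, w.end))
    return out


def count_strands(windows, plus_tags_by_rep, minus_tags_by_rep) -> list[StrandedWindow]:
    """Per-window per-strand per-replicate overlap counts."""
    if len(plus_tags_by_rep) != len(minus_tags_by_rep):
        raise ValueError("replicate count mismatch between strands")
    if not plus_tags_by_rep:
        raise ValueError("need >= 1 replicate")
    plus_idx = [t if isinstance(t, TagIndex) else TagIndex(t) for t in plus_tags_by_rep]
    minus_idx = [t if isinstance(t, TagIndex) else TagIndex(t) for t in minus_tags_by_rep]
    out = []
    for w in windows:
        out.append(StrandedWindow(
            window=w,
            plus_counts=tuple(int(ix.count(w)) for ix in plus_idx),
            minus_counts=tuple(int(ix.count(w)) for ix in minus_idx),
        ))
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_imbalance_test(w: StrandedWindow,
                            expected_plus_fraction: float = 0.5) -> tuple[float, float]:
    """Two-sided exact binomial test of the pooled plus count vs total.

    Returns (p, log2fc); log2fc is computed on depth-adjusted strand means
    with a half-integer pseudo-count.  A window with zero total reads is the
    untested sentinel (p = 1, log2fc = 0).
    """
    plus = sum(w.plus_counts)
    minus = sum(w.minus_counts)
    total = plus + minus
    adj_plus = plus * 0.5 / expected_plus_fraction
    adj_minus = minus * 0.5 / (1.0 - expected_plus_fraction)
    log2fc = float(np.log2((adj_plus + 0.5) / (adj_minus + 0.5)))
    if total == 0:
        return 1.0, 0.0
    p = stats.binomtest(plus, total, expected_plus_fraction).pvalue
    return float(min(p, 1.0)), log2fc


def nb_imbalance_test(windows, sf=None, alpha: float = 0.05) -> list[ImbalanceResult]:
    """Per-window NB Wald test of plus vs minus strand counts.

    With a single replicate per strand, delegates to the exact binomial test
    (dispersion is unidentifiable).  Otherwise: counts are normalized by
    median-of-ratios size factors; per-window dispersion is pooled
    method-of-moments across the two strand conditions, shrunk in log space
    toward an alpha(mu) = a1/mu + a0 trend; the Wald statistic is
    log2fc / SE(log2fc) with a delta-method SE under variance mu + alpha*mu^2;
    p-values are two-sided normal and BH-adjusted across all tested windows.
    """
    if not windows:
        return []
    n_rep = len(windows[0].plus_counts)
    plus = np.array([w.plus_counts for w in windows], dtype=float)
    minus = np.array([w.minus_counts for w in windows], dtype=float)
    counts = np.hstack([plus, minus])
    if sf is None:
        sf = size_factors(counts)
    sf = np.asarray(sf, dtype=float)
    sf_p, sf_m = sf[:n_rep], sf[n_rep:]

    if n_rep == 1:
        lib_p = plus[:, 0].sum() / sf_p[0]
        lib_m = minus[:, 0].sum() / sf_m[0]
        expected = lib_p / (lib_p + lib_m) if (lib_p + lib_m) > 0 else 0.5
        raw, fcs, tested = [], [], []
        for w in windows:
            p, fc = binomial_imbalance_test(w, expected)
            raw.append(p)
            fcs.append(fc)
            tested.append(sum(w.plus_counts) + sum(w.minus_counts) > 0)
        padj = bh_adjust(raw)
        return [
            ImbalanceResult(w.window, fc, p, float(q),
                            "+" if fc > 0 else ("-" if fc < 0 else "."),
                            bool(q <= alpha and t), tested=t)
            for w, fc, p, q, t in zip(windows, fcs, raw, padj, tested)
        ]

    norm_p = plus / sf_p
    norm_m = minus / sf_m
    mp = norm_p.mean(axis=1)
    mm = norm_m.mean(axis=1)
    log2fc = np.log2((mp + 0.5) / (mm + 0.5))

    mom = np.empty(len(windows))
    mu_pooled = np.empty(len(windows))
    for i in range(len(windows)):
        mom[i], mu_pooled[i] = mom_dispersion([norm_p[i], norm_m[i]])
    disp = shrink_dispersion(mom, mu_pooled)

    # delta-method variance of log2(mean): Var(mhat)/(mean^2 ln2^2), with
    # Var(mhat) = (1/n^2) sum_i (mu/sf_i + alpha mu^2) for normalized counts
    def var_log2(mean, sf_cond):
        mu_eff = np.maximum(mean, 0.5)
        var_hat = (mu_eff[:, None] / sf_cond[None, :]
                   + disp[:, None] * mu_eff[:, None] ** 2).sum(axis=1) / len(sf_cond) ** 2
        return var_hat / (mu_eff**2 * LOG2**2)

    se = np.sqrt(var_log2(mp, sf_p) + var_log2(mm, sf_m))
    z = log2fc / se
    raw = 2.0 * stats.norm.sf(np.abs(z))
    tested = (plus.sum(axis=1) + minus.sum(axis=1)) > 0
    raw = np.where(tested, raw, 1.0)
    padj = bh_adjust(raw)
    return [
        ImbalanceResult(w.window, float(fc), float(p), float(q),
                        "+" if fc > 0 else ("-" if fc < 0 else "."),
                        bool(q <= alpha and t), tested=bool(t))
        for w, fc, p, q, t in zip(windows, log2fc, raw, padj, tested)
    ]


def call_rloops(results, alpha: float = 0.05, merge_gap: int = 0,
                window_densities=None) -> list[RLoopRegion]:
    """Merge significant windows into R-loop regions per dominant strand.

    ``window_densities`` optionally maps (chrom, start, end) -> a density
    value used for the region mean; otherwise |log2fc| is averaged.
    """
    regions: list[RLoopRegion] = []
    for strand in ("+", "-"):
        sig = [r for r in results if r.significant and r.dominant_strand == strand
               and r.padj <= alpha]
        if not sig:
            continue
        merged = interval_merge([r.window for r in sig], max_gap=merge_gap)
        for m in merged:
            members = [r for r in sig if r.window.chrom == m.chrom
                       and r.window.start >= m.start and r.window.end <= m.end]
            if window_densities is not None:
                dens = [window_densities[(r.window.chrom, r.window.start, r.window.end)]
                        for r in members]
            else:
                dens = [abs(r.log2fc) for r in members]
            regions.append(RLoopRegion(
                interval=m, dominant_strand=strand,
                n_windows=len(members),
                mean_density=float(np.mean(dens)) if dens else 0.0,
            ))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def rloop_density_track(plus_track: CoverageTrack, minus_track: CoverageTrack) -> CoverageTrack:
    """Per-bin |plus RPKM - minus RPKM| (the R-loop density track)."""
    if plus_track.bin_size != minus_track.bin_size:
        raise ValueError("mismatched bin size")
    if plus_track.normalization != minus_track.normalization:
        raise ValueError("mismatched normalization")
    chroms = set(plus_track.values) | set(minus_track.values)
    values = {}
    for chrom in chroms:
        a = plus_track.values.get(chrom)
        b = minus_track.values.get(chrom)
        if a is None:
            a = np.zeros_like(b)
        if b is None:
            b = np.zeros_like(a)
        values[chrom] = np.abs(np.asarray(a, float) - np.asarray(b, float))
    return CoverageTrack(bin_size=plus_track.bin_size, values=values,
                         normalization=plus_track.normalization)


def _region_track_mean(track: CoverageTrack, iv: GenomicInterval) -> float:
    vals = track.values[iv.chrom]
    bs = track.bin_size
    total = 0.0
    for b in range(iv.start // bs, (iv.end - 1) // bs + 1):
        lo = max(iv.start, b * bs)
        hi = min(iv.end, (b + 1) * bs)
        total += vals[b] * (hi - lo)
    return total / iv.width


def rnaseh_filter(wt_rloops, wt_density: CoverageTrack,
                  treated_density: CoverageTrack, fc_min: float = 1.5,
                  guard: float | None = None):
    """Split R-loop regions into (RNase H-sensitive, insensitive).

    Sensitive iff mean R-loop density over the region satisfies
    WT / treated >= fc_min, i.e. the signal drops at least fc_min-fold after
    RNase H.  ``guard`` (if given) floors the treated denominator; with no
    guard, a region with zero treated density is sensitive iff WT > 0.
    """
    sensitive, insensitive = [], []
    for r in wt_rloops:
        iv = r.interval if isinstance(r, RLoopRegion) else r
        if iv.chrom not in wt_density.values or iv.chrom not in treated_density.values:
            raise KeyError(f"region chromosome {iv.chrom!r} absent from a density track")
        wt = _region_track_mean(wt_density, iv)
        tr = _region_track_mean(treated_density, iv)
        denom = max(tr, guard) if guard is not None else tr
        if denom > 0:
            is_sensitive = wt / denom >= fc_min
        else:
            is_sensitive = wt > 0
        (sensitive if is_sensitive else insensitive).append(r)
    return sensitive, insensitive
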