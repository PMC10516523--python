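"""Library-level quality metrics for KAS-seq samples.

Implements the standard enrichment and complexity diagnostics: fraction of
reads in peaks (FRiP), ENCODE-style library-complexity coefficients
(NRF/PBC1/PBC2), the fingerprint (Lorenz) curve, subsampling saturation, and
replicate correlation, plus a pass/warn verdict.  The recommended thresholds
(>= 50 000 sharp+broad peaks and FRiP > 40%) derive from live human/mouse
cell lines and are overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageTrack, TagIndex
from .intervals import interval_merge

__all__ = [
    "QCReport",
    "frip",
    "complexity",
    "fingerprint_curve",
    "saturation_curve",
    "replicate_correlation",
    "qc_verdict",
]


@dataclass
class QCReport:
    frip: float
    n_peaks: int
    nrf: float
    pbc1: float
    pbc2: float               # math.inf encodes "no two-read positions"
    pbc2_infinite: bool
    fingerprint: list = field(default_factory=list)
    saturation: list = field(default_factory=list)
    verdict: str = "warn"


def _tags_in_peaks(tags, peaks) -> int:
    merged = interval_merge(peaks, max_gap=0)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in merged}:
        chrom_peaks = [p for p in merged if p.chrom == chrom]
        starts[chrom] = np.array([p.start for p in chrom_peaks])
        ends[chrom] = np.array([p.end for p in chrom_peaks])
    n_in = 0
    for t in tags:
        if t.chrom not in starts:
            continue
        s, e = starts[t.chrom], ends[t.chrom]
        # merged peaks are sorted & disjoint: candidate is the rightmost peak
        # starting before the tag end
        idx = int(np.searchsorted(s, t.end, side="left"))
        if idx > 0 and e[idx - 1] > t.start:
            n_in += 1
    return n_in


def frip(tags, peaks) -> float:
    """Fraction of (deduplicated) tags overlapping any peak by >= 1 bp."""
    tags = list(tags)
    if not tags:
        raise ValueError("zero tags")
    if not peaks:
        return 0.0
    return _tags_in_peaks(tags, peaks) / len(tags)


def complexity(raw_tags) -> tuple[float, float, float]:
    """(NRF, PBC1, PBC2) from raw (pre-dedup) tags grouped by their
    (chrom, 5' position, strand).  PBC2 is ``math.inf`` when no position is
    seen exactly twice."""
    raw_tags = list(raw_tags)
    if not raw_tags:
        raise ValueError("empty input")
    counts: dict[tuple, int] = {}
    for t in raw_tags:
        five_prime = t.start if t.strand != "-" else t.end
        key = (t.chrom, five_prime, t.strand)
        counts[key] = counts.get(key, 0) + 1
    distinct = len(counts)
    once = sum(1 for c in counts.values() if c == 1)
    twice = sum(1 for c in counts.values() if c == 2)
    nrf = distinct / len(raw_tags)
    pbc1 = once / distinct
    pbc2 = once / twice if twice > 0 else math.inf
    return nrf, pbc1, pbc2


def fingerprint_curve(track: CoverageTrack, sample_bins: int | None = None,
                      rng=None) -> list[tuple[float, float]]:
    """Lorenz curve of bin counts: sort ascending, plot cumulative fraction of
    signal against fraction of bins; N+1 points from (0,0) to (1,1)."""
    counts = np.concatenate([np.asarray(v) for v in track.values.values()])
    if counts.size < 2:
        raise ValueError("need >= 2 bins")
    if counts.sum() == 0:
        raise ValueError("all-zero track")
    if sample_bins is not None and sample_bins < counts.size:
        rng = np.random.default_rng(rng)
        counts = rng.choice(counts, size=sample_bins, replace=False)
    counts = np.sort(counts)
    n = counts.size
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(counts) / counts.sum()])
    return list(zip(x.tolist(), y.tolist()))


def saturation_curve(tags, peaks, fractions=None, seed: int = 0) -> list[tuple[float, float]]:
    """FRiP recomputed on seeded without-replacement subsamples, against the
    fixed full-data peak set."""
    tags = list(tags)
    if fractions is None:
        fractions = [round(0.1 * k, 1) for k in range(1, 11)]
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} out of (0, 1]")
    rng = np.random.default_rng(seed)
    points = []
    for f in sorted(fractions):
        k = max(1, round(f * len(tags)))
        if f == 1.0:
            sub = tags
        else:
            idx = rng.choice(len(tags), size=k, replace=False)
            sub = [tags[i] for i in idx]
        points.append((f, frip(sub, peaks)))
    return points


def replicate_correlation(densities_a, densities_b) -> float:
    """Pearson r of log2(RPKM + 1)-transformed matched density vectors."""
    a = np.log2(np.asarray(densities_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(densities_b, dtype=float) + 1.0)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a replicate vector")
    return float(np.corrcoef(a, b)[0, 1])


def qc_verdict(n_peaks: int, frip_value: float,
               min_peaks: int = 50_000, min_frip: float = 0.40) -> str:
    """'pass' iff n_peaks >= min_peaks AND frip > min_frip (strict), else
    'warn' — never a hard failure."""
    return "pass" if (n_peaks >= min_peaks and frip_value > min_frip) else "warn"
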