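"""Seeded synthetic-data generators for the full analysis pipeline.

The generators emulate the statistical structure the analysis modules
assume — region-specific Poisson tag placement at configurable per-kb rates
(promoter / body / termination / background), focal ("paused") versus
uniform ("elongation pass-through") enhancer enrichment, negative-binomial
strand-imbalanced window counts with replicates and an RNase-H-treated
condition, and impulse-shaped time-course counts — together with truth
tables sufficient to score every downstream module.  They do not emulate
sequence content, mappability, GC structure, or chromatin-driven rate
heterogeneity of real genomes.

All randomness flows from one seed through named substreams, so adding a
generator does not shift existing streams, and identical specs yield
byte-identical outputs.  Tags are placed by 5' position and then extended to
150 bp through :func:`kaskit.coverage.extend_reads`, so synthetic data
exercises the real pipeline path.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .coverage import extend_reads
from .intervals import ChromSizes, GeneModel, GenomicInterval
from .timecourse import ImpulseParams, TimecourseMatrix, impulse_value, sigmoid_value

__all__ = [
    "SimSpec",
    "simulate_annotation",
    "simulate_kas_tags",
    "simulate_spkas_counts",
    "simulate_spkas_tags",
    "simulate_timecourse_counts",
]

READ_LENGTH = 36     # pre-extension read length
EXT_LENGTH = 150


@dataclass
class SimSpec:
    """Study conditions for the synthetic datasets.

    Rates are expected tags per kb (relative weights; absolute counts are
    scaled to ``depth``).  The defaults encode the conditions exercised
    throughout the test-suite: promoter:body:termination rates 10:2:4 over a
    low background, paused enhancers at 4:1 over their shores versus
    pass-through enhancers at 4:4, strand-imbalanced windows of NB(mu=50,
    alpha=0.05) counts with 2 replicates and |log2FC| = 2, 4x RNase-H
    deflation, and a 6-timepoint x 2-replicate time course.
    """

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 1_500_000, "chr2": 1_200_000,
    })
    # gene geometry
    n_genes: int = 40
    gene_width: tuple = (6000, 15000)
    gene_gap: int = 12_000
    # KAS per-kb rates
    rate_promoter: float = 10.0
    rate_body: float = 2.0
    rate_termination: float = 4.0
    rate_background: float = 0.1
    depth: int = 100_000
    # enhancers (placed on chr2, distal from every gene)
    n_enhancers: int = 100
    enhancer_width: tuple = (1000, 1500)
    paused_fraction: float = 0.5
    rate_enhancer: float = 4.0
    rate_shore: float = 1.0
    # spKAS strand-imbalance windows
    n_null_windows: int = 5000
    n_planted_regions: int = 500
    windows_per_region: int = 1
    window_size: int = 500
    nb_mu: float = 50.0
    nb_alpha: float = 0.05
    log2_imbalance: float = 2.0
    n_replicates: int = 2
    rep_depth_factors: tuple = (1.0, 1.2)
    treated_deflation: float = 4.0
    # time course
    n_per_class: int = 200
    tc_class_weights: tuple = (1.0, 1.0, 1.0)   # constant, monotone, pulse
    timepoints: tuple = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    tc_replicates: int = 2
    tc_alpha: float = 0.05
    tc_base_mu: tuple = (30.0, 300.0)
    tc_fold: tuple = (4.0, 8.0)


def _rng(spec: SimSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# Annotation


def simulate_annotation(spec: SimSpec):
    """(ChromSizes, gene models, enhancer intervals with class in the name).

    Genes are packed non-overlapping on chr1 with both strands represented;
    enhancers sit on chr2, hence >= 5 kb from every gene span (distal).
    """
    sizes = ChromSizes(dict(spec.chrom_lengths))
    rng = _rng(spec, "annotation")

    genes = []
    cursor = 20_000
    for i in range(spec.n_genes):
        width = int(rng.integers(spec.gene_width[0], spec.gene_width[1] + 1))
        if cursor + width + spec.gene_gap > sizes["chr1"]:
            raise ValueError("gene packing infeasible within chr1")
        strand = "+" if i % 2 == 0 else "-"   # both strands always present
        iv = GenomicInterval("chr1", cursor, cursor + width, name=f"gene_{i}",
                             strand=strand)
        genes.append(GeneModel(interval=iv, name=f"gene_{i}"))
        cursor += width + spec.gene_gap

    enhancers = []
    cursor = 20_000
    n_paused = int(round(spec.n_enhancers * spec.paused_fraction))
    for i in range(spec.n_enhancers):
        width = int(rng.integers(spec.enhancer_width[0], spec.enhancer_width[1] + 1))
        slot = 3 * width + 4000   # element + two shores + spacing
        if cursor + slot > sizes["chr2"]:
            raise ValueError("enhancer packing infeasible within chr2")
        cls = "paused" if i < n_paused else "pass_through"
        enhancers.append(GenomicInterval("chr2", cursor + width,
                                         cursor + 2 * width,
                                         name=f"enh_{i}|{cls}"))
        cursor += slot
    return sizes, genes, enhancers


# ---------------------------------------------------------------------------
# KAS tags


def _place_tags(rng, chrom, lo, hi, n, sizes, out):
    """n tags with uniform 5' positions in [lo, hi), random strand."""
    if n <= 0 or hi <= lo:
        return
    pos = rng.integers(lo, hi, size=n)
    strands = rng.random(n) < 0.5
    chrom_len = sizes[chrom]
    for p, is_plus in zip(pos.tolist(), strands.tolist()):
        if is_plus:
            s, e = p, min(p + READ_LENGTH, chrom_len)
        else:
            s, e = max(0, p - READ_LENGTH), p
        if e <= s:
            continue
        out.append(GenomicInterval(chrom, s, e, strand="+" if is_plus else "-"))


def simulate_kas_tags(spec: SimSpec, annotation=None):
    """Poisson tag placement at the spec's per-kb region rates.

    Returns (tags, truth) where truth maps gene names to their true region
    rates and enhancer names to their class, plus the overall scale used.
    """
    if spec.depth <= 0:
        raise ValueError("zero depth")
    if annotation is None:
        annotation = simulate_annotation(spec)
    sizes, genes, enhancers = annotation
    rng = _rng(spec, "kas_tags")

    from .indices import gene_regions  # local import avoids a cycle

    regions = []  # (chrom, lo, hi, rate_per_kb)
    for gene in genes:
        gr = gene_regions(gene, sizes)
        for region, rate in ((gr.promoter, spec.rate_promoter),
                             (gr.body, spec.rate_body),
                             (gr.termination, spec.rate_termination)):
            if region is not None:
                regions.append((region.chrom, region.start, region.end, rate))
    from .intervals import make_shores
    for enh in enhancers:
        paused = enh.name.endswith("paused") and not enh.name.endswith("pass_through")
        left, right = make_shores(enh, sizes)
        e_rate = spec.rate_enhancer
        s_rate = spec.rate_shore if paused else spec.rate_enhancer
        regions.append((enh.chrom, enh.start, enh.end, e_rate))
        for shore in (left, right):
            if shore.interval is not None:
                regions.append((shore.interval.chrom, shore.interval.start,
                                shore.interval.end, s_rate))
    for chrom, length in sizes.items():
        regions.append((chrom, 0, length, spec.rate_background))

    weights = np.array([(hi - lo) / 1000.0 * rate for _, lo, hi, rate in regions])
    scale = spec.depth / weights.sum()
    tags: list[GenomicInterval] = []
    for (chrom, lo, hi, rate), w in zip(regions, weights):
        n = int(rng.poisson(w * scale))
        _place_tags(rng, chrom, lo, hi, n, sizes, tags)
    tags = extend_reads(tags, sizes, EXT_LENGTH)

    truth = {
        "genes": {g.name: {"promoter": spec.rate_promoter, "body": spec.rate_body,
                           "termination": spec.rate_termination} for g in genes},
        "enhancers": {e.name.split("|")[0]: e.name.split("|")[1] for e in enhancers},
        "scale": float(scale),
    }
    return tags, truth


# ---------------------------------------------------------------------------
# spKAS strand imbalance


def _nb_draw(rng, mu, alpha, size=None):
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


def _window_layout(spec: SimSpec):
    """Deterministic layout: contiguous windows on chrR; planted regions of
    ``windows_per_region`` consecutive windows, separated by null windows."""
    wsize = spec.window_size
    n_planted_w = spec.n_planted_regions * spec.windows_per_region
    n_total = spec.n_null_windows + n_planted_w
    chrom_len = n_total * wsize + wsize
    windows = [GenomicInterval("chrR", i * wsize, (i + 1) * wsize)
               for i in range(n_total)]
    # spread planted regions evenly with >= 1 null window between regions
    stride = n_total // max(spec.n_planted_regions, 1)
    planted: dict[int, float] = {}
    rng = _rng(spec, "spkas_layout")
    for k in range(spec.n_planted_regions):
        base = k * stride
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for j in range(spec.windows_per_region):
            planted[base + j] = sign * spec.log2_imbalance
    return windows, planted, ChromSizes({"chrR": chrom_len})


def simulate_spkas_counts(spec: SimSpec):
    """NB window counts per strand per replicate, plus the planted truth.

    Returns (stranded windows, planted truth {window index -> signed log2fc},
    chrom sizes).  Null windows are strand-balanced at NB(mu, alpha); planted
    windows split the imbalance symmetrically (plus mean mu*2^(lfc/2), minus
    mean mu*2^(-lfc/2)); replicate depth factors scale both strands alike.
    """
    from .rloop import StrandedWindow

    windows, planted, sizes = _window_layout(spec)
    rng = _rng(spec, "spkas_counts")
    reps = np.asarray(spec.rep_depth_factors[: spec.n_replicates], dtype=float)
    if reps.size != spec.n_replicates:
        reps = np.ones(spec.n_replicates)
    out = []
    for i, w in enumerate(windows):
        lfc = planted.get(i, 0.0)
        mu_p = spec.nb_mu * 2.0 ** (lfc / 2.0)
        mu_m = spec.nb_mu * 2.0 ** (-lfc / 2.0)
        plus = tuple(int(_nb_draw(rng, mu_p * f, spec.nb_alpha)) for f in reps)
        minus = tuple(int(_nb_draw(rng, mu_m * f, spec.nb_alpha)) for f in reps)
        out.append(StrandedWindow(window=w, plus_counts=plus, minus_counts=minus))
    return out, planted, sizes


def simulate_spkas_tags(spec: SimSpec, treated: bool = False):
    """Per-replicate plus/minus tag lists realizing the spKAS window counts.

    Tags are placed fully inside their window so window counts are exact.
    ``treated=True`` emulates RNase H: the planted strand imbalance is
    deflated ``treated_deflation``-fold while total signal is preserved.
    Returns (plus_tags_by_rep, minus_tags_by_rep, peaks, planted truth
    regions, sizes).
    """
    windows, planted, sizes = _window_layout(spec)
    rng = _rng(spec, "spkas_tags_treated" if treated else "spkas_tags")
    reps = np.asarray(spec.rep_depth_factors[: spec.n_replicates], dtype=float)
    if reps.size != spec.n_replicates:
        reps = np.ones(spec.n_replicates)
    plus_by_rep = [[] for _ in reps]
    minus_by_rep = [[] for _ in reps]
    for i, w in enumerate(windows):
        lfc = planted.get(i, 0.0)
        mu_p = spec.nb_mu * 2.0 ** (lfc / 2.0)
        mu_m = spec.nb_mu * 2.0 ** (-lfc / 2.0)
        if treated and lfc != 0.0:
            delta = (mu_p - mu_m) / spec.treated_deflation
            mid = (mu_p + mu_m) / 2.0
            mu_p, mu_m = mid + delta / 2.0, mid - delta / 2.0
        hi = w.end - EXT_LENGTH
        for j, f in enumerate(reps):
            n_p = int(_nb_draw(rng, mu_p * f, spec.nb_alpha))
            n_m = int(_nb_draw(rng, mu_m * f, spec.nb_alpha))
            for pos in rng.integers(w.start, hi, size=n_p).tolist():
                plus_by_rep[j].append(GenomicInterval(w.chrom, pos, pos + EXT_LENGTH,
                                                      strand="+"))
            for pos in rng.integers(w.start, hi, size=n_m).tolist():
                minus_by_rep[j].append(GenomicInterval(w.chrom, pos, pos + EXT_LENGTH,
                                                       strand="-"))
    peaks = [GenomicInterval("chrR", 0, len(windows) * spec.window_size)]
    truth_regions = [
        GenomicInterval("chrR", min(i for i in idxs) * spec.window_size,
                        (max(i for i in idxs) + 1) * spec.window_size,
                        name="+" if sign > 0 else "-")
        for idxs, sign in _group_planted(planted, spec)
    ]
    return plus_by_rep, minus_by_rep, peaks, truth_regions, sizes


def _group_planted(planted: dict[int, float], spec: SimSpec):
    """Group planted window indices into their contiguous regions."""
    regions = []
    idxs = sorted(planted)
    block: list[int] = []
    for i in idxs:
        if block and (i != block[-1] + 1 or planted[i] != planted[block[0]]):
            regions.append((block, planted[block[0]]))
            block = []
        block.append(i)
    if block:
        regions.append((block, planted[block[0]]))
    return regions


# ---------------------------------------------------------------------------
# Time course


def simulate_timecourse_counts(spec: SimSpec):
    """NB counts for constant / monotone-sigmoid / impulse-pulse features.

    Returns (TimecourseMatrix, truth) where truth maps feature names to
    {"class": constant|monotone|pulse, "direction": up|down|none}.
    """
    if len(set(spec.timepoints)) < 3:
        raise ValueError("need >= 3 distinct timepoints")
    rng = _rng(spec, "timecourse")
    t = np.repeat(np.asarray(spec.timepoints, dtype=float), spec.tc_replicates)
    samples = [(float(tp), f"rep{r+1}")
               for tp in spec.timepoints for r in range(spec.tc_replicates)]
    sf_true = rng.uniform(0.9, 1.1, size=len(samples))
    span = max(spec.timepoints) - min(spec.timepoints)

    names, rows, truth = [], [], {}
    total = 3 * spec.n_per_class
    w = np.asarray(spec.tc_class_weights, dtype=float)
    n_by_class = np.round(total * w / w.sum()).astype(int)
    classes = (["constant"] * n_by_class[0] + ["monotone"] * n_by_class[1]
               + ["pulse"] * n_by_class[2])
    for i, cls in enumerate(classes):
        base = float(np.exp(rng.uniform(np.log(spec.tc_base_mu[0]),
                                        np.log(spec.tc_base_mu[1]))))
        direction = "none"
        if cls == "constant":
            mean_t = np.full_like(t, base)
        elif cls == "monotone":
            fold = rng.uniform(*spec.tc_fold)
            up = rng.random() < 0.5
            direction = "up" if up else "down"
            h1 = base * fold if up else base / fold
            beta = rng.uniform(1.0, 3.0)
            t1 = rng.uniform(min(spec.timepoints) + 0.2 * span,
                             min(spec.timepoints) + 0.7 * span)
            mean_t = sigmoid_value(t, beta, base, h1, t1)
        else:
            fold = rng.uniform(*spec.tc_fold)
            up = rng.random() < 0.5
            direction = "up" if up else "down"
            h1 = base * fold if up else base / fold
            beta = rng.uniform(1.0, 3.0)
            t1 = rng.uniform(min(spec.timepoints) + 0.05 * span,
                             min(spec.timepoints) + 0.35 * span)
            t2 = t1 + rng.uniform(0.25 * span, 0.5 * span)
            mean_t = impulse_value(t, ImpulseParams(beta, base, h1, base, t1, t2))
        counts = _nb_draw(rng, np.maximum(mean_t * sf_true, 1e-6), spec.tc_alpha)
        name = f"feat_{i}"
        names.append(name)
        rows.append(counts)
        truth[name] = {"class": cls, "direction": direction}

    counts = np.asarray(rows, dtype=np.int64)
    from .nbstats import size_factors
    matrix = TimecourseMatrix(
        feature_names=names, features=[None] * len(names), samples=samples,
        counts=counts, size_factors=size_factors(counts),
    )
    return matrix, truth
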