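"""Time-course classification of features as steadily or transiently
regulated.

Each feature's counts over time are fitted with three nested negative-
binomial mean models:

* constant: f(t) = c                                   (1 parameter)
* sigmoid:  f(t) = h0 + (h1-h0) * s(beta*(t-t1))       (4 parameters)
* impulse:  f(t) = (1/h1) * [h0 + (h1-h0)*s(beta*(t-t1))]
                          * [h2 + (h1-h2)*s(-beta*(t-t2))]   (6 parameters)

with s the standard logistic.  The impulse is a product of an entry and an
exit sigmoid: it rises (or falls) from plateau h0 to h1 around t1 and
returns toward h2 around t2, so it nests the sigmoid (t2 -> infinity) and
the constant (h0 = h1 = h2).  Two likelihood-ratio tests classify each
feature: impulse vs constant (any regulation, df 5) and impulse vs sigmoid
(transience, df 2), each BH-adjusted across features.  A feature is
transiently regulated when both reject, steadily regulated when only the
first does.  Direction is judged against the fitted level at the first
timepoint.

Dispersion per feature is method-of-moments over replicates pooled across
timepoints, shrunk toward the across-feature mean-dispersion trend, then
held fixed during mean-model optimization.  The impulse likelihood surface
is multi-modal, so fitting uses bounded multi-start L-BFGS-B with transition
times initialized on the observed timepoint grid and evaluations of the
lower models' optima included as starts — which also guarantees the nested
log-likelihood ordering up to optimizer tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .coverage import TagIndex
from .nbstats import mom_dispersion, nb_loglik, shrink_dispersion, size_factors
from .rloop import bh_adjust

__all__ = [
    "TimecourseMatrix",
    "ImpulseParams",
    "ImpulseFit",
    "TrajectoryCall",
    "build_count_matrix",
    "impulse_value",
    "sigmoid_value",
    "fit_trajectory_models",
    "classify_trajectories",
]

_H_FLOOR = 1e-6
_BETA_LO, _BETA_HI = 0.05, 20.0


@dataclass
class TimecourseMatrix:
    feature_names: list[str]
    features: list                      # GenomicInterval per feature
    samples: list[tuple[float, str]]    # (timepoint hours, replicate id)
    counts: np.ndarray                  # features x samples, non-negative int
    size_factors: np.ndarray

    @property
    def timepoints(self) -> np.ndarray:
        return np.array([t for t, _ in self.samples], dtype=float)


@dataclass(frozen=True)
class ImpulseParams:
    beta: float
    h0: float
    h1: float
    h2: float
    t1: float
    t2: float


@dataclass
class ImpulseFit:
    feature: str
    params: ImpulseParams | None
    sigmoid_params: tuple | None        # (beta, h0, h1, t1)
    constant_level: float
    loglik_constant: float
    loglik_sigmoid: float
    loglik_impulse: float
    dispersion: float
    converged: bool = True


@dataclass(frozen=True)
class TrajectoryCall:
    feature: str
    category: str    # steady_up|steady_down|transient_up|transient_down|not_significant
    p_diff: float
    padj_diff: float
    p_trans: float
    padj_trans: float


def _sigma(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def impulse_value(t, params: ImpulseParams):
    """Impulse mean at time t (vectorized)."""
    if params.h1 <= 0:
        raise ValueError("h1 must be > 0")
    t = np.asarray(t, dtype=float)
    s1 = _sigma(params.beta * (t - params.t1))
    s2 = _sigma(-params.beta * (t - params.t2))
    return (1.0 / params.h1) * (params.h0 + (params.h1 - params.h0) * s1) * (
        params.h2 + (params.h1 - params.h2) * s2
    )


def sigmoid_value(t, beta, h0, h1, t1):
    t = np.asarray(t, dtype=float)
    return h0 + (h1 - h0) * _sigma(beta * (t - t1))


def build_count_matrix(tag_sets, features, metadata) -> TimecourseMatrix:
    """Overlap counts per feature per sample, with median-of-ratios size
    factors.

    ``metadata`` is a list of dicts with keys sample (matching the order of
    ``tag_sets``), timepoint, replicate.
    """
    if len(tag_sets) != len(metadata):
        raise ValueError("one metadata row per tag set required")
    samples = []
    for meta in metadata:
        if "timepoint" not in meta or meta["timepoint"] is None:
            raise ValueError(f"sample {meta.get('sample')!r} missing timepoint")
        samples.append((float(meta["timepoint"]), str(meta.get("replicate", "1"))))
    idxs = [t if isinstance(t, TagIndex) else TagIndex(t) for t in tag_sets]
    names = [getattr(f, "name", ".") for f in features]
    counts = np.stack([ix.count_many(features) for ix in idxs], axis=1)
    return TimecourseMatrix(
        feature_names=names, features=list(features), samples=samples,
        counts=counts, size_factors=size_factors(counts),
    )


# ---------------------------------------------------------------------------
# Model fitting


def _fit_constant(y, sf, disp):
    baseline = max(np.mean(y / sf), _H_FLOOR)
    res = optimize.minimize_scalar(
        lambda lc: -nb_loglik(y, np.exp(lc) * sf, disp),
        bounds=(np.log(_H_FLOOR), np.log(baseline * 10 + 10)),
        method="bounded",
    )
    level = float(np.exp(res.x))
    return level, nb_loglik(y, level * sf, disp)


def _fit_sigmoid(y, t, sf, disp, c_level):
    tgrid = np.unique(t)
    m_first = max(np.mean(y[t == tgrid[0]] / sf[t == tgrid[0]]), _H_FLOOR)
    m_last = max(np.mean(y[t == tgrid[-1]] / sf[t == tgrid[-1]]), _H_FLOOR)

    def nll(theta):
        beta, h0, h1 = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2])
        return -nb_loglik(y, sigmoid_value(t, beta, h0, h1, theta[3]) * sf, disp)

    bounds = [(np.log(_BETA_LO), np.log(_BETA_HI)),
              (np.log(_H_FLOOR), np.log(max(m_first, m_last) * 20 + 10)),
              (np.log(_H_FLOOR), np.log(max(m_first, m_last) * 20 + 10)),
              (tgrid[0] - 1.0, tgrid[-1] + 1.0)]
    starts = []
    for t1 in tgrid:
        starts.append([np.log(1.0), np.log(m_first), np.log(m_last), float(t1)])
    # constant-equivalent start (h0 = h1 = c reproduces the constant model)
    starts.append([np.log(1.0), np.log(c_level), np.log(c_level), float(tgrid[len(tgrid) // 2])])
    best_ll, best_theta = -np.inf, None
    for x0 in starts:
        ll0 = -nll(np.asarray(x0))
        if ll0 > best_ll:
            best_ll, best_theta = ll0, np.asarray(x0)
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 80})
        if -res.fun > best_ll:
            best_ll, best_theta = -res.fun, res.x
    params = (float(np.exp(best_theta[0])), float(np.exp(best_theta[1])),
              float(np.exp(best_theta[2])), float(best_theta[3]))
    return params, float(best_ll)


def _fit_impulse(y, t, sf, disp, c_level, sig_params):
    tgrid = np.unique(t)
    span = tgrid[-1] - tgrid[0]
    means = {tp: max(np.mean(y[t == tp] / sf[t == tp]), _H_FLOOR) for tp in tgrid}
    m_first, m_last = means[tgrid[0]], means[tgrid[-1]]
    m_peak_t = max(means, key=means.get)
    m_dip_t = min(means, key=means.get)
    h_hi = np.log(max(means.values()) * 20 + 10)

    def unpack(theta):
        beta = np.exp(theta[0])
        h0, h1, h2 = np.exp(theta[1]), np.exp(theta[2]), np.exp(theta[3])
        t1 = theta[4]
        t2 = t1 + np.exp(theta[5])          # dt > 0 enforces t1 <= t2
        return ImpulseParams(beta, h0, h1, h2, t1, t2)

    def nll(theta):
        return -nb_loglik(y, impulse_value(t, unpack(theta)) * sf, disp)

    bounds = [(np.log(_BETA_LO), np.log(_BETA_HI)),
              (np.log(_H_FLOOR), h_hi), (np.log(_H_FLOOR), h_hi),
              (np.log(_H_FLOOR), h_hi),
              (tgrid[0] - 1.0, tgrid[-1] + 1.0),
              (np.log(1e-3), np.log(2 * span + 2))]

    starts = []
    # pulse-shaped starts around the empirical extremum (sharp and shallow)
    for ext_t, ext_m in ((m_peak_t, means[m_peak_t]), (m_dip_t, means[m_dip_t])):
        for beta0 in (1.0, 3.0):
            t1 = max(tgrid[0], ext_t - span / 4)
            dt = max(0.5, min(2 * (ext_t - t1) + 0.5, span))
            starts.append([np.log(beta0), np.log(m_first), np.log(ext_m),
                           np.log(m_last), float(t1), np.log(dt)])
    # a pulse start anchored at every interior timepoint
    for k in range(1, len(tgrid) - 1):
        t1 = 0.5 * (tgrid[k - 1] + tgrid[k])
        dt = max(0.5, tgrid[k + 1] - t1)
        starts.append([np.log(2.0), np.log(m_first), np.log(means[tgrid[k]]),
                       np.log(m_last), float(t1), np.log(dt)])
    # sigmoid-equivalent start: t2 far beyond the observed range, h2 = h1
    s_beta, s_h0, s_h1, s_t1 = sig_params
    far = max(1e-3, tgrid[-1] + 10.0 / s_beta - s_t1)
    starts.append([np.log(s_beta), np.log(max(s_h0, _H_FLOOR)),
                   np.log(max(s_h1, _H_FLOOR)), np.log(max(s_h1, _H_FLOOR)),
                   float(s_t1), np.log(min(far, 2 * span + 2))])
    # constant-equivalent start (h0 = h1 = h2 = c reproduces the constant)
    starts.append([np.log(1.0), np.log(c_level), np.log(c_level),
                   np.log(c_level), float(tgrid[0]), np.log(span + 0.5)])

    best_ll, best_theta = -np.inf, None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float),
                     [b[0] for b in bounds], [b[1] for b in bounds])
        ll0 = -nll(x0)
        if ll0 > best_ll:
            best_ll, best_theta = ll0, x0
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 100})
        if -res.fun > best_ll:
            best_ll, best_theta = -res.fun, res.x
    return unpack(best_theta), float(best_ll)


def estimate_dispersions(counts, sf, timepoints) -> np.ndarray:
    """Per-feature NB dispersion: replicate-group MoM pooled across
    timepoints, shrunk toward the across-feature trend."""
    counts = np.asarray(counts, dtype=float)
    norm = counts / np.asarray(sf, dtype=float)
    tgrid = np.unique(timepoints)
    mom = np.empty(counts.shape[0])
    mu = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        groups = [norm[i, timepoints == tp] for tp in tgrid]
        mom[i], mu[i] = mom_dispersion(groups)
    return shrink_dispersion(mom, mu)


def fit_trajectory_models(counts_row, timepoints, sf, dispersion: float) -> ImpulseFit:
    """Fit constant, sigmoid, and impulse NB mean models to one feature."""
    y = np.asarray(counts_row, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct timepoints")
    c_level, ll_c = _fit_constant(y, sf, dispersion)
    sig_params, ll_s = _fit_sigmoid(y, t, sf, dispersion, c_level)
    imp_params, ll_i = _fit_impulse(y, t, sf, dispersion, c_level, sig_params)
    ll_s = max(ll_s, ll_c)     # nested-model ordering up to optimizer tolerance
    ll_i = max(ll_i, ll_s)
    return ImpulseFit(
        feature="", params=imp_params, sigmoid_params=sig_params,
        constant_level=c_level, loglik_constant=ll_c, loglik_sigmoid=ll_s,
        loglik_impulse=ll_i, dispersion=dispersion,
    )


def fit_all(matrix: TimecourseMatrix) -> list[ImpulseFit]:
    """Fit every feature of a time-course matrix."""
    t = matrix.timepoints
    disps = estimate_dispersions(matrix.counts, matrix.size_factors, t)
    fits = []
    for i, name in enumerate(matrix.feature_names):
        fit = fit_trajectory_models(matrix.counts[i], t, matrix.size_factors, disps[i])
        fit.feature = name
        fits.append(fit)
    return fits


def _direction(fit: ImpulseFit, t_lo: float, t_hi: float, transient: bool) -> str:
    grid = np.linspace(t_lo, t_hi, 201)
    f = impulse_value(grid, fit.params)
    start = f[0]
    if transient:
        dev = np.abs(f - start)
        ref = f[int(np.argmax(dev))]
    else:
        ref = f[-1]
    return "up" if ref >= start else "down"


def classify_trajectories(fits, timepoints, alpha: float = 0.05) -> list[TrajectoryCall]:
    """LRT-based classification into steady / transient / not significant.

    impulse vs constant (df 5) tests for any regulation; impulse vs sigmoid
    (df 2) tests for transience; both families BH-adjusted separately.
    """
    t = np.asarray(timepoints, dtype=float)
    t_lo, t_hi = float(t.min()), float(t.max())
    ok = [f for f in fits if f.converged]
    lrt_diff = np.array([2 * (f.loglik_impulse - f.loglik_constant) for f in ok])
    lrt_trans = np.array([2 * (f.loglik_impulse - f.loglik_sigmoid) for f in ok])
    p_diff = stats.chi2.sf(np.maximum(lrt_diff, 0.0), df=5)
    p_trans = stats.chi2.sf(np.maximum(lrt_trans, 0.0), df=2)
    padj_diff = bh_adjust(p_diff)
    padj_trans = bh_adjust(p_trans)
    calls = []
    for f, pd, qd, pt, qt in zip(ok, p_diff, padj_diff, p_trans, padj_trans):
        if qd <= alpha and qt <= alpha:
            category = "transient_" + _direction(f, t_lo, t_hi, transient=True)
        elif qd <= alpha:
            category = "steady_" + _direction(f, t_lo, t_hi, transient=False)
        else:
            category = "not_significant"
        calls.append(TrajectoryCall(f.feature, category, float(pd), float(qd),
                                    float(pt), float(qt)))
    return calls
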