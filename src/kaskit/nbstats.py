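"""Shared negative-binomial count machinery.

Parameterization: variance = mu + alpha * mu**2 (alpha is the dispersion).
Provides median-of-ratios size factors, method-of-moments dispersion with
mean-trend shrinkage, and the NB log-likelihood used by the imbalance test
and the time-course model fits.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

__all__ = ["size_factors", "mom_dispersion", "shrink_dispersion", "nb_loglik"]

ALPHA_FLOOR = 1e-8


def size_factors(count_matrix) -> np.ndarray:
    """DESeq2-style median-of-ratios per-sample size factors.

    Geometric means are taken per feature across samples (features containing
    any zero are excluded); the size factor of a sample is the median over
    features of count / geometric mean.
    """
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2:
        raise ValueError("count matrix must be 2-D (features x samples)")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature with all-positive counts; consider a pseudo-count mode"
        )
    pos = counts[all_positive]
    gm = np.exp(np.log(pos).mean(axis=1, keepdims=True))
    return np.median(pos / gm, axis=0)


def mom_dispersion(group_values) -> tuple[float, float]:
    """Pooled method-of-moments dispersion across >= 1 replicate groups.

    Returns (alpha_hat, mean_pooled) where alpha_hat = (var_pooled - mean) /
    mean**2 with variances pooled by degrees of freedom; alpha_hat may be
    negative (under-dispersion relative to Poisson) — callers decide how to
    floor/shrink it.
    """
    groups = [np.asarray(g, dtype=float) for g in group_values]
    n_obs = sum(g.size for g in groups)
    mean = sum(g.sum() for g in groups) / n_obs
    df = sum(g.size - 1 for g in groups)
    if df <= 0 or mean <= 0:
        return 0.0, float(mean)
    var = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    return float((var - mean) / mean**2), float(mean)


def shrink_dispersion(alpha_mom, mu, min_features_for_trend: int = 10) -> np.ndarray:
    """Shrink per-feature MoM dispersions toward a fitted mean-dispersion
    trend alpha(mu) = a1/mu + a0.

    The trend is fitted by least squares over all features (negative MoM
    values included, keeping the fit unbiased).  Features with a positive MoM
    estimate take the equal-weight arithmetic compromise with the trend;
    features where MoM is non-positive (common at 2 replicates) use the trend
    value alone.  Everything is floored at ALPHA_FLOOR.

    The compromise is averaged in linear space deliberately: the MoM
    estimator is unbiased in linear space, and log-space (geometric)
    averaging of a noisy unbiased estimate is downward-biased (Jensen),
    which makes the downstream Wald test anticonservative at few replicates.
    """
    alpha_mom = np.asarray(alpha_mom, dtype=float)
    mu = np.asarray(mu, dtype=float)
    ok = mu > 0
    if ok.sum() < min_features_for_trend:
        warnings.warn("too few features for a dispersion trend; using raw "
                      "method-of-moments dispersions")
        return np.maximum(alpha_mom, ALPHA_FLOOR)
    X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    trend = np.full_like(alpha_mom, ALPHA_FLOOR)
    trend[ok] = np.maximum(coef[0] / mu[ok] + coef[1], ALPHA_FLOOR)
    out = trend.copy()
    pos = ok & (alpha_mom > 0)
    out[pos] = 0.5 * alpha_mom[pos] + 0.5 * trend[pos]
    return np.maximum(out, ALPHA_FLOOR)


def nb_loglik(y, mu, alpha) -> float:
    """Negative-binomial log-likelihood (variance mu + alpha*mu**2).

    With r = 1/alpha:  sum over observations of
    lgamma(y+r) - lgamma(r) - lgamma(y+1) + r*log(r/(r+mu)) + y*log(mu/(r+mu)).
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    r = 1.0 / max(float(alpha), ALPHA_FLOOR)
    return float(np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))
    ))
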