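"""Genetic-parameter functionals, posterior summaries and diagnostics.

Under a sire model one quarter of the additive genetic variance sits in the
sire variance, hence the factor 4 in the heritability formulas.  All
functionals are intended to be evaluated draw-by-draw on a stored chain and
then summarized (posterior mean of per-iteration ratios); the ratio of
posterior means is a different — also meaningful — estimator and both are
exposed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "heritability",
    "intra_herd_h2",
    "cow_repeatability",
    "herd_repeatability",
    "correlation",
    "hpd_interval",
    "geweke_z",
    "liability_to_probability",
]


def _check_components(*vc):
    vc = [np.asarray(v, dtype=float) for v in vc]
    if any(np.any(v < 0) for v in vc):
        raise ValueError("variance components must be non-negative")
    return vc


def heritability(sire_var, pe_var, herd_var, res_var):
    """h2 = 4 sire / (sire + pe + herd + residual)."""
    s, p, h, e = _check_components(sire_var, pe_var, herd_var, res_var)
    denom = s + p + h + e
    if np.any(denom <= 0):
        raise ValueError("zero phenotypic variance")
    return 4.0 * s / denom


def intra_herd_h2(sire_var, pe_var, res_var):
    """Intra-herd heritability: herd variance excluded from the denominator."""
    s, p, e = _check_components(sire_var, pe_var, res_var)
    denom = s + p + e
    if np.any(denom <= 0):
        raise ValueError("zero phenotypic variance")
    return 4.0 * s / denom


def cow_repeatability(pe_var, sire_var, herd_var, res_var):
    """Cow repeatability free of the genetic term: pe / total."""
    p, s, h, e = _check_components(pe_var, sire_var, herd_var, res_var)
    denom = s + p + h + e
    if np.any(denom <= 0):
        raise ValueError("zero phenotypic variance")
    return p / denom


def herd_repeatability(herd_var, sire_var, pe_var, res_var):
    """Herd repeatability: herd / total."""
    h, s, p, e = _check_components(herd_var, sire_var, pe_var, res_var)
    denom = s + p + h + e
    if np.any(denom <= 0):
        raise ValueError("zero phenotypic variance")
    return h / denom


def correlation(cov, var1, var2):
    """Correlation = covariance / product of standard deviations."""
    cov = np.asarray(cov, dtype=float)
    v1 = np.asarray(var1, dtype=float)
    v2 = np.asarray(var2, dtype=float)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise ValueError("variances must be positive")
    return cov / np.sqrt(v1 * v2)


def hpd_interval(samples, level: float = 0.95):
    """Shortest interval containing ``ceil(level * n)`` sorted samples.

    This is the empirical highest-probability-density interval for a
    unimodal posterior.  ``level=1`` returns (min, max); a constant chain
    returns a zero-width interval.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    m = int(np.ceil(level * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _spectral_var0(x: np.ndarray) -> float:
    """Spectral density at frequency zero / n, by a Bartlett-windowed
    autocovariance sum (Newey-West)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    lag = min(n - 1, max(1, int(np.floor(4 * (n / 100.0) ** (2.0 / 9.0)))))
    g0 = float(x @ x) / n
    s = g0
    for k in range(1, lag + 1):
        gk = float(x[:-k] @ x[k:]) / n
        s += 2.0 * (1.0 - k / (lag + 1.0)) * gk
    return max(s, 0.0) / n


def geweke_z(samples, first: float = 0.1, last: float = 0.5):
    """Geweke convergence statistic.

    Compares the mean of the first `first` fraction of the chain with the
    mean of the last `last` fraction, with variances estimated from the
    spectral density at zero.  Returns NaN for a degenerate (constant)
    chain, which callers should flag.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    na, nb = int(first * n), int(last * n)
    if na < 2 or nb < 2:
        raise ValueError("chain too short for a Geweke comparison")
    a, b = x[:na], x[n - nb:]
    va, vb = _spectral_var0(a), _spectral_var0(b)
    if va + vb == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def liability_to_probability(eta, threshold, res_sd):
    """P(observed class above `threshold`) = 1 - Phi((t - eta) / sd)."""
    from scipy.special import ndtr

    eta = np.asarray(eta, dtype=float)
    return 1.0 - ndtr((threshold - eta) / res_sd)
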