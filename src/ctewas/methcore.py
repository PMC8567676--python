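"""Shared methylation mathematics.

Beta values are methylation proportions in [0, 1]; M-values are their
logit-2 transform ``M = log2(beta / (1 - beta))``, the variance-stabilised
scale on which per-CpG models are fit.  This module also carries the
multiple-testing corrections (Benjamini–Hochberg step-up, Bonferroni) and
the median-chi-square genomic inflation factor used to diagnose test-statistic
calibration in EWAS.

All functions are pure and vectorised over numpy arrays / pandas Series.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "bh_adjust",
    "bonferroni_adjust",
    "genomic_inflation",
]

#: Default boundary clip for the beta -> M transform; avoids infinite M
#: at beta = 0 or 1.
DEFAULT_EPSILON = 1e-3

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """Transform beta values to M-values, clipping boundaries.

    Parameters
    ----------
    beta
        Array-like of methylation proportions in [0, 1].
    epsilon
        Clip betas into [epsilon, 1 - epsilon] before the logit; must lie
        in (0, 0.5).

    Returns
    -------
    ndarray of ``log2(b / (1 - b))`` with ``b = clip(beta, eps, 1 - eps)``.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, epsilon, 1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (without the clip): ``2^m / (2^m + 1)``."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("M-values must be finite")
    # equivalent to expit(m * log 2); numerically safe for large |m|
    return stats.logistic.cdf(m * np.log(2.0))


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1))):
        raise ValueError("p values must be finite and in [0, 1]")
    return p


def bh_adjust(p):
    """Benjamini–Hochberg step-up q values.

    Returns q values in the input order; q >= p elementwise and q is
    monotone in the rank of p.
    """
    p = _validate_p(p)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_adjust(p, n_tests: int):
    """Bonferroni correction ``min(1, p * n_tests)``.

    ``n_tests`` may exceed ``len(p)``: in a two-stage design the correction
    is over the stage-1 test count, not the size of the tested subset.
    """
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    p = _validate_p(p)
    return np.minimum(1.0, p * float(n_tests))


def genomic_inflation(p) -> float:
    """Genomic inflation factor lambda from a vector of p values.

    Uses the median-chi-square estimator: the median of the chi-square(1)
    quantiles at 1 - p, divided by the chi-square(1) median (~0.4549).
    Lambda ~ 1 indicates calibrated tests; lambda > 1 indicates inflation.
    """
    p = _validate_p(p)
    if p.size == 0:
        raise ValueError("cannot compute inflation factor from empty input")
    if p.size < 100:
        warnings.warn(
            f"genomic_inflation computed from only {p.size} p values; "
            "the median-based estimate is unstable below ~100",
            stacklevel=2,
        )
    chi2_obs = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_obs) / CHI2_1_MEDIAN)
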