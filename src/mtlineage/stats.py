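"""Shared statistical helpers: Fisher combination, Storey q-values,
one-sided exact binomial tails.

These are deliberately small, well-specified primitives reused by the
enrichment and bias modules so that every analysis corrects its whole test
family the same way.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

_TINY = 1e-300  # floor for log of exact p-values


def fisher_combine(pvalues) -> float:
    """Combine independent p-values with Fisher's method.

    Returns the chi-square tail probability of ``-2 * sum(log p)`` on
    ``2k`` degrees of freedom for ``k`` p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    statistic = -2.0 * np.log(np.clip(p, _TINY, 1.0)).sum()
    return float(sps.chi2.sf(statistic, df=2 * p.size))


def storey_qvalue(pvalues, pi0: float | None = None, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values for a family of p-values.

    pi0 (the null proportion) is estimated from the tail above ``lambda_``:
    ``pi0 = #{p > lambda} / ((1 - lambda) * m)``, clipped to (0, 1].  With
    very small families this estimate is noisy; pass ``pi0=1.0`` for the
    conservative (BH-equivalent) behaviour.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.asarray([], dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = np.count_nonzero(p > lambda_) / ((1.0 - lambda_) * m)
        pi0 = float(min(max(pi0, 1.0 / m), 1.0))
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q
    return out


def binom_onesided(k, n, p) -> np.ndarray:
    """One-sided exact binomial p-value toward the observed direction.

    Upper tail when the observed rate exceeds ``p``, lower tail otherwise.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    upper = np.asarray(k / np.maximum(n, 1) >= p)
    return np.where(upper, sps.binom.sf(k - 1, n, p), sps.binom.cdf(k, n, p))


def binom_twosided(k, n, p) -> np.ndarray:
    """Two-sided binomial p-value as ``min(1, 2*min(lower, upper))``.

    The doubled-tail convention is used (rather than the minlike method)
    because it vectorises exactly and is conservative under the null.
    """
    k = np.asarray(k)
    lower = sps.binom.cdf(k, n, p)
    upper = sps.binom.sf(k - 1, n, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))
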