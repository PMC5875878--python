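"""Fixed-weight meta-analysis of experiment-level correlation estimates.

A pathway pair is estimated once per experiment; the global correlation is
the Hunter-Schmidt sample-size-weighted mean

    r_bar = sum_i n_i r_i / sum_i n_i

and the global significance is the Liptak (weighted Stouffer) combination of
the per-experiment p-values,

    Y = sum_i n_i * Phi^-1(1 - p_i) / sqrt(sum_i n_i^2),   p_c = 1 - Phi(Y)

with Phi the standard normal CDF.  Combined p-values across all pairs are
then adjusted with the Benjamini-Hochberg FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .correlation import ExperimentEstimate

#: p-values are clamped into [EPS, 1-EPS] before the normal quantile to keep
#: the combination finite at p = 0 or 1
EPS = 1e-15


@dataclass(frozen=True)
class AggregatedEstimate:
    """Global correlation and significance of one pathway pair."""

    set_i: str
    set_j: str
    r_bar: float
    p_combined: float
    n_experiments: int
    total_n: int


def hunter_schmidt(r: Sequence[float], n: Sequence[int]) -> float:
    """Sample-size-weighted mean correlation across experiments."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if r.size == 0 or r.size != n.size:
        raise ValueError("need equal-length, non-empty r and n")
    if np.any(n < 1):
        raise ValueError("sample sizes must be >= 1")
    return float((n * r).sum() / n.sum())


def liptak_combine(p: Sequence[float], n: Sequence[int]) -> float:
    """Weighted-quantile combination of per-experiment p-values."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if p.size == 0 or p.size != n.size:
        raise ValueError("need equal-length, non-empty p and n")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, EPS, 1.0 - EPS)
    z = norm.isf(p)  # Phi^-1(1 - p)
    y = float((n * z).sum() / np.sqrt((n**2).sum()))
    return float(norm.sf(y))


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_flags(q, alpha: float):
    """Boolean flags for q < alpha; alpha = 1 flags everything (no filter)."""
    q = np.asarray(q, dtype=float)
    if alpha >= 1.0:
        return np.ones_like(q, dtype=bool)
    return q < alpha


def aggregate_pair(estimates: Sequence[ExperimentEstimate]) -> AggregatedEstimate:
    """Combine one pair's experiment-level estimates into a global estimate."""
    if not estimates:
        raise ValueError("no usable experiment estimates for this pair")
    r = [e.r_star for e in estimates]
    n = [e.n for e in estimates]
    p = [e.p for e in estimates]
    first = estimates[0]
    return AggregatedEstimate(
        set_i=first.set_i,
        set_j=first.set_j,
        r_bar=hunter_schmidt(r, n),
        p_combined=liptak_combine(p, n),
        n_experiments=len(estimates),
        total_n=int(sum(n)),
    )
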