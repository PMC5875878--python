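"""Experiment-level pathway correlations with analytic shrinkage.

The association between two pathway expression summaries within one
experiment is a Spearman correlation, realized as the Pearson correlation of
the within-experiment ranks of the summary vectors.  The empirical
correlation matrix R is shrunk toward the identity target T with the analytic
intensity

    lambda* = sum_{k!=l} Var(r_kl) / sum_{k!=l} r_kl^2        (clamped to [0,1])

where Var(r_kl) is the small-sample variance of the correlation estimator
computed from standardized products (the Schafer-Strimmer analytic-shrinkage
framework).  When two gene sets share genes, the shrunk 3x3 correlation
matrix of (E_i, E_j, E_shared) is reduced to a first-order partial
correlation conditioned on the shared-gene summary, removing the association
contributed by the annotation overlap itself.

Significance is a two-sided t-test with n-2 degrees of freedom for disjoint
sets and n-3 for the conditioned case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateConditioningError(ValueError):
    """A pathway summary is indistinguishable from its shared-gene summary."""


@dataclass(frozen=True)
class ExperimentEstimate:
    """One pathway pair's shrunk (partial) correlation in one experiment."""

    experiment_id: str
    set_i: str
    set_j: str
    n: int
    r_raw: float
    lam: float
    r_star: float
    p: float
    df: int
    shared_summary_used: bool


def _rank_standardize(vectors: np.ndarray) -> np.ndarray:
    """Rank each row (average ties) and standardize to zero mean, unit sample sd."""
    ranked = stats.rankdata(vectors, axis=1, method="average")
    centered = ranked - ranked.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant summary vector at position {bad}")
    return centered / sd[:, None]


def shrinkage_corr_matrix(
    vectors, shrink: str = "pre"
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shrunk Spearman correlation matrix of m summary vectors.

    Parameters
    ----------
    vectors : array-like, shape (m, n)
        m summary vectors observed on the same n samples; each is replaced by
        its within-experiment ranks before correlating.
    shrink : {'pre', 'off'}
        'pre' applies the analytic shrinkage toward the identity; 'off'
        returns the empirical matrix (lambda forced to 0), used for
        sensitivity checks and oracle comparisons.

    Returns
    -------
    r_star : (m, m) ndarray
        Shrunk correlation matrix ``lambda*I + (1-lambda)*R``.
    r_raw : (m, m) ndarray
        Empirical (unshrunk) correlation matrix R.
    lam : float
        The shrinkage intensity actually applied.
    """
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need at least two vectors")
    m, n = V.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    W = _rank_standardize(V)

    R = W @ W.T / (n - 1)
    np.fill_diagonal(R, 1.0)
    R = np.clip(R, -1.0, 1.0)

    if shrink == "off":
        lam = 0.0
    elif shrink == "pre":
        # Var(r_kl) from the standardized products q_i = w_ki * w_li:
        #   Var(r_kl) = n/(n-1)^3 * sum_i (q_i - q_bar)^2
        # using sum_i q_i = (n-1) r_kl to avoid forming the products pairwise.
        W2 = W * W
        sum_q2 = W2 @ W2.T
        ss = sum_q2 - ((n - 1) * R) ** 2 / n
        var_r = n / (n - 1) ** 3 * ss
        off = ~np.eye(m, dtype=bool)
        denom = float((R[off] ** 2).sum())
        if denom == 0.0:
            lam = 1.0
        else:
            lam = float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    else:
        raise ValueError(f"unknown shrink mode: {shrink!r}")

    r_star = (1.0 - lam) * R
    np.fill_diagonal(r_star, 1.0)
    return r_star, R, lam


def corr_test(r_star: float, n: int, df: int) -> float:
    """Two-sided p-value for H0: correlation = 0 via the t distribution.

    t = r * sqrt(df) / sqrt(1 - r^2) with the stated degrees of freedom
    (n-2 for plain, n-3 for first-order partial correlations).
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    r = float(r_star)
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"|r| > 1: {r}")
    r = max(-1.0, min(1.0, r))
    if r == 0.0:
        return 1.0
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df))


def pathcor_disjoint(
    E_i,
    E_j,
    experiment_id: str = "",
    set_i: str = "",
    set_j: str = "",
    shrink: str = "pre",
) -> ExperimentEstimate:
    """PathCor for two gene sets without shared genes: shrunk Spearman r."""
    V = np.vstack([np.asarray(E_i, float), np.asarray(E_j, float)])
    n = V.shape[1]
    r_star_mat, r_raw_mat, lam = shrinkage_corr_matrix(V, shrink=shrink)
    r_star = float(r_star_mat[0, 1])
    df = n - 2
    p = corr_test(r_star, n, df)
    return ExperimentEstimate(
        experiment_id, set_i, set_j, n, float(r_raw_mat[0, 1]), lam, r_star, p, df, False
    )


def partial_from_matrix(r: np.ndarray) -> float:
    """First-order partial correlation r_12.3 from a 3x3 correlation matrix."""
    r_ij, r_is, r_js = r[0, 1], r[0, 2], r[1, 2]
    denom = (1.0 - r_is**2) * (1.0 - r_js**2)
    if denom <= 1e-24:
        raise DegenerateConditioningError(
            "a summary is perfectly correlated with the shared-gene summary"
        )
    return float((r_ij - r_is * r_js) / np.sqrt(denom))


def pathcor_overlap(
    E_i,
    E_j,
    E_shared,
    experiment_id: str = "",
    set_i: str = "",
    set_j: str = "",
    shrink: str = "pre",
) -> ExperimentEstimate:
    """PathCor for overlapping gene sets: partial correlation given the
    shared-gene summary, computed from the shrunk 3x3 correlation matrix
    (one common lambda for the triplet)."""
    V = np.vstack(
        [np.asarray(E_i, float), np.asarray(E_j, float), np.asarray(E_shared, float)]
    )
    n = V.shape[1]
    r_star_mat, r_raw_mat, lam = shrinkage_corr_matrix(V, shrink=shrink)
    if max(abs(r_raw_mat[0, 2]), abs(r_raw_mat[1, 2])) >= 1.0 - 1e-12:
        raise DegenerateConditioningError(
            "pathway summary indistinguishable from its shared-gene summary"
        )
    r_star = partial_from_matrix(r_star_mat)
    r_star = max(-1.0, min(1.0, r_star))
    df = n - 3
    p = corr_test(r_star, n, df)
    return ExperimentEstimate(
        experiment_id, set_i, set_j, n, float(r_raw_mat[0, 1]), lam, r_star, p, df, True
    )
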