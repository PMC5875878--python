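"""Split-based validation harness: structured vs random gene-set splits.

A structured gene set (in the motivating use, the 126-gene KEGG Ribosome
pathway; here, a planted coexpression module) is repeatedly permuted and
split into two halves -- disjoint, or overlapping according to a stepping
schema -- and the full pathway-correlation pipeline is run on each split.  A
size-matched random gene set is split with identical geometry at every
iteration as the paired negative control.  Treating a significant p-value
for the structured set as a true positive and for the random set as a false
positive yields a ROC curve over p-value cutoffs.

The stepping schema on n indexed elements alternates shrink and shift
operations: after step t (a = ceil(t/2) shrinks, b = floor(t/2) shifts)

    s1 = {1, ..., n - a},   s2 = {b + 1, ..., n}

so the two sets share max(0, n - a - b) elements; at t = n they are the two
disjoint halves.  On n = 126 the steps t = 33, 78 and 123 give overlap
coefficients 93/109 = 0.8532, 48/87 = 0.5517 and 3/64 = 0.0469.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .correlation import (
    DegenerateConditioningError,
    pathcor_disjoint,
    pathcor_overlap,
)
from .io_formats import ExperimentGrouping
from .meta_aggregation import aggregate_pair
from .rank_summary import rank_transform


def default_steps(n: int) -> tuple[int, ...]:
    """The three canonical overlap configurations, scaled to a set of size n.

    On n = 126 these are t = 33, 78 and 123 (high, medium and low overlap);
    for other sizes the step fractions t/n are preserved.
    """
    steps = tuple(
        sorted({min(n, max(1, round(n * t / 126))) for t in (33, 78, 123)})
    )
    return steps


def stepping_counts(n: int, t: int) -> tuple[int, int]:
    """(a, b) = (number of shrink, shift operations) after step t."""
    if not 1 <= t <= n:
        raise ValueError(f"step index t must be in 1..{n}, got {t}")
    return (t + 1) // 2, t // 2


def split_no_overlap(genes: Sequence[str], seed: int) -> tuple[list[str], list[str]]:
    """Seeded permutation, then split into two equal disjoint halves."""
    genes = list(genes)
    n = len(genes)
    if n < 4 or n % 2:
        raise ValueError(f"need an even number >= 4 of genes, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    half = n // 2
    return [genes[i] for i in perm[:half]], [genes[i] for i in perm[half:]]


def split_with_overlap(
    genes: Sequence[str], t: int, seed: int
) -> tuple[list[str], list[str]]:
    """Seeded permutation, then the stepping-schema overlapping split at step t."""
    genes = list(genes)
    n = len(genes)
    a, b = stepping_counts(n, t)
    perm = np.random.default_rng(seed).permutation(n)
    s1 = [genes[i] for i in perm[: n - a]]
    s2 = [genes[i] for i in perm[b:]]
    return s1, s2


def random_geneset(background: Sequence[str], size: int, seed: int) -> list[str]:
    """Seeded uniform sample of genes without replacement."""
    background = list(background)
    if size > len(background):
        raise ValueError(f"cannot sample {size} genes from {len(background)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(background), size=size, replace=False)
    return [background[i] for i in idx]


@dataclass
class BenchmarkResult:
    """Per-iteration estimates and ROC summaries of a benchmark run."""

    estimates: pd.DataFrame  # iteration, case, kind, r_bar, p_combined, ...
    roc: dict[str, pd.DataFrame] = field(default_factory=dict)
    auc: dict[str, float] = field(default_factory=dict)

    def confusion(self, case: str, cutoff: float = 0.05) -> dict[str, int]:
        """TP/FP/FN/TN counts at a p-value cutoff (inclusive significance)."""
        sub = self.estimates[self.estimates["case"] == case]
        p_true = sub.loc[sub["kind"] == "structured", "p_combined"]
        p_rand = sub.loc[sub["kind"] == "random", "p_combined"]
        return {
            "TP": int((p_true <= cutoff).sum()),
            "FN": int((p_true > cutoff).sum()),
            "FP": int((p_rand <= cutoff).sum()),
            "TN": int((p_rand > cutoff).sum()),
        }


def roc_from_pvalues(
    p_true: Sequence[float], p_random: Sequence[float]
) -> tuple[pd.DataFrame, float]:
    """ROC over p-value cutoffs and its trapezoidal AUC.

    A structured-set p-value at or below the cutoff is a true positive, a
    random-set one a false positive; cutoffs run over the sorted union of
    the observed p-values plus {0, 1}.
    """
    p_true = np.asarray(p_true, float)
    p_random = np.asarray(p_random, float)
    if p_true.size == 0 or p_random.size == 0:
        raise ValueError("both p-value lists must be non-empty")
    cutoffs = np.unique(np.concatenate([[0.0, 1.0], p_true, p_random]))
    tpr = (p_true[None, :] <= cutoffs[:, None]).mean(axis=1)
    fpr = (p_random[None, :] <= cutoffs[:, None]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    roc = pd.DataFrame({"cutoff": cutoffs, "fpr": fpr, "tpr": tpr})
    return roc, auc


def _split_pair_estimate(
    ranks: pd.DataFrame,
    exp_samples: dict[str, list[str]],
    s1: list[str],
    s2: list[str],
    shrink: str,
):
    """Run the pathway-correlation pipeline on one split (all experiments)."""
    shared = sorted(set(s1) & set(s2))
    E1_all = ranks.loc[s1].mean(axis=0)
    E2_all = ranks.loc[s2].mean(axis=0)
    E_sh_all = ranks.loc[shared].mean(axis=0) if shared else None
    estimates = []
    for exp, samples in exp_samples.items():
        E1 = E1_all[samples].to_numpy()
        E2 = E2_all[samples].to_numpy()
        try:
            if shared:
                est = pathcor_overlap(
                    E1, E2, E_sh_all[samples].to_numpy(), exp, "s1", "s2", shrink=shrink
                )
            else:
                est = pathcor_disjoint(E1, E2, exp, "s1", "s2", shrink=shrink)
        except DegenerateConditioningError:
            # a summary can coincide in ordering with the shared-gene summary
            # in a small experiment; that experiment carries no information
            # about the conditioned association and is skipped
            continue
        estimates.append(est)
    return aggregate_pair(estimates), len(shared)


def run_benchmark(
    expr: pd.DataFrame,
    grouping: ExperimentGrouping,
    structured_set: Sequence[str],
    iterations: int = 100,
    steps: Sequence[int] | None = None,
    include_no_overlap: bool = True,
    seed: int = 0,
    config: RunConfig | None = None,
) -> BenchmarkResult:
    """Paired structured-vs-random split benchmark with ROC per case.

    At every iteration the structured set and a freshly sampled size-matched
    random set are split with identical geometry (same case, same iteration
    seed), the full estimation pipeline is run on both, and the aggregated
    p-values are recorded.  Cases are the no-overlap split plus each
    requested stepping index.
    """
    config = (config or RunConfig()).validate()
    if steps is None:
        steps = config.steps
    structured_set = list(structured_set)
    if steps is None:
        steps = default_steps(len(structured_set))
    missing = [g for g in structured_set if g not in expr.index]
    if missing:
        raise ValueError(f"structured set has unmeasured genes: {missing[:5]}")
    grouping.validate_against(expr.columns)

    ranks = rank_transform(expr)
    exp_samples = {
        exp: grouping.samples_of(exp)
        for exp in grouping.experiments
        if grouping.sample_counts[exp] >= config.min_experiment_size
    }
    if not exp_samples:
        raise ValueError("no experiment meets the minimum size")
    background = list(expr.index)
    size = len(structured_set)

    cases: list[tuple[str, int | None]] = []
    if include_no_overlap:
        cases.append(("no_overlap", None))
    cases.extend((f"step_{t}", t) for t in steps)

    seedseq = np.random.SeedSequence(seed)
    iter_seeds = seedseq.generate_state(2 * max(iterations, 1) * max(len(cases), 1))

    rows = []
    idx = 0
    for case, t in cases:
        for it in range(iterations):
            split_seed = int(iter_seeds[idx] % (2**31))
            sample_seed = int(iter_seeds[idx + 1] % (2**31))
            idx += 2
            rand_set = random_geneset(background, size, sample_seed)
            for kind, genes in (("structured", structured_set), ("random", rand_set)):
                if t is None:
                    s1, s2 = split_no_overlap(genes, split_seed)
                else:
                    s1, s2 = split_with_overlap(genes, t, split_seed)
                agg, n_shared = _split_pair_estimate(
                    ranks, exp_samples, s1, s2, config.shrink
                )
                rows.append(
                    {
                        "iteration": it,
                        "case": case,
                        "kind": kind,
                        "r_bar": agg.r_bar,
                        "p_combined": agg.p_combined,
                        "n_shared": n_shared,
                    }
                )

    estimates = pd.DataFrame(rows)
    result = BenchmarkResult(estimates=estimates)
    if iterations > 0:
        for case, _ in cases:
            sub = estimates[estimates["case"] == case]
            roc, auc = roc_from_pvalues(
                sub.loc[sub["kind"] == "structured", "p_combined"],
                sub.loc[sub["kind"] == "random", "p_combined"],
            )
            result.roc[case] = roc
            result.auc[case] = auc
    return result
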