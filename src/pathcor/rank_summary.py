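"""Within-array rank transform and per-experiment pathway expression summaries.

Each array (column) is ranked independently over the full gene universe, from
1 (lowest expression) to K (highest), with ties receiving average ranks.  The
expression summary of a pathway in a sample is the mean rank of its measured
member genes, so every summary lives on the common scale [1, K] regardless of
the dynamic range of the underlying array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExperimentGrouping, GeneSet, GeneSetCollection


class PathwayExcludedError(ValueError):
    """Raised when a gene set has too few measured members to summarize."""


def rank_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace each column of the expression matrix by its within-column ranks.

    Ranks are ascending (1 = lowest expression, K = highest) and ties receive
    the average of the tied positions, so every column sums to K(K+1)/2
    exactly.
    """
    ranks = rankdata(expr.to_numpy(dtype=float), axis=0, method="average")
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


@dataclass(frozen=True)
class PathwaySummary:
    """Mean member-gene rank of one gene set in one experiment's samples."""

    experiment_id: str
    set_id: str
    values: pd.Series  # indexed by sample id
    n_used: int


def pathway_summary(
    ranks: pd.DataFrame,
    genes,
    samples=None,
    min_genes_measured: int = 2,
    set_id: str = "",
    experiment_id: str = "",
) -> PathwaySummary:
    """Summarize a gene set as the per-sample mean rank of its measured members.

    Members absent from the rank matrix are dropped; if fewer than
    ``min_genes_measured`` remain the set is excluded with
    :class:`PathwayExcludedError`.
    """
    if isinstance(genes, GeneSet):
        set_id = set_id or genes.set_id
        genes = genes.genes
    genes = list(dict.fromkeys(genes))
    measured = [g for g in genes if g in ranks.index]
    if len(measured) < min_genes_measured:
        raise PathwayExcludedError(
            f"gene set {set_id or '<anonymous>'!r}: {len(measured)} of {len(genes)} "
            f"members measured, need >= {min_genes_measured}"
        )
    sub = ranks.loc[measured]
    if samples is not None:
        sub = sub[list(samples)]
    values = sub.mean(axis=0)
    return PathwaySummary(experiment_id, set_id, values, len(measured))


def summarize_collection(
    ranks: pd.DataFrame,
    grouping: ExperimentGrouping,
    collection: GeneSetCollection,
    min_genes_measured: int = 2,
    min_experiment_size: int = 5,
) -> dict[str, dict[str, PathwaySummary]]:
    """Per-experiment summaries for every retained pathway in a collection.

    Returns ``{experiment_id: {set_id: PathwaySummary}}`` in deterministic
    (sorted experiment, collection) order.  Experiments smaller than
    ``min_experiment_size`` and sets with too few measured genes are skipped.
    """
    grouping.validate_against(ranks.columns)
    background = ranks.index
    out: dict[str, dict[str, PathwaySummary]] = {}
    # precompute the measured member list once per set
    measured = {s.set_id: list(s.measured(background)) for s in collection}
    for exp in grouping.experiments:
        samples = [s for s in ranks.columns if grouping.mapping[s] == exp]
        if len(samples) < min_experiment_size:
            continue
        per_set: dict[str, PathwaySummary] = {}
        sub = ranks[samples]
        for s in collection:
            genes = measured[s.set_id]
            if len(genes) < min_genes_measured:
                continue
            values = sub.loc[genes].mean(axis=0)
            per_set[s.set_id] = PathwaySummary(exp, s.set_id, values, len(genes))
        out[exp] = per_set
    return out
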