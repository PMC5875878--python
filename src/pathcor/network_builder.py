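"""Assemble the pathway coexpression network and its query operations.

For every unordered pair of pathways the pipeline estimates a shrunk
(shared-gene-adjusted) correlation per experiment, aggregates across
experiments (Hunter-Schmidt mean, Liptak combined p), applies BH-FDR jointly
over all pairs, and attaches annotation-overlap statistics.  An edge exists
in the network iff its adjusted combined p-value passes the alpha cutoff.

Query gene signatures are integrated as extra nodes with the same machinery;
their p-values enter the same BH universe as the pathway-pathway pairs.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .config import RunConfig
from .correlation import (
    DegenerateConditioningError,
    ExperimentEstimate,
    pathcor_disjoint,
    pathcor_overlap,
)
from .io_formats import (
    EDGE_COLUMNS,
    ExperimentGrouping,
    GeneSet,
    GeneSetCollection,
    sort_edges,
)
from .meta_aggregation import aggregate_pair, bh_fdr, significance_flags
from .overlap_analysis import overlap_table
from .rank_summary import rank_transform, summarize_collection

logger = logging.getLogger(__name__)


def _pair_estimates(
    ranks: pd.DataFrame,
    summaries: dict[str, dict[str, "object"]],
    measured: dict[str, list[str]],
    exp_samples: dict[str, list[str]],
    set_i: str,
    set_j: str,
    shrink: str,
) -> list[ExperimentEstimate]:
    """Per-experiment estimates for one pair, overlap-adjusted when needed."""
    shared = sorted(set(measured[set_i]) & set(measured[set_j]))
    estimates: list[ExperimentEstimate] = []
    for exp, per_set in summaries.items():
        if set_i not in per_set or set_j not in per_set:
            continue
        E_i = per_set[set_i].values.to_numpy()
        E_j = per_set[set_j].values.to_numpy()
        try:
            if shared:
                E_sh = ranks.loc[shared, exp_samples[exp]].mean(axis=0).to_numpy()
                est = pathcor_overlap(
                    E_i, E_j, E_sh, exp, set_i, set_j, shrink=shrink
                )
            else:
                est = pathcor_disjoint(E_i, E_j, exp, set_i, set_j, shrink=shrink)
        except (DegenerateConditioningError, ValueError) as err:
            logger.warning("pair (%s, %s) in %s skipped: %s", set_i, set_j, exp, err)
            continue
        estimates.append(est)
    return estimates


def estimate_all_pairs(
    expr: pd.DataFrame,
    grouping: ExperimentGrouping,
    collection: GeneSetCollection,
    config: RunConfig | None = None,
    extra_sets: GeneSetCollection | None = None,
) -> pd.DataFrame:
    """Aggregated estimates for all pathway pairs (and optional extra nodes).

    Returns the unfiltered pair table (no FDR yet) with columns
    pathway_a, pathway_b, pathcor, p_combined, n_experiments, total_n,
    n_shared, is_query.
    """
    config = (config or RunConfig()).validate()
    ranks = rank_transform(expr)
    summaries = summarize_collection(
        ranks,
        grouping,
        collection,
        min_genes_measured=config.min_genes_measured,
        min_experiment_size=config.min_experiment_size,
    )
    exp_samples = {
        exp: [s for s in ranks.columns if grouping.mapping[s] == exp]
        for exp in summaries
    }
    measured = {
        s.set_id: list(s.measured(ranks.index)) for s in collection
    }
    pairs = [(a, b, False) for a, b in combinations(collection.set_ids, 2)]

    if extra_sets is not None:
        extra_summaries = summarize_collection(
            ranks,
            grouping,
            extra_sets,
            min_genes_measured=config.min_genes_measured,
            min_experiment_size=config.min_experiment_size,
        )
        for exp in summaries:
            summaries[exp].update(extra_summaries.get(exp, {}))
        for s in extra_sets:
            measured[s.set_id] = list(s.measured(ranks.index))
            pairs.extend((s.set_id, b, True) for b in collection.set_ids)

    rows = []
    for set_i, set_j, is_query in pairs:
        estimates = _pair_estimates(
            ranks, summaries, measured, exp_samples, set_i, set_j, config.shrink
        )
        if not estimates:
            logger.warning("pair (%s, %s): no usable experiments, dropped", set_i, set_j)
            continue
        agg = aggregate_pair(estimates)
        rows.append(
            {
                "pathway_a": set_i,
                "pathway_b": set_j,
                "pathcor": agg.r_bar,
                "p_combined": agg.p_combined,
                "n_experiments": agg.n_experiments,
                "total_n": agg.total_n,
                "n_shared": len(set(measured[set_i]) & set(measured[set_j])),
                "is_query": is_query,
            }
        )
    return pd.DataFrame(rows)


def build_pcxn(
    expr: pd.DataFrame,
    grouping: ExperimentGrouping,
    collection: GeneSetCollection,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Full network build: estimates, joint FDR, overlap statistics.

    Returns one row per pathway pair with the canonical edge columns;
    ``significant`` marks network edges (q < alpha).
    """
    config = (config or RunConfig()).validate()
    table = estimate_all_pairs(expr, grouping, collection, config)
    if table.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    table["q"] = bh_fdr(table["p_combined"].to_numpy())
    table["significant"] = significance_flags(table["q"], config.alpha)

    background = expr.index
    ov = overlap_table(collection, background, alpha=config.alpha)
    ov = ov.rename(
        columns={
            "set_i": "pathway_a",
            "set_j": "pathway_b",
            "o": "overlap_coefficient",
            "significant": "overlap_significant",
        }
    ).drop(columns=["n_shared"])
    table = table.merge(ov, on=["pathway_a", "pathway_b"], how="left")
    return sort_edges(table[EDGE_COLUMNS + ["n_experiments", "total_n"]])


def integrate_query(
    expr: pd.DataFrame,
    grouping: ExperimentGrouping,
    collection: GeneSetCollection,
    signature: GeneSet,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Integrate a query gene signature as an additional network node.

    The signature's pairwise estimates join the pathway-pathway pairs in a
    single BH universe; the returned table holds only the signature's pairs,
    ranked by |pathcor| among the significant ones first.
    """
    config = (config or RunConfig()).validate()
    measured = signature.measured(expr.index)
    if len(measured) < config.min_genes_measured:
        raise ValueError(
            f"signature {signature.set_id!r}: only {len(measured)} genes measured"
        )
    if signature.set_id in collection.set_ids:
        raise ValueError(f"signature id {signature.set_id!r} collides with a pathway")
    table = estimate_all_pairs(
        expr, grouping, collection, config,
        extra_sets=GeneSetCollection([signature]),
    )
    table["q"] = bh_fdr(table["p_combined"].to_numpy())
    table["significant"] = significance_flags(table["q"], config.alpha)
    out = table[table["is_query"]].copy()
    out["neighbor"] = out["pathway_b"]
    out["_abs"] = out["pathcor"].abs()
    out = out.sort_values(
        by=["significant", "_abs", "q", "neighbor"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).drop(columns="_abs")
    return out.reset_index(drop=True)


def top_neighbors(edges: pd.DataFrame, node: str, k: int = 10) -> pd.DataFrame:
    """The k significant edges at ``node`` with the largest |pathcor|.

    Ties are broken by ascending q and then lexicographic partner id so the
    result is fully deterministic.
    """
    mask = (edges["pathway_a"] == node) | (edges["pathway_b"] == node)
    if not mask.any():
        raise KeyError(f"node {node!r} not present in the edge table")
    sub = edges[mask & edges["significant"]].copy()
    sub["neighbor"] = np.where(
        sub["pathway_a"] == node, sub["pathway_b"], sub["pathway_a"]
    )
    sub["_abs"] = sub["pathcor"].abs()
    sub = sub.sort_values(
        by=["_abs", "q", "neighbor"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_abs")
    return sub.head(k).reset_index(drop=True)


def cluster_pathways(
    edges: pd.DataFrame, nodes: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering with distance 1 - |pathcor|.

    Pairs absent from the edge table are assigned |pathcor| = 0 (distance 1).
    Returns the scipy linkage matrix and the leaf ordering (node labels).
    """
    if nodes is None:
        nodes = sorted(set(edges["pathway_a"]) | set(edges["pathway_b"]))
    if len(nodes) < 2:
        raise ValueError("need at least two nodes to cluster")
    index = {n: i for i, n in enumerate(nodes)}
    dist = np.ones((len(nodes), len(nodes)))
    np.fill_diagonal(dist, 0.0)
    known = set()
    for row in edges.itertuples(index=False):
        i, j = index.get(row.pathway_a), index.get(row.pathway_b)
        if i is None or j is None:
            continue
        dist[i, j] = dist[j, i] = 1.0 - abs(row.pathcor)
        known.add((min(i, j), max(i, j)))
    n_missing = len(nodes) * (len(nodes) - 1) // 2 - len(known)
    if n_missing:
        logger.warning("%d node pairs without estimates set to distance 1", n_missing)
    linkage = average(squareform(dist, checks=False))
    order = [nodes[i] for i in leaves_list(linkage)]
    return linkage, order


def enrichment_bin_curve(
    ranked_neighbors: list[str], flagged: set[str] | list[str], bin_step: int = 10
) -> list[tuple[int, float]]:
    """Proportion of flagged elements among the top-s, top-2s, ... neighbors.

    The final bin always covers the full ranked list even when its length is
    not a multiple of ``bin_step``.
    """
    flagged = set(flagged)
    sizes = list(range(bin_step, len(ranked_neighbors), bin_step))
    sizes.append(len(ranked_neighbors))
    out = []
    for s in sizes:
        top = ranked_neighbors[:s]
        out.append((s, sum(1 for x in top if x in flagged) / s))
    return out
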