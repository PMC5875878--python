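"""Annotation overlap between gene sets: overlap coefficient and Fisher test.

The overlap coefficient o_GH = |G n H| / min(|G|, |H|) is 1 whenever one set
is contained in the other and 0 when they are disjoint, which is why it is
preferred here over the Jaccard index: redundant annotations stand out.
Overlap significance is a one-sided Fisher's exact test on the 2x2 table
(|GnH|, |G\\H|; |H\\G|, rest) over the measured-gene background, with BH-FDR
across all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io_formats import GeneSetCollection
from .meta_aggregation import bh_fdr, significance_flags


@dataclass(frozen=True)
class OverlapResult:
    set_i: str
    set_j: str
    o: float
    n_shared: int
    fisher_p: float
    contingency: tuple[int, int, int, int]  # (GnH, G\H, H\G, neither)


def overlap_coefficient(G: Iterable[str], H: Iterable[str]) -> float:
    """|G n H| / min(|G|, |H|); both sets must be non-empty."""
    G, H = set(G), set(H)
    if not G or not H:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(G & H) / min(len(G), len(H))


def fisher_overlap(
    G: Iterable[str], H: Iterable[str], background: Iterable[str]
) -> tuple[float, tuple[int, int, int, int]]:
    """One-sided (enrichment) Fisher's exact p for the shared-gene table."""
    G, H, bg = set(G), set(H), set(background)
    if not G <= bg or not H <= bg:
        raise ValueError("gene sets must be subsets of the background")
    both = len(G & H)
    only_g = len(G - H)
    only_h = len(H - G)
    neither = len(bg) - both - only_g - only_h
    table = np.array([[both, only_g], [only_h, neither]])
    p = float(fisher_exact(table, alternative="greater")[1])
    return p, (both, only_g, only_h, neither)


def overlap_table(
    collection: GeneSetCollection,
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs overlap statistics with BH-adjusted Fisher p-values.

    Sets are restricted to the measured background before any statistic is
    computed.  Returns one row per unordered pair in collection order with
    columns set_i, set_j, o, n_shared, fisher_p, fisher_q, significant.
    """
    bg = set(background)
    if len(collection) < 2:
        raise ValueError("need at least two gene sets")
    restricted = {s.set_id: set(s.genes) & bg for s in collection}
    rows = []
    for a, b in combinations(collection.set_ids, 2):
        G, H = restricted[a], restricted[b]
        p, cells = fisher_overlap(G, H, bg)
        rows.append(
            {
                "set_i": a,
                "set_j": b,
                "o": overlap_coefficient(G, H) if G and H else float("nan"),
                "n_shared": cells[0],
                "fisher_p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["fisher_q"] = bh_fdr(table["fisher_p"].to_numpy())
    table["significant"] = significance_flags(table["fisher_q"], alpha)
    return table
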