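"""Readers and writers for the external formats used by the pipeline.

Expression backgrounds are tab-separated gene x sample tables, gene sets
come as GMT collections (the MSigDB interchange format), sample-to-experiment
assignments as two-column TSV, and networks leave as edge tables or GraphML.
Gene identifiers are opaque strings throughout; no namespace translation is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column order of the edge table written by :func:`write_edges`
EDGE_COLUMNS = [
    "pathway_a",
    "pathway_b",
    "pathcor",
    "p_combined",
    "q",
    "overlap_coefficient",
    "n_shared",
    "fisher_p",
    "fisher_q",
    "significant",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (pathway annotation)."""

    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        # preserve first-occurrence order while deduplicating
        seen: dict[str, None] = dict.fromkeys(self.genes)
        object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def measured(self, background: Iterable[str]) -> tuple[str, ...]:
        """Members present in the expression background, in annotation order."""
        bg = set(background)
        return tuple(g for g in self.genes if g in bg)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique identifiers."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate gene set ids: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]


class ExperimentGrouping:
    """Assignment of each sample to exactly one experiment."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = dict(mapping)
        counts: dict[str, int] = {}
        for exp in self.mapping.values():
            counts[exp] = counts.get(exp, 0) + 1
        self.sample_counts = counts

    @property
    def experiments(self) -> list[str]:
        # deterministic: sorted experiment ids
        return sorted(self.sample_counts)

    def samples_of(self, experiment_id: str) -> list[str]:
        return [s for s, e in self.mapping.items() if e == experiment_id]

    def validate_against(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValueError(
                f"{len(missing)} samples missing from grouping: {missing[:10]}"
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, ExperimentGrouping) and self.mapping == other.mapping


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of an expression matrix (genes x samples)."""
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:10]}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:10]}")
    if expr.shape[0] < 2 or expr.shape[1] < 1:
        raise ValueError(f"expression matrix too small: {expr.shape}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return expr


def read_expression(
    path: str | Path,
    probe_map: Mapping[str, str] | None = None,
    collapse: str = "mean",
) -> pd.DataFrame:
    """Read a gene x sample expression table from TSV.

    The first column holds row identifiers (genes, or probes when
    ``probe_map`` is given) and the header row holds sample ids.  Probes
    mapping to the same gene are collapsed to a single row: with
    ``collapse='mean'`` the per-sample mean over the probes, with
    ``collapse='max_mean'`` the probe with the highest overall mean
    expression.  Probes absent from ``probe_map`` are dropped (counted in a
    warning).  Rows containing missing values are dropped.

    Returns a validated DataFrame sorted by gene id.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")

    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)

    n_missing = int(expr.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d rows with missing values", n_missing)
        expr = expr.dropna(axis=0)

    if probe_map is not None:
        mapped = expr.index.to_series().map(dict(probe_map))
        n_unmapped = int(mapped.isna().sum())
        if n_unmapped:
            logger.warning("dropping %d unmapped probes", n_unmapped)
        expr = expr.loc[mapped.notna().to_numpy()]
        genes = mapped.dropna()
        if collapse == "mean":
            expr = expr.groupby(genes.to_numpy()).mean()
        elif collapse == "max_mean":
            overall = expr.mean(axis=1)
            order = overall.groupby(genes.to_numpy()).idxmax()
            expr = expr.loc[order.to_numpy()]
            expr.index = order.index
        else:
            raise ValueError(f"unknown collapse rule: {collapse!r}")
        expr.index.name = "gene_id"
    elif expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids without a probe map: {dupes[:10]}")

    expr = expr.sort_index()
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a gene-set collection in GMT format (set, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description, *s.genes]) + "\n")


def read_grouping(path: str | Path) -> ExperimentGrouping:
    """Read a two-column TSV mapping sample_id -> experiment_id."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "experiment_id"], dtype=str)
    mapping: dict[str, str] = {}
    for sample, exp in zip(table["sample_id"], table["experiment_id"]):
        if sample in mapping and mapping[sample] != exp:
            raise ValueError(
                f"sample {sample!r} assigned to both {mapping[sample]!r} and {exp!r}"
            )
        mapping[sample] = exp
    return ExperimentGrouping(mapping)


def write_grouping(grouping: ExperimentGrouping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, exp in grouping.mapping.items():
            fh.write(f"{sample}\t{exp}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one identifier per line, deduplicated."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return list(dict.fromkeys(genes))


def sort_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Stable edge ordering: q ascending, then |pathcor| descending, then ids."""
    edges = edges.copy()
    edges["_abs"] = edges["pathcor"].abs()
    edges = edges.sort_values(
        by=["q", "_abs", "pathway_a", "pathway_b"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_abs")
    return edges.reset_index(drop=True)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    """Write the edge table as TSV with the canonical column order and sort."""
    out = sort_edges(edges[EDGE_COLUMNS]) if len(edges) else edges.reindex(columns=EDGE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graphml(edges: pd.DataFrame, path: str | Path, significant_only: bool = True) -> None:
    """Export the network as GraphML with edge attributes from the table."""
    graph = nx.Graph()
    rows = edges[edges["significant"]] if significant_only else edges
    for row in rows.itertuples(index=False):
        graph.add_edge(
            row.pathway_a,
            row.pathway_b,
            pathcor=float(row.pathcor),
            p_combined=float(row.p_combined),
            q=float(row.q),
            overlap_coefficient=float(row.overlap_coefficient),
            n_shared=int(row.n_shared),
        )
    nx.write_graphml(graph, path)
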