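import numpy as np
import pandas as pd
import pytest

from pathcor.config import RunConfig
from pathcor.io_formats import GeneSet, GeneSetCollection
from pathcor.meta_aggregation import bh_fdr
from pathcor.network_builder import (
    build_pcxn,
    cluster_pathways,
    enrichment_bin_curve,
    estimate_all_pairs,
    integrate_query,
    top_neighbors,
)
from pathcor.synthetic_data import SyntheticSpec, generate_background, generate_confounded_pair


@pytest.fixture(scope="module")
def planted():
    """Two correlated disjoint modules (rho = 0.8) in a 6 x 25 background."""
    corr = np.array([[1.0, 0.8], [0.8, 1.0]])
    spec = SyntheticSpec(
        n_genes=300,
        experiments=[25] * 6,
        modules=[(0, 30, 1.0), (30, 60, 1.0)],
        module_correlation_matrix=corr,
        noise_sd=1.0,
        seed=42,
    )
    return generate_background(spec)


class TestBuildPcxn:
    def test_planted_correlated_pair_is_significant_edge(self, planted):
        expr, grouping, collection = planted
        edges = build_pcxn(expr, grouping, collection)
        row = edges.iloc[0]
        assert len(edges) == 1
        assert row["significant"]
        assert row["pathcor"] > 0.3
        assert row["n_shared"] == 0

    def test_pair_table_has_choose_two_rows(self, planted):
        expr, grouping, _ = planted
        genes = list(expr.index)
        collection = GeneSetCollection(
            [GeneSet(f"P{i}", "", tuple(genes[60 + 10 * i : 70 + 10 * i])) for i in range(5)]
        )
        edges = build_pcxn(expr, grouping, collection)
        assert len(edges) == 10  # C(5, 2)

    def test_shared_gene_dependence_not_significant_but_raw_is(self):
        from pathcor.correlation import pathcor_disjoint
        from pathcor.rank_summary import rank_transform

        expr, grouping, collection = generate_confounded_pair(seed=9)
        adjusted = build_pcxn(expr, grouping, collection)
        assert not adjusted.iloc[0]["significant"]
        assert adjusted.iloc[0]["overlap_coefficient"] == pytest.approx(0.5)
        # ignoring the shared genes, the same summaries correlate strongly
        ranks = rank_transform(expr)
        raw_p = []
        for exp in grouping.experiments:
            samples = grouping.samples_of(exp)
            e_a = ranks.loc[list(collection["pathway_A"].genes), samples].mean(axis=0)
            e_b = ranks.loc[list(collection["pathway_B"].genes), samples].mean(axis=0)
            est = pathcor_disjoint(e_a.to_numpy(), e_b.to_numpy())
            assert est.r_raw > 0.5
            raw_p.append(est.p)
        assert max(raw_p) < 0.01

    def test_alpha_one_flags_everything(self, planted):
        expr, grouping, collection = planted
        edges = build_pcxn(expr, grouping, collection, RunConfig(alpha=1.0))
        assert edges["significant"].all()


class TestIntegrateQuery:
    def test_signature_tracking_module_a_ranks_it_first(self, planted):
        expr, grouping, collection = planted
        genes = list(expr.index)
        # extra unannotated genes from module 1's block are correlated with it
        signature = GeneSet("sig", "", tuple(genes[0:12]))
        collection = GeneSetCollection(
            [
                GeneSet("module_1", "", tuple(genes[12:30])),
                GeneSet("module_2", "", tuple(genes[30:60])),
                GeneSet("noise", "", tuple(genes[100:130])),
            ]
        )
        table = integrate_query(expr, grouping, collection, signature)
        assert len(table) == 3
        assert table.iloc[0]["neighbor"] == "module_1"
        assert table.iloc[0]["significant"]

    def test_null_signature_at_tiny_alpha_has_no_significant_rows(self, planted):
        expr, grouping, collection = planted
        genes = list(expr.index)
        signature = GeneSet("sig", "", tuple(genes[200:220]))
        table = integrate_query(
            expr, grouping, collection, signature, RunConfig(alpha=1e-9)
        )
        assert not table["significant"].any()

    def test_unmeasured_signature_rejected(self, planted):
        expr, grouping, collection = planted
        with pytest.raises(ValueError, match="measured"):
            integrate_query(expr, grouping, collection, GeneSet("sig", "", ("zz1", "zz2")))

    def test_joint_fdr_never_lowers_pathway_q(self, planted):
        expr, grouping, collection = planted
        genes = list(expr.index)
        base = estimate_all_pairs(expr, grouping, collection)
        base_q = bh_fdr(base["p_combined"].to_numpy())
        joint = estimate_all_pairs(
            expr, grouping, collection,
            extra_sets=GeneSetCollection([GeneSet("sig", "", tuple(genes[200:220]))]),
        )
        joint_q = bh_fdr(joint["p_combined"].to_numpy())
        merged = base.assign(q=base_q).merge(
            joint.assign(q_joint=joint_q), on=["pathway_a", "pathway_b"]
        )
        assert (merged["q_joint"] >= merged["q"] - 1e-12).all()
        assert len(joint) == len(base) + len(collection)


def _edges(rows):
    frame = pd.DataFrame(
        rows, columns=["pathway_a", "pathway_b", "pathcor", "q", "significant"]
    )
    return frame


class TestTopNeighbors:
    def test_k_larger_than_neighbor_count_returns_all(self):
        edges = _edges([["A", "B", 0.9, 0.01, True], ["A", "C", 0.5, 0.01, True]])
        assert len(top_neighbors(edges, "A", k=10)) == 2

    def test_equal_magnitude_breaks_ties_lexicographically(self):
        edges = _edges(
            [["A", "C", 0.5, 0.01, True], ["A", "B", -0.5, 0.01, True]]
        )
        result = top_neighbors(edges, "A", k=1)
        assert result.iloc[0]["neighbor"] == "B"

    def test_matches_sort_oracle(self, rng):
        rows = [
            ["A", f"N{i}", float(rng.uniform(-1, 1)), float(rng.uniform()), True]
            for i in range(12)
        ]
        edges = _edges(rows)
        result = top_neighbors(edges, "A", k=5)
        expected = sorted(rows, key=lambda r: -abs(r[2]))[:5]
        assert result["neighbor"].tolist() == [r[1] for r in expected]

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            top_neighbors(_edges([["A", "B", 0.5, 0.01, True]]), "Z")

    def test_non_significant_edges_excluded(self):
        edges = _edges([["A", "B", 0.9, 0.5, False], ["A", "C", 0.2, 0.01, True]])
        assert top_neighbors(edges, "A")["neighbor"].tolist() == ["C"]


def average_linkage_oracle(dist):
    """Naive agglomerative average linkage over a dense distance matrix."""
    clusters = {i: [i] for i in range(len(dist))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return heights


class TestClusterPathways:
    def test_two_nodes_single_merge_at_distance(self):
        edges = _edges([["A", "B", 0.7, 0.01, True]])
        linkage, order = cluster_pathways(edges)
        assert linkage.shape == (1, 4)
        assert linkage[0, 2] == pytest.approx(0.3)
        assert set(order) == {"A", "B"}

    def test_closest_pair_merges_first(self):
        edges = _edges(
            [
                ["A", "B", 0.9, 0.01, True],   # distance 0.1
                ["A", "C", 0.1, 0.5, False],   # distance 0.9
                ["B", "C", 0.1, 0.5, False],
            ]
        )
        linkage, _ = cluster_pathways(edges)
        assert linkage[0, 2] == pytest.approx(0.1)
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}  # A and B

    def test_merge_heights_match_average_linkage_oracle(self, rng):
        nodes = [f"P{i}" for i in range(6)]
        rows = []
        for i in range(6):
            for j in range(i + 1, 6):
                rows.append([nodes[i], nodes[j], float(rng.uniform(-1, 1)), 0.01, True])
        edges = _edges(rows)
        linkage, _ = cluster_pathways(edges, nodes)
        dist = np.ones((6, 6)) - np.eye(6)
        for a, b, pc, *_ in rows:
            i, j = nodes.index(a), nodes.index(b)
            dist[i, j] = dist[j, i] = 1 - abs(pc)
        np.testing.assert_allclose(linkage[:, 2], average_linkage_oracle(dist), atol=1e-12)

    def test_missing_pairs_default_to_distance_one(self):
        edges = _edges([["A", "B", 0.9, 0.01, True]])
        linkage, _ = cluster_pathways(edges, ["A", "B", "C"])
        assert linkage[-1, 2] == pytest.approx(1.0)


class TestEnrichmentBinCurve:
    def test_all_flagged_gives_ones(self):
        ranked = [f"p{i}" for i in range(30)]
        assert all(v == 1.0 for _, v in enrichment_bin_curve(ranked, set(ranked)))

    def test_none_flagged_gives_zeros(self):
        ranked = [f"p{i}" for i in range(30)]
        assert all(v == 0.0 for _, v in enrichment_bin_curve(ranked, set()))

    def test_hand_counted_bins_of_25_elements(self):
        ranked = [f"p{i}" for i in range(25)]
        flagged = {f"p{i}" for i in range(0, 25, 2)}  # 13 even-indexed
        curve = enrichment_bin_curve(ranked, flagged, bin_step=10)
        assert [s for s, _ in curve] == [10, 20, 25]
        assert curve[0][1] == pytest.approx(5 / 10)
        assert curve[1][1] == pytest.approx(10 / 20)
        assert curve[2][1] == pytest.approx(13 / 25)
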