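import numpy as np
import pandas as pd
import pytest

from tegrn.screening_network import (
    EdgeList,
    TEMatrix,
    all_pairs_te,
    build_network,
    one_way_screen,
    pair_count,
    pvalue_screen,
    read_edge_tsv,
    read_sif,
    strongest_per_source,
    strongest_per_target,
    te_threshold_screen,
    write_edge_tsv,
    write_sif,
)
from tegrn.significance import derive_pair_seed, permutation_pvalue


def make_te_matrix(entries, genes):
    df = pd.DataFrame(entries, columns=["source", "target", "te", "p_value"])
    return TEMatrix(df, genes)


def random_te_matrix(genes, seed=0):
    rng = np.random.default_rng(seed)
    rows = [
        (a, b, float(rng.random()), float(rng.random()))
        for a in genes
        for b in genes
        if a != b
    ]
    return make_te_matrix(rows, list(genes))


class TestPairCount:
    @pytest.mark.parametrize("n, expected", [(124, 15252), (2, 2), (10, 90)])
    def test_ordered_pair_formula(self, n, expected):
        assert pair_count(n) == expected

    def test_rejects_single_gene(self):
        with pytest.raises(ValueError):
            pair_count(1)


class TestAllPairsTE:
    def test_three_gene_matrix_has_six_entries(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(3, 40)), index=["a", "b", "c"])
        tm = all_pairs_te(m, n_permutations=10, master_seed=1)
        assert len(tm.entries) == 6

    def test_entries_reproducible_standalone(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(4, 60)), index=["a", "b", "c", "d"])
        tm = all_pairs_te(m, n_permutations=25, master_seed=5)
        lookup = tm.entries.set_index(["source", "target"])
        for src, tgt in [("a", "b"), ("d", "c"), ("b", "d")]:
            res = permutation_pvalue(
                m.loc[src].to_numpy(),
                m.loc[tgt].to_numpy(),
                n_permutations=25,
                seed=derive_pair_seed(5, src, tgt),
            )
            assert lookup.loc[(src, tgt), "te"] == pytest.approx(res.observed_te)
            assert lookup.loc[(src, tgt), "p_value"] == pytest.approx(res.p_value)

    def test_copied_gene_gives_symmetric_te(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=50)
        m = pd.DataFrame({"A": a, "B": a.copy()}).T
        tm = all_pairs_te(m, n_permutations=5, master_seed=0)
        lookup = tm.entries.set_index(["source", "target"])
        assert lookup.loc[("A", "B"), "te"] == pytest.approx(lookup.loc[("B", "A"), "te"])

    def test_self_pairs_and_wrong_counts_rejected(self):
        with pytest.raises(ValueError):
            make_te_matrix([("a", "a", 0.1, 0.5), ("a", "b", 0.1, 0.5)], ["a", "b"])
        with pytest.raises(ValueError):
            make_te_matrix([("a", "b", 0.1, 0.5)], ["a", "b"])


class TestOneWayScreen:
    def test_keeps_stronger_direction(self):
        tm = make_te_matrix(
            [("a", "b", 0.8, 0.01), ("b", "a", 0.2, 0.5)], ["a", "b"]
        )
        edges = one_way_screen(tm)
        assert edges.pairs() == {("a", "b")}

    def test_exact_tie_broken_lexicographically(self):
        tm = make_te_matrix(
            [("gB", "gA", 0.4, 0.1), ("gA", "gB", 0.4, 0.2)], ["gA", "gB"]
        )
        edges = one_way_screen(tm)
        assert edges.pairs() == {("gA", "gB")}

    def test_output_size_is_half_the_ordered_pairs(self):
        genes = [f"g{i}" for i in range(8)]
        edges = one_way_screen(random_te_matrix(genes, seed=3))
        assert len(edges) == pair_count(8) // 2


class TestThresholdScreens:
    def test_pvalue_screen_is_strict(self):
        edges = EdgeList(
            pd.DataFrame(
                [("a", "b", 0.5, 0.001), ("a", "c", 0.5, 0.0009)],
                columns=["source", "target", "te", "p_value"],
            )
        )
        kept = pvalue_screen(edges, alpha=0.001)
        assert kept.pairs() == {("a", "c")}

    def test_all_p_one_empties_list(self):
        edges = EdgeList(
            pd.DataFrame(
                [("a", "b", 0.5, 1.0), ("b", "c", 0.9, 1.0)],
                columns=["source", "target", "te", "p_value"],
            )
        )
        assert len(pvalue_screen(edges)) == 0

    def test_te_screen_is_inclusive(self):
        edges = EdgeList(
            pd.DataFrame(
                [("a", "b", 0.5, 0.0), ("a", "c", 0.49, 0.0), ("b", "c", 0.7, 0.0)],
                columns=["source", "target", "te", "p_value"],
            )
        )
        kept = te_threshold_screen(edges, min_te=0.5)
        assert kept.pairs() == {("a", "b"), ("b", "c")}

    def test_manual_filter_counts(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"s{i}", f"t{i}", float(rng.random()), float(rng.random())) for i in range(10)
        ]
        edges = EdgeList(pd.DataFrame(rows, columns=["source", "target", "te", "p_value"]))
        alpha, min_te = 0.4, 0.5
        assert len(pvalue_screen(edges, alpha)) == sum(r[3] < alpha for r in rows)
        assert len(te_threshold_screen(edges, min_te)) == sum(r[2] >= min_te for r in rows)


class TestStrongestEdges:
    def cascade_edges(self):
        rows = [
            ("a", "b", 0.6, 0.0),
            ("a", "c", 0.9, 0.0),
            ("b", "c", 0.3, 0.0),
            ("c", "d", 0.7, 0.0),
            ("e", "d", 0.7, 0.0),
        ]
        return EdgeList(pd.DataFrame(rows, columns=["source", "target", "te", "p_value"]))

    def test_per_source_argmax(self):
        kept = strongest_per_source(self.cascade_edges())
        assert kept.pairs() == {("a", "c"), ("b", "c"), ("c", "d"), ("e", "d")}

    def test_per_target_argmax_with_lexicographic_tie(self):
        kept = strongest_per_target(self.cascade_edges())
        # d receives 0.7 from both c and e: lexicographic keeps c->d
        assert kept.pairs() == {("a", "c"), ("a", "b"), ("c", "d")}

    def test_matches_exhaustive_per_group_max(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(6)]
        edges = one_way_screen(random_te_matrix(genes, seed=6))
        kept = strongest_per_source(edges)
        df = edges.edges
        for src, group in df.groupby("source"):
            best = group.sort_values(["te", "target"], ascending=[False, True]).iloc[0]
            row = kept.edges[kept.edges["source"] == src]
            assert len(row) == 1
            assert row.iloc[0]["target"] == best["target"]

    def test_empty_input_passes_through(self):
        empty = EdgeList(pd.DataFrame(columns=["source", "target", "te", "p_value"]))
        assert len(strongest_per_source(empty)) == 0
        assert len(strongest_per_target(empty)) == 0


class TestCascadeMonotonicity:
    def test_each_stage_subsets_its_input(self):
        tm = random_te_matrix([f"g{i}" for i in range(7)], seed=8)
        one_way = one_way_screen(tm)
        sig = pvalue_screen(one_way, alpha=0.5)
        strong = te_threshold_screen(sig, min_te=0.3)
        out = strongest_per_source(strong)
        inc = strongest_per_target(strong)
        assert sig.pairs() <= one_way.pairs()
        assert strong.pairs() <= sig.pairs()
        assert out.pairs() <= strong.pairs()
        assert inc.pairs() <= strong.pairs()


class TestNetworkExport:
    def test_empty_edge_list_round_trip(self, tmp_path):
        empty = EdgeList(pd.DataFrame(columns=["source", "target", "te", "p_value"]))
        graph = build_network(empty, sif_path=tmp_path / "e.sif", tsv_path=tmp_path / "e.tsv")
        assert graph.number_of_nodes() == 0
        assert read_sif(tmp_path / "e.sif") == set()
        assert len(read_edge_tsv(tmp_path / "e.tsv")) == 0

    def test_chain_graph(self):
        rows = [("A", "B", 0.5, 0.0), ("B", "C", 0.5, 0.0), ("A", "C", 0.5, 0.0)]
        edges = EdgeList(pd.DataFrame(rows, columns=["source", "target", "te", "p_value"]))
        graph = build_network(edges)
        assert graph.number_of_nodes() == 3 and graph.number_of_edges() == 3

    def test_sif_and_tsv_round_trip(self, tmp_path):
        edges = one_way_screen(random_te_matrix(["x", "y", "z"], seed=9))
        write_sif(edges, tmp_path / "n.sif")
        write_edge_tsv(edges, tmp_path / "n.tsv")
        assert read_sif(tmp_path / "n.sif") == edges.pairs()
        back = read_edge_tsv(tmp_path / "n.tsv")
        pd.testing.assert_frame_equal(back.edges, edges.edges)
        assert back.stage == edges.stage
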