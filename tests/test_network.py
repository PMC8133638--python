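import networkx as nx
import numpy as np
import pandas as pd
import pytest

from seedcoex import (
    OrthologTable,
    SeedGeneSet,
    build_network,
    collapse_orthologs,
    compute_kphq,
    export_network,
    extract_candidates,
    gcc_pairwise,
    gcc_seed_profile,
    import_network,
)
from seedcoex.network import ConnectivityTable


def make_profile(seed_values: dict[str, dict[str, float]]):
    """GCCProfile stub from a seed -> {gene: gcc_sym} mapping."""
    from seedcoex import GCCProfile

    seeds = list(seed_values)
    genes = sorted({g for d in seed_values.values() for g in d})
    sym = pd.DataFrame(
        [[seed_values[s].get(g, 0.0) for g in genes] for s in seeds], index=seeds, columns=genes
    )
    return GCCProfile(seeds, genes, sym.copy(), sym.copy(), sym)


class TestExtractCandidates:
    def test_top_k_keeps_largest_signed_values(self):
        vals = {"s": {"s": 1.0, "g1": 0.9, "g2": -0.95, "g3": 0.5, "g4": 0.7, "g5": 0.1}}
        cand = extract_candidates(make_profile(vals), mode="top_k", k=3)
        assert [g for g, _ in cand.per_seed["s"]] == ["g1", "g4", "g3"]

    def test_absolute_mode_ranks_by_magnitude(self):
        vals = {"s": {"s": 1.0, "g1": 0.9, "g2": -0.95, "g3": 0.5}}
        cand = extract_candidates(make_profile(vals), mode="top_k", k=2, use_abs=True)
        assert [g for g, _ in cand.per_seed["s"]] == ["g2", "g1"]

    def test_self_pair_excluded(self):
        vals = {"s": {"s": 1.0, "g1": 0.2}}
        cand = extract_candidates(make_profile(vals), mode="top_k", k=5)
        assert all(g != "s" for g, _ in cand.per_seed["s"])

    def test_other_seeds_are_rankable_targets(self):
        vals = {
            "s1": {"s1": 1.0, "s2": 0.9, "g1": 0.5},
            "s2": {"s1": 0.9, "s2": 1.0, "g1": 0.4},
        }
        cand = extract_candidates(make_profile(vals), mode="top_k", k=1)
        assert cand.per_seed["s1"][0][0] == "s2"

    def test_threshold_mode_matches_linear_scan(self, rng):
        genes = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(-1, 1, size=200))}
        genes["g_edge"] = 0.8  # boundary inclusive
        vals = {"s": {**genes, "s": 1.0}}
        cand = extract_candidates(make_profile(vals), mode="threshold", min_gcc=0.8)
        expected = {g for g, v in genes.items() if v >= 0.8}
        assert {g for g, _ in cand.per_seed["s"]} == expected
        assert "g_edge" in {g for g, _ in cand.per_seed["s"]}

    def test_union_of_identical_lists_is_one_list(self):
        shared = {"g1": 0.9, "g2": 0.8, "g3": 0.7}
        vals = {"s1": {**shared, "s1": 1.0}, "s2": {**shared, "s2": 1.0}}
        cand = extract_candidates(make_profile(vals), mode="top_k", k=3)
        assert cand.union == {"g1", "g2", "g3"}

    def test_ties_break_lexicographically(self):
        vals = {"s": {"s": 1.0, "gb": 0.5, "ga": 0.5, "gc": 0.9}}
        cand = extract_candidates(make_profile(vals), mode="top_k", k=3)
        assert [g for g, _ in cand.per_seed["s"]] == ["gc", "ga", "gb"]

    def test_top_k_invariant_under_increasing_transform(self, rng):
        genes = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(-1, 1, size=50))}
        vals = {"s": {**genes, "s": 1.0}}
        base = extract_candidates(make_profile(vals), mode="top_k", k=10)
        warped = {"s": {g: np.tanh(3 * v) for g, v in vals["s"].items()}}
        again = extract_candidates(make_profile(warped), mode="top_k", k=10)
        assert [g for g, _ in base.per_seed["s"]] == [g for g, _ in again.per_seed["s"]]

    @pytest.mark.parametrize("kwargs", [{"mode": "top_k", "k": 0}, {"mode": "threshold", "min_gcc": 1.5}, {"mode": "bogus"}])
    def test_bad_config_rejected(self, kwargs):
        vals = {"s": {"s": 1.0, "g1": 0.5}}
        with pytest.raises(ValueError):
            extract_candidates(make_profile(vals), **kwargs)


class TestBuildNetwork:
    def test_threshold_semantics_at_cutoff(self, small_synthetic):
        from seedcoex import ExpressionMatrix

        # three constructed genes with known pairwise gcc: use direct pairwise
        matrix, _ = small_synthetic
        genes = matrix.gene_ids[:20]
        pw = gcc_pairwise(matrix, genes)
        net = build_network(matrix, genes, cutoff=0.6, pairwise=pw, drop_isolated=False)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                assert net.has_edge(a, b) == (pw.at[a, b] >= 0.6)

    def test_boundary_inclusive_and_exclusive(self):
        genes = ["a", "b", "c"]
        pw = pd.DataFrame(
            [[1.0, 0.9, 0.61], [0.9, 1.0, 0.59], [0.61, 0.59, 1.0]], index=genes, columns=genes
        )
        net = build_network(None, genes, cutoff=0.6, pairwise=pw, drop_isolated=False)
        assert set(map(frozenset, net.edges)) == {frozenset({"a", "b"}), frozenset({"a", "c"})}

    def test_all_below_cutoff_gives_empty_network(self):
        genes = ["a", "b"]
        pw = pd.DataFrame([[1.0, 0.1], [0.1, 1.0]], index=genes, columns=genes)
        net = build_network(None, genes, cutoff=0.6, pairwise=pw)
        assert net.number_of_edges() == 0

    def test_matches_brute_force_thresholding(self, small_synthetic):
        matrix, truth = small_synthetic
        rng = np.random.default_rng(11)
        genes = list(rng.choice(matrix.gene_ids[:150], size=50, replace=False))
        pw = gcc_pairwise(matrix, genes)
        net = build_network(matrix, genes, cutoff=0.6, pairwise=pw, drop_isolated=False)
        expected = set()
        for i in range(len(genes)):  # independent double loop
            for j in range(i + 1, len(genes)):
                if pw.iat[i, j] >= 0.6:
                    expected.add(frozenset({genes[i], genes[j]}))
        assert set(map(frozenset, net.edges)) == expected

    def test_isolated_nodes_dropped(self):
        genes = ["a", "b", "c"]
        pw = pd.DataFrame(
            [[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]], index=genes, columns=genes
        )
        net = build_network(None, genes, cutoff=0.6, pairwise=pw)
        assert set(net.nodes) == {"a", "b"}

    def test_missing_node_raises(self, small_matrix):
        with pytest.raises(KeyError, match="zz"):
            build_network(small_matrix, ["a", "zz"])

    def test_raising_cutoff_never_adds_edges_or_kphq(self, small_synthetic):
        matrix, truth = small_synthetic
        seeds = SeedGeneSet(truth.seeds)
        genes = sorted(set(matrix.gene_ids[:80]) | set(truth.seeds))
        pw = gcc_pairwise(matrix, genes)
        prev_edges, prev_k = None, None
        for cutoff in (0.4, 0.6, 0.8):
            net = build_network(matrix, genes, seeds=seeds, cutoff=cutoff, pairwise=pw, drop_isolated=False)
            conn = compute_kphq(net, seeds)
            k = conn.table.set_index("node").k_phq
            if prev_edges is not None:
                assert net.number_of_edges() <= prev_edges
                assert (k <= prev_k).all()
            prev_edges, prev_k = net.number_of_edges(), k


class TestComputeKphq:
    def test_star_graph_fractions(self):
        net = nx.Graph()
        seeds = SeedGeneSet(["hub"])
        net.add_node("hub", role="seed")
        for i in range(5):
            net.add_node(f"c{i}", role="candidate")
            net.add_edge("hub", f"c{i}", weight=0.9)
        conn = compute_kphq(net, seeds)
        assert all(conn.k_of(f"c{i}") == 1 for i in range(5))
        assert conn.fraction_at_least(1, "all") == pytest.approx(5 / 6)
        assert conn.fraction_at_least(1, "nonseed") == pytest.approx(1.0)

    def test_hand_built_graph_matches_golden_table(self, data_dir):
        edges = pd.read_csv(data_dir / "toy_network_edges.tsv", sep="\t")
        net = nx.Graph()
        seeds = SeedGeneSet(["S1", "S2", "S3"])
        for _, row in edges.iterrows():
            for n in (row.node_a, row.node_b):
                net.add_node(n, role="seed" if n in seeds.seeds else "candidate")
            net.add_edge(row.node_a, row.node_b, weight=1.0)
        conn = compute_kphq(net, seeds)
        golden = pd.read_csv(data_dir / "toy_kphq_golden.tsv", sep="\t")
        pd.testing.assert_frame_equal(conn.table, golden)

    def test_no_seed_edges_means_zero_kphq(self):
        net = nx.Graph()
        net.add_node("s", role="seed")
        net.add_edge("c1", "c2", weight=0.8)
        conn = compute_kphq(net, SeedGeneSet(["s"]))
        assert conn.k_of("c1") == 0 and conn.k_of("c2") == 0

    def test_nonseed_kphq_sum_equals_seed_nonseed_edges(self, small_synthetic):
        matrix, truth = small_synthetic
        seeds = SeedGeneSet(truth.seeds)
        genes = sorted(set(matrix.gene_ids[:100]) | set(truth.seeds))
        net = build_network(matrix, genes, seeds=seeds, cutoff=0.6)
        conn = compute_kphq(net, seeds)
        seed_set = set(truth.seeds)
        cross = sum(1 for a, b in net.edges if (a in seed_set) != (b in seed_set))
        nonseed_sum = conn.table[conn.table.role != "seed"].k_phq.sum()
        assert nonseed_sum == cross

    def test_kphq_bounded_by_seed_count(self, small_synthetic):
        matrix, truth = small_synthetic
        seeds = SeedGeneSet(truth.seeds)
        genes = sorted(set(matrix.gene_ids[:100]) | set(truth.seeds))
        net = build_network(matrix, genes, seeds=seeds, cutoff=0.5)
        conn = compute_kphq(net, seeds)
        assert (conn.table.k_phq <= len(seeds.seeds)).all()
        assert (conn.table.k_phq >= 0).all()

    def test_band_fraction(self):
        table = pd.DataFrame(
            {"node": list("abcde"), "role": ["candidate"] * 5, "k_phq": [0, 2, 4, 5, 6]}
        )
        ct = ConnectivityTable(table, n_seeds=7)
        assert ct.fraction_band(4, 6) == pytest.approx(3 / 5)


class TestCollapseOrthologs:
    def make_table(self, rows):
        return OrthologTable(pd.DataFrame(rows, columns=["species", "gene", "orthogroup"]))

    def test_one_representative_per_group_per_species(self):
        table = self.make_table(
            [["A", "a1", "OG1"], ["B", "b2", "OG1"], ["B", "b1", "OG1"]]
        )
        out, presence = collapse_orthologs({"A": {"a1"}, "B": set()}, table)
        assert out["B"] == {"b1"}  # lexicographically smallest representative
        assert out["A"] == {"a1"}
        assert presence.loc["OG1"].all()

    def test_unassigned_gene_survives_as_singleton(self):
        table = self.make_table([["A", "a1", "OG1"]])
        out, presence = collapse_orthologs({"A": {"a1", "orphan"}}, table)
        assert "orphan" in out["A"]
        assert presence.loc["singleton:orphan", "A"]

    def test_expansion_restricted_to_transcriptome(self):
        table = self.make_table(
            [["A", "a1", "OG1"], ["B", "b1", "OG1"], ["B", "b2", "OG2"], ["A", "a2", "OG2"]]
        )
        out, _ = collapse_orthologs(
            {"A": {"a1"}, "B": {"b2"}},
            table,
            transcriptomes={"A": {"a1"}, "B": {"b1", "b2"}},
        )
        # OG2 hit via B expands to A, but a2 is not in A's filtered transcriptome
        assert out["A"] == {"a1"}
        assert out["B"] == {"b1", "b2"}

    def test_three_species_fixture_matches_hand_computation(self):
        # 3 species, 10 orthogroups OG0..OG9; species sets hit OG0-2 (A),
        # OG2-4 (B), OG5 (C). Expanded union of hit groups: OG0..OG5.
        rows = []
        for og in range(10):
            for sp, prefix in (("A", "a"), ("B", "b"), ("C", "c")):
                rows.append([sp, f"{prefix}{og}", f"OG{og}"])
                rows.append([sp, f"{prefix}{og}x", f"OG{og}"])  # two members each
        table = self.make_table(rows)
        sets = {"A": {"a0", "a1", "a2"}, "B": {"b2", "b3", "b4"}, "C": {"c5"}}
        out, presence = collapse_orthologs(sets, table)
        # hand computation: every species gets one representative for OG0..OG5
        for sp, prefix in (("A", "a"), ("B", "b"), ("C", "c")):
            assert out[sp] == {f"{prefix}{og}" for og in range(6)}
        assert presence.shape == (6, 3)
        assert presence.to_numpy().all()


class TestExportImport:
    @pytest.fixture
    def net(self):
        g = nx.Graph()
        g.add_node("a", role="seed")
        g.add_node("b", role="candidate")
        g.add_node("c", role="candidate")
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("a", "c", weight=0.7)
        g.add_edge("b", "c", weight=0.61)
        return g

    @pytest.mark.parametrize("fmt,ext", [("graphml", "graphml"), ("edge_tsv", "tsv")])
    def test_lossless_round_trip(self, net, tmp_path, fmt, ext):
        p = tmp_path / f"net.{ext}"
        export_network(net, p, format=fmt)
        again = import_network(p, format=fmt)
        assert set(again.nodes) == set(net.nodes)
        assert set(map(frozenset, again.edges)) == set(map(frozenset, net.edges))
        for n in net.nodes:
            assert again.nodes[n]["role"] == net.nodes[n]["role"]
        for a, b in net.edges:
            assert float(again.edges[a, b]["weight"]) == pytest.approx(net.edges[a, b]["weight"])

    def test_sif_matches_golden_file(self, net, tmp_path, data_dir):
        p = tmp_path / "net.sif"
        export_network(net, p, format="sif")
        assert p.read_text() == (data_dir / "toy_network_golden.sif").read_text()

    def test_empty_graph_is_valid_document(self, tmp_path):
        g = nx.Graph()
        p = tmp_path / "empty.graphml"
        export_network(g, p, format="graphml")
        assert import_network(p).number_of_nodes() == 0
        p2 = tmp_path / "empty.sif"
        export_network(g, p2, format="sif")
        assert p2.read_text() == ""

    def test_unknown_format_rejected(self, net, tmp_path):
        with pytest.raises(ValueError, match="unknown network format"):
            export_network(net, tmp_path / "x", format="dot")
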