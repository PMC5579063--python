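"""Functional-network construction, matrix similarity, centrality nulls,
and localization."""

import itertools

import networkx as nx
import numpy as np
import pytest

from drugfams.core import DrugProfile, FamilyTable, ParseError
from drugfams.network import (
    FunctionalNetwork,
    betweenness_analysis,
    drug_neighbourhood_table,
    family_neighbourhood,
    localization,
    matrix_similarity,
    read_network,
)


def net_from(edges):
    return FunctionalNetwork(edges)


class TestReadNetwork:
    def test_string1000_scale(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\na\tb\t800\n")
        net = read_network(path, score_scale="string1000")
        assert net.score("a", "b") == pytest.approx(0.8)

    def test_duplicate_symmetric_rows_collapse(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text(
            "protein1\tprotein2\tcombined_score\na\tb\t0.7\nb\ta\t0.7\n"
        )
        net = read_network(path)
        assert net.graph.number_of_edges() == 1

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text(
            "protein1\tprotein2\tcombined_score\na\tb\t0.7\nb\ta\t0.9\n"
        )
        with pytest.raises(ParseError, match="conflicting"):
            read_network(path)

    def test_five_edge_fixture_adjacency(self, tmp_path):
        edges = [("a", "b", 0.9), ("a", "c", 0.5), ("b", "c", 0.85),
                 ("c", "d", 0.3), ("d", "e", 1.0)]
        path = tmp_path / "net.tsv"
        path.write_text(
            "protein1\tprotein2\tcombined_score\n"
            + "".join(f"{u}\t{v}\t{w}\n" for u, v, w in edges)
        )
        net = read_network(path)
        assert net.graph.number_of_edges() == 5
        for u, v, w in edges:
            assert net.score(u, v) == pytest.approx(w)
            assert net.score(v, u) == pytest.approx(w)
        assert net.score("a", "e") == 0.0  # absent pair
        # thresholded view keeps only high-confidence edges
        assert set(net.thresholded(0.8).edges) == {("a", "b"), ("b", "c"), ("d", "e")}

    def test_zero_scores_dropped(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\na\tb\t0\nb\tc\t0.5\n")
        assert read_network(path).graph.number_of_edges() == 1


class TestMatrixSimilarity:
    def test_single_pair_equals_edge_weight(self):
        net = net_from([("i", "j", 0.7)])
        assert matrix_similarity({"i", "j"}, net).value == pytest.approx(0.7)

    def test_no_edges_is_zero(self):
        net = net_from([("a", "x", 0.5)])  # a,b,c pairwise unconnected
        score = matrix_similarity({"a", "b", "c"}, net, restrict_to_network=False)
        assert score.value == 0.0

    def test_hand_sum_four_proteins(self):
        # edges 0.8 and 0.6 among the 6 pairs -> mean (0.8+0.6)/6 = 7/30
        net = net_from([("a", "b", 0.8), ("c", "d", 0.6)])
        score = matrix_similarity({"a", "b", "c", "d"}, net)
        assert score.value == pytest.approx(7 / 30)

    def test_permutation_invariance_and_bounds(self):
        rng = np.random.default_rng(21)
        nodes = [f"n{i}" for i in range(8)]
        edges = [(u, v, float(rng.uniform(0.1, 1.0)))
                 for u, v in itertools.combinations(nodes, 2) if rng.random() < 0.4]
        net = net_from(edges)
        vals = {
            matrix_similarity(perm, net).value
            for perm in [nodes, nodes[::-1], sorted(nodes, key=hash)]
        }
        assert len(vals) == 1
        assert 0.0 <= vals.pop() <= 1.0

    def test_constant_complete_graph(self):
        nodes = [f"n{i}" for i in range(5)]
        net = net_from([(u, v, 0.42) for u, v in itertools.combinations(nodes, 2)])
        for k in (2, 3, 5):
            s = matrix_similarity(nodes[:k], net)
            assert s.value == pytest.approx(0.42)
            s_med = matrix_similarity(nodes[:k], net, kind="median_pairwise")
            assert s_med.value == pytest.approx(0.42)

    def test_adding_member_edge_never_decreases_mean(self):
        base = [("a", "b", 0.5), ("c", "d", 0.2)]
        before = matrix_similarity({"a", "b", "c", "d"}, net_from(base)).value
        after = matrix_similarity(
            {"a", "b", "c", "d"}, net_from(base + [("a", "c", 0.3)])
        ).value
        assert after >= before

    def test_small_sets_missing(self):
        net = net_from([("a", "b", 0.5)])
        assert matrix_similarity({"a"}, net).value is None
        assert matrix_similarity({"x", "y"}, net).value is None  # off-network


class TestBetweenness:
    def test_star_center_exceeds_leaves(self):
        edges = [("hub", f"leaf{i}", 0.9) for i in range(6)]
        net = net_from(edges)
        hub = betweenness_analysis(["hub"], net, n_random=100, seed=1)
        leaves = betweenness_analysis(["leaf0", "leaf1"], net, n_random=100, seed=1)
        assert hub.observed > leaves.observed
        assert leaves.observed == 0.0

    def test_path_graph_hand_enumeration(self):
        # a-b-c: only the (a, c) shortest path passes through b;
        # normalized by (n-1)(n-2)/2 = 1 -> betweenness(b) = 1
        net = net_from([("a", "b", 0.9), ("b", "c", 0.9)])
        res = betweenness_analysis(["b"], net, n_random=50, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_matches_exhaustive_shortest_path_oracle(self):
        """On random graphs of <= 8 nodes, mean normalized betweenness of a
        set equals a from-scratch all-pairs shortest-path count."""
        rng = np.random.default_rng(22)
        for trial in range(5):
            n = int(rng.integers(4, 9))
            nodes = [f"n{i}" for i in range(n)]
            edges = [(u, v, 0.95) for u, v in itertools.combinations(nodes, 2)
                     if rng.random() < 0.45]
            if not edges:
                continue
            net = net_from(edges)
            g = net.thresholded(0.8)

            # oracle: enumerate all shortest paths via BFS predecessor counts
            def count_through(node):
                total = 0.0
                others = [x for x in g.nodes if x != node]
                for s, t in itertools.combinations(others, 2):
                    try:
                        paths = list(nx.all_shortest_paths(g, s, t))
                    except nx.NetworkXNoPath:
                        continue
                    total += sum(node in p[1:-1] for p in paths) / len(paths)
                return total / ((len(g.nodes) - 1) * (len(g.nodes) - 2) / 2)

            query = [nodes[i] for i in rng.choice(n, size=2, replace=False)]
            res = betweenness_analysis(query, net, n_random=10, seed=3)
            oracle = np.mean([count_through(q) for q in query])
            assert res.observed == pytest.approx(oracle, abs=1e-12)

    def test_empirical_p_floor_and_reproducibility(self):
        edges = [(f"a{i}", f"a{j}", 0.9) for i in range(8) for j in range(i + 1, 8)]
        net = net_from(edges)
        r1 = betweenness_analysis(["a0", "a1"], net, n_random=99, seed=5)
        r2 = betweenness_analysis(["a0", "a1"], net, n_random=99, seed=5)
        assert r1.empirical_p == r2.empirical_p
        assert r1.empirical_p >= 1 / 100

    def test_query_outside_graph_rejected(self):
        net = net_from([("a", "b", 0.9)])
        with pytest.raises(ValueError):
            betweenness_analysis(["zzz"], net, n_random=10, seed=0)

    def test_planted_hub_targets_are_central(self, world, profiles):
        all_targets = sorted(
            {p for pr in profiles.values() for p in pr.targets} & world.network.nodes
        )
        res = betweenness_analysis(all_targets, world.network, n_random=200, seed=9)
        assert res.empirical_p <= 0.05


class TestDrugNeighbourhoods:
    def test_planted_ordering(self, world, profiles):
        df = drug_neighbourhood_table(profiles, world.network, n_random=1, seed=2)
        assert df["target_score"].median() > df["off_target_score"].median()
        assert df["off_target_score"].median() > df["random_score"].median()

    def test_deterministic_under_seed(self, world, profiles):
        a = drug_neighbourhood_table(profiles, world.network, n_random=2, seed=42)
        b = drug_neighbourhood_table(profiles, world.network, n_random=2, seed=42)
        assert a.equals(b)

    def test_constant_weight_complete_graph(self):
        nodes = [f"n{i}" for i in range(6)]
        net = net_from([(u, v, 0.3) for u, v in itertools.combinations(nodes, 2)])
        prof = DrugProfile("d", frozenset(nodes[:3]), frozenset(nodes[3:5]),
                           frozenset())
        df = drug_neighbourhood_table({"d": prof}, net, n_random=3, seed=0)
        row = df.iloc[0]
        assert row["target_score"] == pytest.approx(0.3)
        assert row["off_target_score"] == pytest.approx(0.3)
        assert row["random_score"] == pytest.approx(0.3)


class TestFamilyNeighbourhood:
    def test_planted_module_all_weights_one(self):
        members = [f"m{i}" for i in range(4)]
        net = net_from([(u, v, 1.0) for u, v in itertools.combinations(members, 2)])
        table = FamilyTable(families={"M": frozenset(members)})
        df, _ = family_neighbourhood(table, net)
        assert df.loc[df.family_id == "M", "score"].iloc[0] == pytest.approx(1.0)

    def test_druggable_vs_scattered_contrast(self, world, profiles):
        from drugfams.enrichment import run_enrichment

        _, druggable = run_enrichment(profiles, world.family_table)
        df, comp = family_neighbourhood(world.family_table, world.network,
                                        druggable=druggable)
        assert comp["median_druggable"] > comp["median_rest"]
        assert comp["p_value"] < 0.01

    def test_identical_groups_p_near_one(self):
        nodes = [f"n{i}" for i in range(12)]
        net = net_from([(u, v, 0.5) for u, v in itertools.combinations(nodes, 2)])
        fams = {f"F{i}": frozenset(nodes[i * 3:(i + 1) * 3]) for i in range(4)}
        table = FamilyTable(families=fams)
        _, comp = family_neighbourhood(table, net, druggable={"F0", "F1"})
        assert comp["p_value"] > 0.9  # all scores equal -> exchangeable

    def test_empty_group_rejected(self):
        nodes = ["a", "b", "c"]
        net = net_from([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)])
        table = FamilyTable(families={"F": frozenset(nodes)})
        with pytest.raises(ValueError):
            family_neighbourhood(table, net, druggable=set())


class TestLocalization:
    def test_clique_subset_distance_one(self):
        nodes = [f"n{i}" for i in range(6)]
        net = net_from([(u, v, 0.9) for u, v in itertools.combinations(nodes, 2)])
        res = localization(nodes[:4], net, n_random=20, seed=0)
        assert res.d_observed == pytest.approx(1.0)

    def test_disconnected_members_get_finite_penalty(self):
        # two separate high-confidence edges; members of different
        # components are unreachable from each other
        net = net_from([("a", "b", 0.9), ("c", "d", 0.9), ("a", "c", 0.1)])
        res = localization(["a", "c"], net, n_random=10, seed=0)
        assert np.isfinite(res.d_observed)
        assert res.n_disconnected == 2

    def test_planted_module_localized(self, world):
        rng = np.random.default_rng(30)
        mods = sorted(world.truth.module_families)
        hits = 0
        trials = 0
        for mod in mods[:5]:
            core = sorted(p for p, m in world.truth.module_of.items() if m == mod)
            if len(core) < 3:
                continue
            trials += 1
            res = localization(core, world.network, n_random=50, seed=rng)
            if res.z_score < 0:
                hits += 1
        assert trials > 0 and hits == trials
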