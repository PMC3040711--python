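"""Threshold graphs, percolation, topology statistics, null model, bridges."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pytest

from hybnet.distances import RD, SAD, DistanceMatrix
from hybnet.errors import ValidationError
from hybnet.genotype_io import SPIRALIS, VESICULOSUS
from hybnet.network_analysis import (
    PercolationProfile,
    build_graph,
    detect_percolation_threshold,
    detect_putative_hybrids,
    find_intermediates,
    mean_cluster_size_excluding_largest,
    node_statistics,
    percolation_profile,
    rewiring_null_model,
    threshold_sweep,
    write_graphml,
)


def matrix_from_array(values, species=None, metric=RD):
    values = np.asarray(values, dtype=float)
    ids = tuple(f"n{i}" for i in range(values.shape[0]))
    meta = {}
    if species:
        meta = {f"n{i}": {"species": s, "location": "x", "region": "r"} for i, s in enumerate(species)}
    return DistanceMatrix(ids=ids, values=values, metric=metric, node_meta=meta)


def random_matrix(rng, n, low=1, high=8):
    vals = rng.integers(low, high, size=(n, n)).astype(float)
    vals = np.triu(vals, 1)
    vals = vals + vals.T
    return matrix_from_array(vals)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_profile(matrix):
    """Percolation profile by exhaustive per-threshold component labeling."""
    n = len(matrix.ids)
    iu = np.triu_indices(n, 1)
    thresholds = sorted(set(matrix.values[iu]), reverse=True)
    out = []
    for thr in thresholds:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in zip(*iu):
            if matrix.values[i, j] <= thr:
                g.add_edge(i, j)
        sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        smax, rest = sizes[0], sizes[1:]
        n_out = sum(rest)
        s_star = sum(s * s for s in rest) / n_out if n_out else 0.0
        out.append((thr, s_star, len(sizes), smax))
    return out


def oracle_betweenness(g):
    """bc(i) over unordered pairs by explicit shortest-path enumeration."""
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bc[v] += through / len(paths)
    return bc


# ---------------------------------------------------------------------------


class TestBuildGraph:
    def test_threshold_below_min_gives_isolates(self, rng):
        m = random_matrix(rng, 6)
        g = build_graph(m, m.offdiag_values().min() - 0.5)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 6

    def test_threshold_at_max_gives_complete_graph(self, rng):
        m = random_matrix(rng, 6)
        g = build_graph(m, m.offdiag_values().max())
        assert g.number_of_edges() == 15

    def test_inclusive_edge_rule_enumerated(self):
        vals = [[0, 1, 2, 4], [1, 0, 3, 5], [2, 3, 0, 6], [4, 5, 6, 0]]
        g = build_graph(matrix_from_array(vals), 2)
        assert set(map(frozenset, g.edges)) == {frozenset({"n0", "n1"}), frozenset({"n0", "n2"})}

    def test_edge_monotonicity(self, rng):
        m = random_matrix(rng, 8)
        thrs = sorted(set(m.offdiag_values()))
        prev_edges, prev_ncomp = set(), np.inf
        for thr in thrs:
            g = build_graph(m, thr)
            edges = set(map(frozenset, g.edges))
            assert prev_edges <= edges
            ncomp = nx.number_connected_components(g)
            assert ncomp <= prev_ncomp
            prev_edges, prev_ncomp = edges, ncomp


class TestPercolation:
    def test_mean_cluster_size_hand_example(self):
        # component sizes {5, 2, 2, 1}: largest excluded, <S>* = (4+4+1)/5
        assert mean_cluster_size_excluding_largest([5, 2, 2, 1]) == pytest.approx(1.8)

    def test_connected_graph_gives_zero(self):
        assert mean_cluster_size_excluding_largest([7]) == 0.0

    def test_tied_largest_excludes_exactly_one(self):
        # sizes {3, 3}: one excluded, <S>* = 9/3
        assert mean_cluster_size_excluding_largest([3, 3]) == pytest.approx(3.0)

    def test_profile_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            m = random_matrix(rng, n)
            prof = percolation_profile(m)
            expected = oracle_profile(m)
            assert len(prof.thresholds) == len(expected)
            for k, (thr, s_star, ncomp, smax) in enumerate(expected):
                assert prof.thresholds[k] == pytest.approx(thr)
                assert prof.mean_cluster_size[k] == pytest.approx(s_star)
                assert prof.n_components[k] == ncomp
                assert prof.largest_component_size[k] == smax

    def test_largest_component_non_increasing(self, rng):
        prof = percolation_profile(random_matrix(rng, 10))
        assert np.all(np.diff(prof.largest_component_size) <= 0)

    def test_degenerate_equal_matrix_warns(self):
        vals = np.full((4, 4), 3.0)
        np.fill_diagonal(vals, 0)
        with pytest.warns(UserWarning, match="degenerate"):
            prof = percolation_profile(matrix_from_array(vals))
        assert len(prof.thresholds) == 1
        assert prof.dp == 3.0


class TestDetectThreshold:
    def _profile(self, thresholds, s_star):
        return PercolationProfile(
            thresholds=np.array(thresholds, dtype=float),
            mean_cluster_size=np.array(s_star, dtype=float),
            n_components=np.ones(len(thresholds), dtype=int),
            largest_component_size=np.ones(len(thresholds), dtype=int),
        )

    def test_argmax(self):
        prof = self._profile([10, 8, 7, 6], [0, 0.4, 1.8, 0.6])
        assert detect_percolation_threshold(prof) == 7

    def test_tie_breaks_to_larger_threshold(self):
        prof = self._profile([7, 6, 5], [1.8, 0.2, 1.8])
        assert detect_percolation_threshold(prof) == 7

    def test_all_zero_profile_warns_and_returns_min(self):
        prof = self._profile([9, 5, 2], [0, 0, 0])
        with pytest.warns(UserWarning, match="never fragments"):
            assert detect_percolation_threshold(prof) == 2

    def test_agrees_with_exhaustive_scan_on_random_profiles(self, rng):
        for _ in range(30):
            m = random_matrix(rng, 12)
            prof = percolation_profile(m)
            s = prof.mean_cluster_size
            if np.all(s == 0):
                continue
            best = max(zip(s, prof.thresholds))[1]
            assert prof.dp == best


class TestNodeStatistics:
    def test_complete_graph_k4(self):
        g = nx.complete_graph(4)
        stats = node_statistics(g)
        assert np.all(stats.table["clustering"] == 1.0)
        assert np.all(stats.table["betweenness"] == 0.0)
        assert stats.avg_clustering == 1.0

    def test_path_graph_betweenness(self):
        g = nx.path_graph(3)
        stats = node_statistics(g).table.set_index("id")
        assert stats.loc[1, "betweenness"] == 1.0
        assert stats.loc[0, "betweenness"] == 0.0

    def test_partial_neighborhood_clustering(self):
        # node 0 with neighbors 1,2,3; edges (1,2),(2,3) among them -> C = 2/3
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 2), (2, 3)])
        stats = node_statistics(g).table.set_index("id")
        assert stats.loc[0, "clustering"] == pytest.approx(2 / 3)

    def test_degree_distribution_sums_to_one(self, rng):
        g = nx.gnp_random_graph(12, 0.4, seed=5)
        stats = node_statistics(g)
        assert sum(stats.degree_distribution.values()) == pytest.approx(1.0)

    def test_matches_bruteforce_path_enumeration(self, rng):
        for trial in range(20):
            g = nx.gnp_random_graph(int(rng.integers(5, 11)), float(rng.uniform(0.2, 0.7)),
                                    seed=int(rng.integers(10_000)))
            stats = node_statistics(g).table.set_index("id")
            expected = oracle_betweenness(g)
            for v in g.nodes:
                assert stats.loc[v, "betweenness"] == pytest.approx(expected[v], abs=1e-9)
                assert stats.loc[v, "degree"] == g.degree(v)

    def test_triangle_free_graph_has_zero_clustering(self):
        g = nx.cycle_graph(6)  # even cycle: triangle-free
        assert node_statistics(g).avg_clustering == 0.0

    def test_disjoint_cliques_have_unit_clustering(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        assert node_statistics(g).avg_clustering == 1.0

    def test_tree_betweenness_sum_identity(self, rng):
        """On a tree every pair has a unique path, so the bc(i) total equals
        the number of (pair, interior node) incidences: sum over pairs of
        (path length - 1)."""
        for trial in range(10):
            n = int(rng.integers(4, 11))
            tree = nx.random_labeled_tree(n, seed=int(rng.integers(10_000)))
            stats = node_statistics(tree)
            total = stats.table["betweenness"].sum()
            interior_incidences = sum(
                nx.shortest_path_length(tree, s, t) - 1
                for s, t in itertools.combinations(tree.nodes, 2)
            )
            assert total == pytest.approx(interior_incidences)


class TestNullModel:
    def test_z_score_formula(self):
        # observed 0.72 against null 0.11 +/- 0.1 -> z = 6.1
        from hybnet.network_analysis import NullModelResult

        r = NullModelResult(
            n_iter=100, mean_cc=0.11, sd_cc=0.1, observed_cc=0.72,
            z_score=(0.72 - 0.11) / 0.1, seed=0,
        )
        assert r.z_score == pytest.approx(6.1)

    def test_observed_cc_matches_networkx(self):
        g = nx.karate_club_graph()
        res = rewiring_null_model(g, n_iter=100, seed=2)
        assert res.observed_cc == pytest.approx(nx.average_clustering(g))

    def test_reproducible_under_seed(self):
        g = nx.karate_club_graph()
        a = rewiring_null_model(g, n_iter=150, seed=9)
        b = rewiring_null_model(g, n_iter=150, seed=9)
        assert a.mean_cc == b.mean_cc and a.sd_cc == b.sd_cc

    def test_two_cluster_graph_exceeds_null(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(8))
        g.add_edge(0, 8)
        res = rewiring_null_model(g, n_iter=300, seed=4)
        assert res.z_score > 3

    def test_star_graph_degenerate(self):
        g = nx.star_graph(5)
        with pytest.warns(UserWarning, match="zero variance"):
            res = rewiring_null_model(g, n_iter=100, seed=1)
        assert res.degenerate
        assert res.z_score is None

    def test_gnm_method(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        res = rewiring_null_model(g, n_iter=100, seed=3, method="gnm")
        assert res.method == "gnm"
        assert res.observed_cc > res.mean_cc

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValidationError):
            rewiring_null_model(nx.complete_graph(4), n_iter=10, seed=0)


def two_clique_species_matrix():
    """Two 4-cliques of different species joined by one short edge."""
    n = 8
    vals = np.full((n, n), 10.0)
    for block in (range(4), range(4, 8)):
        for i, j in itertools.combinations(block, 2):
            vals[i, j] = vals[j, i] = 1.0
    vals[0, 4] = vals[4, 0] = 1.0  # the bridge
    np.fill_diagonal(vals, 0)
    species = [SPIRALIS] * 4 + [VESICULOSUS] * 4
    return matrix_from_array(vals, species=species, metric=SAD)


class TestIntermediates:
    def test_no_inter_species_edge_gives_empty_set(self):
        m = two_clique_species_matrix()
        g = build_graph(m, 1.0)
        g.remove_edge("n0", "n4")
        rep = find_intermediates(g)
        assert rep.ids == set()
        assert rep.separates_species  # already separate

    def test_bridge_endpoints_detected_and_articulate(self):
        g = build_graph(two_clique_species_matrix(), 1.0)
        rep = find_intermediates(g)
        assert rep.ids == {"n0", "n4"}
        assert rep.separates_species
        row = rep.table.set_index("id").loc["n0"]
        assert row["n_same_species"] == 3
        assert row["n_other_species"] == 1

    def test_all_nodes_inter_linked_on_complete_graph(self):
        m = two_clique_species_matrix()
        g = build_graph(m, 10.0)  # complete graph: every node inter-linked
        rep = find_intermediates(g)
        assert rep.ids == set(g.nodes)

    def test_hybrid_labeled_path_keeps_species_connected(self):
        """A simulated-hybrid node carries no spiralis-vesiculosus edge, so it
        is not an intermediate, yet it can keep the species in one component
        after the intermediates are removed."""
        g = build_graph(two_clique_species_matrix(), 1.0)
        g.remove_edge("n0", "n4")
        g.add_node("hyb", species="simulated_hybrid")
        g.add_edge("n1", "hyb", distance=0.5)
        g.add_edge("n5", "hyb", distance=0.5)
        rep = find_intermediates(g)
        assert rep.ids == set()
        assert not rep.separates_species


class TestThresholdSweep:
    def test_component_transition_at_gap(self):
        m = two_clique_species_matrix()
        m.values[0, 4] = m.values[4, 0] = 5.0  # bridge value inside the gap
        df = threshold_sweep(m, [10.0, 5.0, 1.0])
        ncomp = df.groupby("threshold")["component"].nunique()
        assert ncomp[10.0] == 1 and ncomp[5.0] == 1 and ncomp[1.0] == 2
        assert len(df) == 1 + 1 + 2

    def test_species_composition_reported(self):
        m = two_clique_species_matrix()
        df = threshold_sweep(m, [1.0])
        assert df["n_spiralis"].sum() == 4
        assert df["n_vesiculosus"].sum() == 4

    def test_out_of_range_threshold_warns(self):
        m = two_clique_species_matrix()
        with pytest.warns(UserWarning, match="outside realized"):
            threshold_sweep(m, [99.0])


class TestExports:
    def test_graphml_round_trip_attributes(self, tmp_path):
        m = two_clique_species_matrix()
        g = build_graph(m, 1.0)
        stats = node_statistics(g)
        rep = find_intermediates(g)
        p = tmp_path / "g.graphml"
        write_graphml(g, p, stats, rep, run_id="test123")
        back = nx.read_graphml(p)
        assert back.graph["run_id"] == "test123"
        assert back.nodes["n0"]["intermediate"]
        assert back.nodes["n1"]["species"] == SPIRALIS
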