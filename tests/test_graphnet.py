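"""Correlation matrix, clustering, graph construction and centralities."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import hub_phantom
from dbsnet import (CorrelationMatrix, NodeAtlas, betweenness, build_graph,
                    centrality_table, closeness, hierarchical_cluster,
                    region_correlation_matrix, simulate_bold,
                    zscore_centralities)
from dbsnet import NetworkSpec, PhantomSpec, RegionSpec
from oracles import brute_force_centralities, random_connected_graph

AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def corr_matrix(labels, values):
    return CorrelationMatrix(labels=labels, values=np.asarray(values, float),
                             n_subjects=10)


class TestRegionCorrelationMatrix:
    def test_unit_diagonal_symmetry_bounds(self):
        spec = hub_phantom(n_networks=3, n_subjects=5, seed=2)
        scans = simulate_bold(spec)
        atlas = NodeAtlas(
            labels=[r.name for r in spec.regions],
            masks={r.name: spec.region_mask(r.name).mask for r in spec.regions},
            affine=spec.affine,
        )
        m = region_correlation_matrix(scans, atlas)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)
        assert np.abs(m.values).max() <= 1.0

    def test_shared_network_pair_matches_closed_form(self):
        """Two single-voxel regions with loading a on one network: population
        r = a^2/(a^2 + sigma^2)."""
        a = 1.0
        spec = PhantomSpec(
            grid_shape=(4, 4, 4), n_subjects=200, n_timepoints=124,
            regions=[RegionSpec("p", [(0, 0, 0)], {"n": a}),
                     RegionSpec("q", [(3, 3, 3)], {"n": a})],
            networks=[NetworkSpec("n")], rng_seed=9,
        )
        scans = simulate_bold(spec)
        atlas = NodeAtlas(labels=["p", "q"],
                          masks={"p": spec.region_mask("p").mask,
                                 "q": spec.region_mask("q").mask},
                          affine=spec.affine)
        m = region_correlation_matrix(scans, atlas)
        expected = a**2 / (a**2 + 1.0)
        assert abs(m.values[0, 1] - expected) < 0.05

    def test_two_block_structure_recovered(self):
        """Within-block correlations exceed between-block correlations."""
        nets = [NetworkSpec("n1"), NetworkSpec("n2")]
        regions = [
            RegionSpec("a1", [(0, 0, 0)], {"n1": 1.5}),
            RegionSpec("a2", [(0, 0, 2)], {"n1": 1.5}),
            RegionSpec("b1", [(2, 2, 0)], {"n2": 1.5}),
            RegionSpec("b2", [(2, 2, 2)], {"n2": 1.5}),
        ]
        spec = PhantomSpec(grid_shape=(3, 3, 3), n_subjects=40,
                           n_timepoints=124, regions=regions, networks=nets,
                           rng_seed=4)
        scans = simulate_bold(spec)
        atlas = NodeAtlas(labels=[r.name for r in regions],
                          masks={r.name: spec.region_mask(r.name).mask
                                 for r in regions},
                          affine=spec.affine)
        m = region_correlation_matrix(scans, atlas).to_frame()
        within = (m.loc["a1", "a2"] + m.loc["b1", "b2"]) / 2
        between = m.loc[["a1", "a2"], ["b1", "b2"]].values.mean()
        assert within > between + 0.3


class TestHierarchicalCluster:
    def test_degenerate_cuts(self):
        m = corr_matrix(list("abcd"), np.eye(4))
        singletons = hierarchical_cluster(m, 4)
        assert len(set(singletons.cluster_id.values())) == 4
        one = hierarchical_cluster(m, 1)
        assert set(one.cluster_id.values()) == {1}

    def test_invalid_k_rejected(self):
        m = corr_matrix(list("abc"), np.eye(3))
        for k in (0, 4):
            with pytest.raises(ValueError):
                hierarchical_cluster(m, k)

    def test_two_block_matrix_recovers_blocks(self):
        """Exact block matrix (within r=0.8, between 0): the k=2 cut equals the
        partition minimising total within-cluster Euclidean distance, found by
        brute force over all 2-partitions."""
        labels = list("abcdef")
        v = np.eye(6)
        for i, j in itertools.combinations(range(6), 2):
            same = (i < 3) == (j < 3)
            v[i, j] = v[j, i] = 0.8 if same else 0.0
        m = corr_matrix(labels, v)
        got = hierarchical_cluster(m, 2)
        groups = {}
        for lab, c in got.cluster_id.items():
            groups.setdefault(c, set()).add(lab)
        # brute-force best 2-partition by summed within-cluster distances
        best, best_cost = None, np.inf
        idx = {l: i for i, l in enumerate(labels)}
        for size in range(1, 6):
            for combo in itertools.combinations(labels, size):
                part = [set(combo), set(labels) - set(combo)]
                cost = 0.0
                for group in part:
                    for a, b in itertools.combinations(group, 2):
                        cost += np.linalg.norm(v[idx[a]] - v[idx[b]])
                if cost < best_cost - 1e-12:
                    best_cost, best = cost, part
        assert set(map(frozenset, groups.values())) == set(map(frozenset, best))


class TestBuildGraph:
    def test_anticorrelation_excluded_no_self_loops(self):
        v = np.array([[1.0, -0.4, 0.5],
                      [-0.4, 1.0, 0.2],
                      [0.5, 0.2, 1.0]])
        g = build_graph(corr_matrix(list("abc"), v), display_cutoff=0.3)
        assert not g.has_edge("a", "b")
        assert g.has_edge("a", "c") and not g["a"]["c"]["below_cutoff"]
        assert g.has_edge("b", "c") and g["b"]["c"]["below_cutoff"]
        assert all(u != v for u, v in g.edges)

    def test_uniform_matrix_gives_complete_graph(self):
        v = np.full((4, 4), 0.5); np.fill_diagonal(v, 1.0)
        g = build_graph(corr_matrix(list("abcd"), v))
        assert g.number_of_edges() == 6
        assert all(np.isclose(d["weight"], 0.5) for _, _, d in g.edges(data=True))

    def test_display_cutoff_never_removes_edges(self):
        v = np.full((4, 4), 0.1); np.fill_diagonal(v, 1.0)
        g = build_graph(corr_matrix(list("abcd"), v), display_cutoff=0.9)
        assert g.number_of_edges() == 6


def path_graph():
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0, length=1.0)
    g.add_edge("b", "c", weight=1.0, length=1.0)
    return g


class TestCentralities:
    def test_path_graph(self):
        b = betweenness(path_graph())
        assert b == {"a": 0.0, "b": 1.0, "c": 0.0}
        c = closeness(path_graph())
        assert np.isclose(c["b"], 1.0)
        assert np.isclose(c["a"], 2.0 / 3.0)

    def test_star_graph(self):
        g = nx.Graph()
        for leaf in "abcd":
            g.add_edge("hub", leaf, weight=1.0, length=1.0)
        b = betweenness(g)
        assert b["hub"] == 6.0          # C(4, 2)
        assert all(b[l] == 0.0 for l in "abcd")

    def test_triangle_closeness_symmetric(self):
        g = nx.Graph()
        for u, v in (("a", "b"), ("b", "c"), ("a", "c")):
            g.add_edge(u, v, weight=1.0, length=1.0)
        assert all(np.isclose(v, 1.0) for v in closeness(g).values())

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(40):
            g = random_connected_graph(rng)
            b_ref, c_ref = brute_force_centralities(g)
            b = betweenness(g)
            c = closeness(g)
            for n in g.nodes:
                assert np.isclose(b[n], b_ref[n], atol=1e-8)
                assert np.isclose(c[n], c_ref[n], atol=1e-8)

    def test_disconnected_graph_per_component(self):
        g = path_graph()
        g.add_edge("x", "y", weight=0.5, length=2.0)
        c = closeness(g)
        assert np.isclose(c["x"], 0.5)          # (2-1)/2
        b = betweenness(g)
        assert b["b"] == 1.0

    def test_permutation_equivariance(self, rng):
        g = random_connected_graph(rng)
        mapping = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, mapping)
        bg, bh = betweenness(g), betweenness(h)
        for n in g.nodes:
            assert np.isclose(bg[n], bh[mapping[n]], atol=1e-10)


class TestZscores:
    def test_one_two_three(self):
        z = zscore_centralities({"a": 1.0, "b": 2.0, "c": 3.0})
        assert np.allclose([z["a"], z["b"], z["c"]], [-1.0, 0.0, 1.0])

    def test_constant_vector_all_zero(self):
        z = zscore_centralities({"a": 2.0, "b": 2.0, "c": 2.0})
        assert all(v == 0.0 for v in z.values())

    def test_mean_zero_sd_one(self, rng):
        vals = {f"n{i}": float(v) for i, v in enumerate(rng.standard_normal(10))}
        z = np.array(list(zscore_centralities(vals).values()))
        assert np.isclose(z.mean(), 0.0, atol=1e-12)
        assert np.isclose(z.std(ddof=1), 1.0)


def test_planted_hub_attains_top_centrality():
    """The connector region loading on every latent network is the top hub."""
    spec = hub_phantom(n_subjects=20, seed=7)
    scans = simulate_bold(spec)
    atlas = NodeAtlas(labels=[r.name for r in spec.regions],
                      masks={r.name: spec.region_mask(r.name).mask
                             for r in spec.regions},
                      affine=spec.affine)
    m = region_correlation_matrix(scans, atlas)
    table = centrality_table(build_graph(m))
    top_b = table.loc[table["betweenness_z"].idxmax(), "region"]
    top_c = table.loc[table["closeness_z"].idxmax(), "region"]
    assert top_b == "hub" and top_c == "hub"
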