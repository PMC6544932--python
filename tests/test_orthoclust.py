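"""The coupled-modularity objective, its incremental deltas, and the annealer."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossexp.homology import OrthologPairSet
from crossexp.network import from_edges
from crossexp.orthoclust import (
    CrossSpeciesNetwork,
    ModuleAssignment,
    OrthoClustParams,
    build_caches,
    count_modules,
    delta_H_single_move,
    modularity_score,
    objective_H,
    parameter_sweep,
    rank_labels,
    sa_optimize,
    summarize_modules,
)

from conftest import make_cross_instance, random_sigma
from oracles import brute_objective, pair_modularity


def empty_orthologs():
    return OrthologPairSet(pairs=set(), weights={}, mode="rbh")


def single_species_instance(edges, extra=None):
    return CrossSpeciesNetwork(
        net1=from_edges(edges, species_tag="s1", extra_nodes=extra),
        net2=from_edges(set(), species_tag="s2"),
        orthologs=empty_orthologs(),
    )


class TestModularityScore:
    def test_triangle_pair(self):
        net = from_edges({("a", "b"), ("b", "c"), ("a", "c")})
        assert modularity_score(net, "a", "b") == pytest.approx(1.0 / 3.0)

    def test_isolated_pair_scores_zero(self):
        net = from_edges({("a", "b")}, extra_nodes=["x", "y"])
        assert modularity_score(net, "x", "y") == 0.0

    def test_same_node_rejected(self):
        net = from_edges({("a", "b")})
        with pytest.raises(ValueError):
            modularity_score(net, "a", "a")

    def test_partition_sum_matches_networkx_modularity(self):
        rng = np.random.default_rng(15)
        nodes = [f"n{i}" for i in range(12)]
        edges = {
            (u, v)
            for u, v in itertools.combinations(nodes, 2)
            if rng.random() < 0.3
        }
        net = from_edges(edges, extra_nodes=nodes)
        labels = {n: int(rng.integers(3)) for n in nodes}
        pair_sum = sum(
            modularity_score(net, i, j)
            for i, j in itertools.combinations(nodes, 2)
            if labels[i] == labels[j]
        )
        G = nx.Graph(sorted(edges))
        G.add_nodes_from(nodes)
        communities = [
            {n for n in nodes if labels[n] == c} for c in set(labels.values())
        ]
        q = nx.algorithms.community.modularity(G, communities)
        # unordered-pair sum = Q*m + sum_i k_i^2 / (4m)  (diagonal convention)
        ksq = sum(d * d for _, d in G.degree())
        assert pair_sum == pytest.approx(q * net.m + ksq / (4 * net.m), abs=1e-9)


class TestObjective:
    def test_all_singletons_score_zero(self, cross_instance_factory):
        rng = np.random.default_rng(1)
        x = cross_instance_factory(rng)
        sigma = {n: i for i, n in enumerate(x.universe)}
        assert objective_H(x, sigma, kappa=3.0) == 0.0

    def test_lone_ortholog_pair_scores_minus_kappa_w(self):
        orth = OrthologPairSet(pairs={("A0", "B0")}, weights={("A0", "B0"): 1.0},
                               mode="rbh")
        x = CrossSpeciesNetwork(
            net1=from_edges(set(), extra_nodes=["A0"]),
            net2=from_edges(set(), extra_nodes=["B0"]),
            orthologs=orth,
        )
        assert objective_H(x, {"A0": 1, "B0": 1}, kappa=3.0) == pytest.approx(-3.0)
        assert objective_H(x, {"A0": 1, "B0": 2}, kappa=3.0) == 0.0

    @pytest.mark.parametrize("kappa", [0.0, 1.0, 3.0])
    def test_matches_triple_loop_oracle(self, kappa):
        rng = np.random.default_rng(int(kappa * 10) + 2)
        for _ in range(5):
            x = make_cross_instance(rng, n1=5, n2=5, weighted=True)
            sigma = random_sigma(rng, x)
            assert objective_H(x, sigma, kappa) == pytest.approx(
                brute_objective(x, sigma, kappa), abs=1e-9
            )

    def test_missing_label_rejected(self, cross_instance_factory):
        x = cross_instance_factory(np.random.default_rng(3))
        sigma = {n: 0 for n in x.universe[:-1]}
        with pytest.raises(ValueError, match="missing"):
            objective_H(x, sigma, 1.0)

    def test_decomposes_into_species_terms_plus_coupling(self):
        rng = np.random.default_rng(8)
        x = make_cross_instance(rng, n1=6, n2=7, n_orth=5)
        sigma = random_sigma(rng, x)
        h_k0 = objective_H(x, sigma, kappa=0.0)
        coupling = sum(
            x.orthologs.weights[p]
            for p in x.orthologs.pairs
            if sigma[p[0]] == sigma[p[1]]
        )
        assert objective_H(x, sigma, kappa=2.5) == pytest.approx(
            h_k0 - 2.5 * coupling, abs=1e-12
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_label_permutation(self, seed):
        rng = np.random.default_rng(seed)
        x = make_cross_instance(rng, n1=5, n2=5)
        sigma = random_sigma(rng, x, n_labels=4)
        perm = {old: new for old, new in
                zip(range(4), rng.permutation(100)[:4])}
        permuted = {n: int(perm[l]) for n, l in sigma.items()}
        assert objective_H(x, sigma, 1.7) == pytest.approx(
            objective_H(x, permuted, 1.7), abs=1e-12
        )


class TestDeltaH:
    def test_isolated_unpaired_node_move_is_free(self):
        x = single_species_instance({("a", "b")}, extra=["lone"])
        sigma = {"a": 0, "b": 0, "lone": 1}
        caches = build_caches(x, sigma)
        assert delta_H_single_move(x, sigma, "lone", 0, 3.0, caches) == 0.0

    def test_matches_full_recomputation(self):
        rng = np.random.default_rng(44)
        for trial in range(10):
            x = make_cross_instance(rng, n1=6, n2=6, weighted=(trial % 2 == 0))
            sigma = random_sigma(rng, x, n_labels=5)
            caches = build_caches(x, sigma)
            kappa = float(rng.uniform(0, 4))
            for _ in range(20):
                node = x.universe[int(rng.integers(len(x.universe)))]
                new = int(rng.integers(8))
                if new == sigma[node]:
                    continue
                before = objective_H(x, sigma, kappa)
                d = delta_H_single_move(x, sigma, node, new, kappa, caches)
                after_sigma = dict(sigma)
                after_sigma[node] = new
                assert d == pytest.approx(
                    objective_H(x, after_sigma, kappa) - before, abs=1e-9
                )

    def test_reverse_move_negates(self):
        rng = np.random.default_rng(46)
        x = make_cross_instance(rng, n1=5, n2=5)
        sigma = random_sigma(rng, x, n_labels=3)
        node = x.universe[2]
        old, new = sigma[node], (sigma[node] + 1) % 3
        caches = build_caches(x, sigma)
        d_fwd = delta_H_single_move(x, sigma, node, new, 2.0, caches)
        sigma2 = dict(sigma)
        sigma2[node] = new
        caches2 = build_caches(x, sigma2)
        d_rev = delta_H_single_move(x, sigma2, node, old, 2.0, caches2)
        assert d_fwd == pytest.approx(-d_rev, abs=1e-12)

    def test_same_label_rejected(self):
        x = single_species_instance({("a", "b")})
        sigma = {"a": 0, "b": 1}
        with pytest.raises(ValueError):
            delta_H_single_move(x, sigma, "a", 0, 1.0, build_caches(x, sigma))

    def test_module_merge_equals_sum_of_cross_pair_terms(self):
        rng = np.random.default_rng(48)
        x = make_cross_instance(rng, n1=6, n2=6, n_orth=6)
        sigma = random_sigma(rng, x, n_labels=3)
        kappa = 2.0
        merged = {n: (0 if l == 1 else l) for n, l in sigma.items()}
        got = objective_H(x, merged, kappa) - objective_H(x, sigma, kappa)
        # independent evaluation: cross-pair terms between the two modules
        mod0 = [n for n, l in sigma.items() if l == 0]
        mod1 = [n for n, l in sigma.items() if l == 1]
        expected = 0.0
        for i in mod0:
            for j in mod1:
                si, sj = x.species_of(i), x.species_of(j)
                if si == sj:
                    expected -= pair_modularity(x.net_of(i), i, j)
        for (a, b), w in x.orthologs.weights.items():
            if {sigma[a], sigma[b]} == {0, 1}:
                expected -= kappa * w
        assert got == pytest.approx(expected, abs=1e-9)


class TestAnnealer:
    def test_empty_instance_returns_zero(self):
        x = CrossSpeciesNetwork(
            net1=from_edges(set()), net2=from_edges(set()), orthologs=empty_orthologs()
        )
        sigma, H, _ = sa_optimize(x, OrthoClustParams(seed=1, n_restarts=1))
        assert H == 0.0
        assert sigma.sigma == {}

    def test_two_disjoint_cliques_recovered(self):
        g1 = [f"a{i}" for i in range(5)]
        g2 = [f"b{i}" for i in range(5)]
        edges = {
            tuple(sorted(p)) for p in itertools.combinations(g1, 2)
        } | {tuple(sorted(p)) for p in itertools.combinations(g2, 2)}
        x = single_species_instance(edges)
        sigma, H, _ = sa_optimize(x, OrthoClustParams(kappa=0, seed=7, n_restarts=5))
        groups = sorted(
            tuple(sorted(m)) for m in sigma.modules().values()
        )
        assert groups == [tuple(g1), tuple(g2)]
        # optimum of the clique partition, evaluated independently
        expected = brute_objective(
            x, {**{g: 0 for g in g1}, **{g: 1 for g in g2}}, 0.0
        )
        assert H == pytest.approx(expected, abs=1e-9)

    def test_never_worse_than_singleton_baseline(self):
        rng = np.random.default_rng(52)
        for seed in range(5):
            x = make_cross_instance(rng, n1=7, n2=7, p_edge=0.2)
            _, H, _ = sa_optimize(x, OrthoClustParams(seed=seed, n_restarts=2))
            assert H <= 1e-12

    def test_incremental_energy_consistent_with_full_eval(self):
        rng = np.random.default_rng(53)
        x = make_cross_instance(rng, n1=8, n2=8, p_edge=0.3, n_orth=6)
        params = OrthoClustParams(kappa=2.0, seed=3, n_restarts=2)
        sigma, H, _ = sa_optimize(x, params)
        assert objective_H(x, sigma, 2.0) == pytest.approx(H, abs=1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(54)
        x = make_cross_instance(rng, n1=8, n2=8)
        params = OrthoClustParams(kappa=1.0, seed=11, n_restarts=2)
        s1, h1, _ = sa_optimize(x, params)
        s2, h2, _ = sa_optimize(x, params)
        assert h1 == h2 and s1.sigma == s2.sigma


class TestSummaries:
    def fixture_instance(self, n1, n2):
        g1 = [f"A{i}" for i in range(n1)]
        g2 = [f"B{i}" for i in range(n2)]
        return CrossSpeciesNetwork(
            net1=from_edges(set(), extra_nodes=g1),
            net2=from_edges(set(), extra_nodes=g2),
            orthologs=empty_orthologs(),
        ), g1, g2

    def test_published_style_percentages(self):
        x, g1, g2 = self.fixture_instance(79, 273)
        sigma = ModuleAssignment(sigma={g: 1 for g in g1 + g2})
        row = summarize_modules(sigma, x).iloc[0]
        assert row["total"] == 352
        assert (row["pct_species2"], row["pct_species1"]) == (77.6, 22.4)

    def test_single_gene_module(self):
        x, g1, _ = self.fixture_instance(1, 0)
        row = summarize_modules(ModuleAssignment(sigma={g1[0]: 4}), x).iloc[0]
        assert row["pct_species1"] == 100.0 and row["pct_species2"] == 0.0

    def test_counts_match_groupby_oracle_and_sorted_by_size(self):
        rng = np.random.default_rng(61)
        x = make_cross_instance(rng, n1=20, n2=20)
        sigma = ModuleAssignment(sigma=random_sigma(rng, x, n_labels=6))
        out = summarize_modules(sigma, x)
        assert list(out["total"]) == sorted(out["total"], reverse=True)
        assert out["total"].sum() == len(x.universe)
        expected_sizes = sorted(
            (len(m) for m in sigma.modules().values()), reverse=True
        )
        assert list(out["total"]) == expected_sizes
        assert (out["n_species1"] + out["n_species2"] == out["total"]).all()

    def test_rank_labels_orders_by_size(self):
        rng = np.random.default_rng(62)
        x = make_cross_instance(rng, n1=10, n2=10)
        sigma = ModuleAssignment(sigma=random_sigma(rng, x, n_labels=4))
        ranked = rank_labels(sigma, x)
        sizes = {l: len(m) for l, m in ranked.modules().items()}
        assert sorted(sizes) == list(range(1, len(sizes) + 1))
        assert [sizes[l] for l in sorted(sizes)] == sorted(sizes.values(), reverse=True)


class TestParameterSweep:
    def test_single_cell_equals_direct_call(self):
        rng = np.random.default_rng(71)
        x = make_cross_instance(rng, n1=8, n2=8, n_orth=5)
        base = OrthoClustParams(seed=5, n_restarts=2)
        table = parameter_sweep(lambda cutoff: x, [2.0], [0.99], base)
        direct_params = OrthoClustParams(kappa=2.0, seed=5, n_restarts=2)
        sigma, H, _ = sa_optimize(x, direct_params)
        assert table.loc[0, "H"] == pytest.approx(H)
        assert table.loc[0, "n_modules_ge2"] == count_modules(sigma, x)["n_modules_ge2"]

    def test_kappa_zero_yields_no_cross_species_modules(self):
        rng = np.random.default_rng(72)
        x = make_cross_instance(rng, n1=10, n2=10, p_edge=0.4, n_orth=8)
        sigma, _, _ = sa_optimize(x, OrthoClustParams(kappa=0.0, seed=9, n_restarts=3))
        assert count_modules(sigma, x)["n_cross_species_modules"] == 0
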