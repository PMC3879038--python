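import itertools

import networkx as nx
import numpy as np
import pytest

import triopba as tp
from triopba.io import Interactome
from triopba.network import (
    NetworkScanConfig,
    avg_connectivity,
    empirical_null,
    minimal_connected_network,
    scan,
)
from triopba.sim import rng_for

from conftest import subnetwork_oracle


def interactome_of(edges):
    return Interactome.from_edges(edges)


class TestMinimalConnectedNetwork:
    def test_direct_edge(self):
        inter = interactome_of([("A", "B"), ("B", "C")])
        sub = minimal_connected_network(["A", "B"], inter)
        assert sub.nodes == {"A", "B"}
        assert sub.edges == {("A", "B")}
        assert sub.intermediates == set()

    def test_single_intermediate(self):
        inter = interactome_of([("A", "X"), ("X", "B"), ("X", "Y")])
        sub = minimal_connected_network(["A", "B"], inter)
        assert sub.nodes == {"A", "X", "B"}
        assert sub.intermediates == {"X"}
        assert all(len({a, b} & {"X"}) > 0 or {a, b} <= {"A", "B"} for a, b in sub.edges)

    def test_direct_only_mode_skips_intermediates(self):
        inter = interactome_of([("A", "X"), ("X", "B")])
        sub = minimal_connected_network(["A", "B"], inter, max_intermediates_per_link=0)
        assert sub.is_empty

    def test_multi_hop_paths_not_allowed(self):
        inter = interactome_of([("A", "X"), ("X", "Y"), ("Y", "B")])
        sub = minimal_connected_network(["A", "B"], inter)
        assert sub.is_empty
        assert sub.seeds_unlinked == {"A", "B"}

    def test_every_intermediate_touches_two_linked_seeds(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(1 << 30)))
            edges = [(f"n{a}", f"n{b}") for a, b in g.edges]
            if not edges:
                continue
            nodes = sorted({v for e in edges for v in e})
            seeds = list(rng.choice(nodes, size=min(4, len(nodes)), replace=False))
            sub = minimal_connected_network(seeds, interactome_of(edges))
            adj = {}
            for a, b in sub.edges:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            for x in sub.intermediates:
                assert len(adj[x] & sub.seeds_linked) >= 2

    def test_seed_order_invariance(self):
        inter = interactome_of([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")])
        a = minimal_connected_network(["A", "B", "C"], inter)
        b = minimal_connected_network(["C", "A", "B"], inter)
        assert a.nodes == b.nodes and a.edges == b.edges

    def test_matches_exhaustive_oracle_on_small_graphs(self):
        """Random graphs <= 12 nodes, all seed subsets <= 4, against the
        explicit path-enumeration oracle."""
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)))
            edges = [(f"n{a}", f"n{b}") for a, b in g.edges]
            if not edges:
                continue
            inter = interactome_of(edges)
            nodes = inter.nodes
            for size in (2, 3, 4):
                for seeds in itertools.islice(
                    itertools.combinations(nodes, size), 40
                ):
                    sub = minimal_connected_network(list(seeds), inter)
                    o_nodes, o_edges = subnetwork_oracle(seeds, edges)
                    assert sub.nodes == o_nodes
                    assert sub.edges == o_edges


class TestAvgConnectivity:
    def test_two_isolated_partners(self):
        inter = interactome_of([("A", "B")])
        sub = minimal_connected_network(["A", "B"], inter)
        assert avg_connectivity(sub, inter) == 1.0

    def test_star_with_intermediate_center(self):
        edges = [("H", x) for x in ("A", "B", "C", "D", "E")]
        inter = interactome_of(edges)
        sub = minimal_connected_network(["A", "B"], inter)
        assert sub.nodes == {"A", "H", "B"}
        assert avg_connectivity(sub, inter) == pytest.approx(7 / 3)
        assert avg_connectivity(sub, inter, seeds_only=True) == 1.0

    def test_locality_unaffected_by_remote_edges(self):
        base = [("A", "B"), ("B", "C")]
        remote = [("Q", "R"), ("R", "S")]
        i1 = interactome_of(base + remote)
        i2 = interactome_of(base + remote + [("Q", "S")])
        sub1 = minimal_connected_network(["A", "C"], i1)
        sub2 = minimal_connected_network(["A", "C"], i2)
        assert avg_connectivity(sub1, i1) == avg_connectivity(sub2, i2)

    def test_empty_subnetwork_undefined(self):
        inter = interactome_of([("A", "B")])
        sub = minimal_connected_network(["A"], inter)
        with pytest.raises(ValueError):
            avg_connectivity(sub, inter)


class TestEmpiricalNull:
    def test_degenerate_full_draw_has_zero_variance(self):
        inter = interactome_of([("A", "B"), ("B", "C"), ("C", "D")])
        cfg = NetworkScanConfig(n_null_samples=100, seed=1)
        null = empirical_null(4, inter, cfg)
        assert np.ptp(null) == 0.0

    def test_deterministic_given_seed(self):
        inter = interactome_of(
            [(f"n{a}", f"n{b}") for a, b in nx.gnp_random_graph(20, 0.2, seed=3).edges]
        )
        cfg = NetworkScanConfig(n_null_samples=200, seed=5)
        assert np.array_equal(empirical_null(5, inter, cfg), empirical_null(5, inter, cfg))

    def test_matches_exhaustive_subset_enumeration(self):
        """On a 6-node graph the sampled null matches the exact
        distribution over all C(6,3) = 20 subsets."""
        g = nx.gnp_random_graph(6, 0.5, seed=9)
        edges = [(f"n{a}", f"n{b}") for a, b in g.edges]
        inter = interactome_of(edges)
        cfg = NetworkScanConfig(n_null_samples=4000, seed=2, seeds_only_connectivity=False)
        null = empirical_null(3, inter, cfg)
        exact = []
        for seeds in itertools.combinations(inter.nodes, 3):
            nodes, _edges = subnetwork_oracle(seeds, edges)
            exact.append(
                0.0 if not nodes else float(np.mean([inter.degree(v) for v in nodes]))
            )
        assert set(np.round(null, 9)) <= set(np.round(exact, 9))
        assert np.mean(null) == pytest.approx(np.mean(exact), abs=0.15)


class TestScan:
    def _module_study(self, seed):
        cfg = tp.SimConfig(n_genes=300, n_snps=900, seed=seed)
        module = [f"G{i:04d}" for i in range(12)]
        truth = tp.TruthSet([], [], [], module)
        inter = tp.generate_interactome(cfg, truth)
        rng = rng_for(seed, "ranks")
        rest = [g for g in inter.nodes if g not in set(module)]
        ranked = module + list(np.asarray(rest)[rng.permutation(len(rest))])
        return ranked, inter

    def test_alpha_one_stops_immediately(self):
        ranked, inter = self._module_study(31)
        cfg = NetworkScanConfig(n_start=10, n_max=50, n_null_samples=100, alpha=1.0, seed=0)
        res = scan(ranked, inter, cfg)
        assert res.n_final == 10 and res.significant

    def test_addone_estimator_lower_bound(self):
        ranked, inter = self._module_study(32)
        cfg = NetworkScanConfig(n_start=10, n_max=15, n_null_samples=100, seed=0)
        res = scan(ranked, inter, cfg)
        for _n, _s, p in res.trace:
            assert p >= 1 / 101

    def test_planted_module_found_significant(self):
        ranked, inter = self._module_study(33)
        cfg = NetworkScanConfig(n_start=10, n_max=30, n_null_samples=500, seed=4)
        res = scan(ranked, inter, cfg)
        assert res.significant and res.n_final <= 25
        assert res.subnetwork.seeds_linked <= set(ranked[: res.n_final])

    def test_too_few_mappable_genes_is_an_error(self):
        inter = interactome_of([("A", "B")])
        with pytest.raises(ValueError, match="n_start"):
            scan(["A", "B", "Z"], inter, NetworkScanConfig(n_start=10, n_max=20))

    def test_result_json_roundtrip(self, tmp_path):
        ranked, inter = self._module_study(34)
        cfg = NetworkScanConfig(n_start=10, n_max=12, n_null_samples=100, seed=0)
        res = scan(ranked, inter, cfg)
        res.write_json(tmp_path / "net.json")
        import json

        doc = json.loads((tmp_path / "net.json").read_text())
        assert doc["n_final"] == res.n_final
        assert doc["empirical_p"] == res.empirical_p
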