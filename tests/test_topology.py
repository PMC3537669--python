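"""Topology statistics, degree-preserving randomization, and CSR."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy.special import comb

from aspnet.containers import Interactome, SubNetwork
from aspnet.topology import (
    characteristic_path_length,
    csr,
    csr_group_contrast,
    in_degree_ratio,
    maslov_sneppen_randomize,
    subnetwork_density,
    topology_null_test,
)


def path_graph_net(n=3, itype="PPI"):
    return Interactome([(f"n{i}", f"n{i+1}", itype) for i in range(n - 1)])


def sub(genes, net):
    gs = frozenset(genes)
    return SubNetwork("s", gs, net.induced_edges(gs))


class TestCharPathLength:
    def test_endpoints_of_path_graph(self):
        net = path_graph_net(3)
        length, excl = characteristic_path_length(net, {"n0", "n2"})
        assert length == 2.0 and excl == 0.0

    def test_clique_subset_is_one(self):
        net = Interactome(
            [(a, b, "PPI") for a in "ABCD" for b in "ABCD" if a < b])
        length, _ = characteristic_path_length(net, {"A", "B", "C"})
        assert length == 1.0

    def test_disconnected_pairs_excluded_and_reported(self):
        net = Interactome([("A", "B", "PPI"), ("C", "D", "PPI")])
        length, excl = characteristic_path_length(net, {"A", "B", "C"})
        assert length == 1.0 and excl == pytest.approx(2 / 3)

    def test_all_disconnected_raises(self):
        net = Interactome([("A", "B", "PPI"), ("C", "D", "PPI")])
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(net, {"A", "C"})

    def test_matches_all_pairs_bfs_oracle(self):
        rng = np.random.default_rng(0)
        g = nx.gnm_random_graph(200, 500, seed=1)
        net = Interactome([(f"v{a}", f"v{b}", "PPI") for a, b in g.edges()])
        und = net.undirected_view()
        for _ in range(5):
            genes = {f"v{i}" for i in rng.choice(200, size=12, replace=False)}
            length, _ = characteristic_path_length(net, genes)
            dists = []
            gl = sorted(genes)
            for i, a in enumerate(gl):
                for b in gl[i + 1:]:
                    if a not in und or b not in und:
                        continue  # isolated gene: pair counts as disconnected
                    try:
                        dists.append(nx.shortest_path_length(und, a, b))
                    except nx.NetworkXNoPath:
                        pass
            assert length == pytest.approx(float(np.mean(dists)))


class TestDensity:
    def test_triangle_is_one(self, triangle_interactome):
        assert subnetwork_density(sub("ABC", triangle_interactome)) == 1.0

    def test_three_nodes_one_edge_is_third(self):
        net = Interactome([("A", "B", "PPI")])
        s = SubNetwork("s", frozenset("ABC"), net.induced_edges({"A", "B", "C"}))
        assert subnetwork_density(s) == pytest.approx(1 / 3)

    def test_parallel_typed_edges_counted_once(self):
        net = Interactome([("A", "B", "PPI"), ("A", "B", "KPI")])
        assert subnetwork_density(sub("AB", net)) == 1.0

    def test_single_gene_undefined(self):
        net = Interactome([("A", "B", "PPI")])
        with pytest.raises(ValueError):
            subnetwork_density(sub("A", net))

    def test_matches_combinatorial_count_oracle(self):
        rng = np.random.default_rng(1)
        g = nx.gnm_random_graph(30, 90, seed=2)
        net = Interactome([(f"v{a}", f"v{b}", "PPI") for a, b in g.edges()])
        for _ in range(5):
            genes = {f"v{i}" for i in rng.choice(30, size=8, replace=False)}
            e = sum(1 for a, b in g.edges()
                    if f"v{a}" in genes and f"v{b}" in genes)
            assert subnetwork_density(sub(genes, net)) == pytest.approx(
                e / comb(8, 2))


class TestInDegreeRatio:
    def test_star_center_only_is_zero(self):
        net = Interactome([("hub", f"leaf{i}", "PPI") for i in range(5)])
        assert in_degree_ratio(net, {"hub"}) == 0.0

    def test_isolated_clique_flagged_infinite(self):
        net = Interactome([("A", "B", "PPI"), ("B", "C", "PPI"),
                           ("A", "C", "PPI"), ("X", "Y", "PPI")])
        with pytest.warns(UserWarning, match="boundary"):
            assert math.isinf(in_degree_ratio(net, {"A", "B", "C"}))

    def test_matches_edge_classification_oracle(self):
        rng = np.random.default_rng(3)
        g = nx.gnm_random_graph(40, 150, seed=4)
        net = Interactome([(f"v{a}", f"v{b}", "PPI") for a, b in g.edges()])
        for _ in range(5):
            genes = {f"v{i}" for i in rng.choice(40, size=10, replace=False)}
            within = sum(1 for a, b in g.edges()
                         if (f"v{a}" in genes) and (f"v{b}" in genes))
            boundary = sum(1 for a, b in g.edges()
                           if (f"v{a}" in genes) != (f"v{b}" in genes))
            assert in_degree_ratio(net, genes) == pytest.approx(within / boundary)


class TestMaslovSneppen:
    @staticmethod
    def _degrees(net):
        out = {}
        for itype in ("PPI", "PDI", "KPI", "EEI"):
            sub_ = net.edges_of_type(itype)
            if itype in ("PDI", "KPI"):
                outd, ind = {}, {}
                for a, b, _ in sub_.itertuples(index=False, name=None):
                    outd[a] = outd.get(a, 0) + 1
                    ind[b] = ind.get(b, 0) + 1
                out[itype] = (outd, ind)
            else:
                d = {}
                for a, b, _ in sub_.itertuples(index=False, name=None):
                    d[a] = d.get(a, 0) + 1
                    d[b] = d.get(b, 0) + 1
                out[itype] = d
        return out

    def test_per_type_degree_sequences_preserved(self, small_dataset):
        net = small_dataset[2]
        rand = maslov_sneppen_randomize(net, swaps_per_edge=5, seed=0)
        assert self._degrees(rand) == self._degrees(net)
        assert len(rand) == len(net)

    def test_four_cycle_stays_simple_with_same_degrees(self):
        net = Interactome([("A", "B", "PPI"), ("B", "C", "PPI"),
                           ("C", "D", "PPI"), ("A", "D", "PPI")])
        rand = maslov_sneppen_randomize(net, swaps_per_edge=20, seed=1)
        assert len(rand) == 4
        assert self._degrees(rand)["PPI"] == self._degrees(net)["PPI"]

    def test_single_edge_type_unchanged_with_warning(self):
        net = Interactome([("A", "B", "EEI")])
        with pytest.warns(UserWarning, match="unchanged"):
            rand = maslov_sneppen_randomize(net, swaps_per_edge=10, seed=2)
        assert rand.edge_keys == net.edge_keys

    def test_mixing_drives_edge_overlap_below_half(self):
        """After 100 swaps/edge on a 6,000-edge network, most edges move."""
        from aspnet.simulate import simulate_interactome

        net = simulate_interactome(2000, {"PPI": 6000}, seed=5)
        rand = maslov_sneppen_randomize(net, swaps_per_edge=100, seed=6)
        overlap = len(net.edge_keys & rand.edge_keys) / len(net)
        assert overlap < 0.5

    def test_seed_determinism(self, small_dataset):
        net = small_dataset[2]
        r1 = maslov_sneppen_randomize(net, swaps_per_edge=3, seed=7)
        r2 = maslov_sneppen_randomize(net, swaps_per_edge=3, seed=7)
        assert r1.edge_keys == r2.edge_keys


class TestTopologyNullTest:
    def test_planted_dense_module_detected(self):
        """A planted near-clique: density Z > 3, path-length Z < -3."""
        rng = np.random.default_rng(8)
        module = [f"m{i}" for i in range(12)]
        edges = [(a, b, "PPI") for i, a in enumerate(module)
                 for b in module[i + 1:] if rng.random() < 0.8]
        others = [f"o{i}" for i in range(150)]
        nodes = module + others
        while len(edges) < 450:
            a, b = rng.choice(nodes, 2, replace=False)
            if a != b:
                edges.append((a, b, "PPI"))
        net = Interactome(edges)
        subs = {"mod": sub(module, net)}
        stats = topology_null_test(net, subs, n_random=200, swaps_per_edge=10,
                                   seed=9)["mod"]
        assert stats.z_scores["density"] > 3
        assert stats.z_scores["char_path_length"] < -3
        assert stats.p_empirical["density"] == 0.0

    def test_whole_network_density_z_near_zero(self):
        rng = np.random.default_rng(10)
        g = nx.gnm_random_graph(40, 120, seed=11)
        net = Interactome([(f"v{a}", f"v{b}", "PPI") for a, b in g.edges()])
        subs = {"all": sub({f"v{i}" for i in range(40)}, net)}
        stats = topology_null_test(net, subs, n_random=50, swaps_per_edge=5,
                                   seed=12)["all"]
        # edge swaps preserve global edge count, hence global density
        assert stats.observed["density"] == stats.null_mean["density"]

    def test_gene_resample_null_mode(self):
        g = nx.gnm_random_graph(60, 200, seed=13)
        net = Interactome([(f"v{a}", f"v{b}", "PPI") for a, b in g.edges()])
        subs = {"s": sub({f"v{i}" for i in range(8)}, net)}
        stats = topology_null_test(net, subs, n_random=30, seed=14,
                                   null="gene_resample")["s"]
        assert np.isfinite(stats.null_mean["density"])


class TestCsr:
    def test_identical_sets_give_one(self):
        assert csr({"A", "B"}, {"A", "B"}) == 1.0

    def test_disjoint_sets_give_zero(self):
        assert csr({"A"}, {"B"}) == 0.0

    def test_enumerated_half_overlap(self):
        assert csr({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_symmetry(self):
        a, b = {"A", "B", "C"}, {"B", "Z"}
        assert csr(a, b) == csr(b, a)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            csr(set(), {"A"})


class TestCsrGroupContrast:
    def test_identical_groups_not_significant(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5]
        assert csr_group_contrast(vals, vals) > 0.9

    def test_fully_separated_groups_match_exact_enumeration(self):
        """min two-sided rank-sum p for 10 vs 10 is 2 / C(20,10)."""
        lo = list(np.linspace(0.01, 0.1, 10))
        hi = list(np.linspace(0.5, 0.9, 10))
        p = csr_group_contrast(hi, lo, method="exact")
        assert p == pytest.approx(2 / comb(20, 10, exact=True))

    def test_zero_csr_values_tolerated(self):
        p = csr_group_contrast([0.0, 0.1, 0.2], [0.0, 0.3, 0.4])
        assert 0.0 < p <= 1.0
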