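import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nitronet.io_tables import CountTable
from nitronet.network import (
    CooccurrenceNetwork,
    build_network,
    classify_role,
    correlation_screen,
    detect_modules,
    module_summary,
    natural_connectivity,
    network_dissimilarity,
    paired_networks,
    prevalence_filter,
    robustness,
    topology,
    zipi,
)
from nitronet.synthetic import SyntheticConfig, generate_community


def table_from(counts, prefix="o"):
    arr = np.asarray(counts, dtype=np.int64)
    return CountTable(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])]))


class TestPrevalenceFilter:
    def test_zero_thresholds_identity(self, toy_table):
        out = prevalence_filter(toy_table, 0.0, 0.0)
        pd.testing.assert_frame_equal(out.data, toy_table.data)

    def test_rare_otu_dropped(self):
        counts = np.ones((6, 3), dtype=int) * 5
        counts[1:, 0] = 0  # o0 present in 1 of 6 samples
        table = table_from(counts)
        out = prevalence_filter(table, 0.5, 0.0)
        assert "o0" not in out.otu_ids and {"o1", "o2"} <= set(out.otu_ids)

    def test_manual_enumeration_oracle(self, rng):
        counts = rng.integers(0, 4, size=(8, 10))
        counts[:, 0] = 1  # keep totals positive
        table = table_from(counts)
        out = prevalence_filter(table, 0.4, 0.01)
        rel = counts / counts.sum(axis=1, keepdims=True)
        expect = [
            f"o{j}" for j in range(10)
            if (counts[:, j] > 0).mean() >= 0.4 and rel[:, j].mean() >= 0.01
        ]
        assert out.otu_ids == expect

    def test_all_removed_errors(self):
        table = table_from(np.eye(4, dtype=int) + 0)
        table = CountTable(table.data + pd.DataFrame(
            np.eye(4, dtype=int), index=table.data.index, columns=table.data.columns))
        with pytest.raises(ValueError, match="removed every OTU"):
            prevalence_filter(table, 1.0, 0.0)


class TestCorrelationScreen:
    def test_identical_columns_rho_one(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 50, size=8)
        counts = np.column_stack([base, base, rng.integers(1, 50, size=8)])
        screen = correlation_screen(table_from(counts), use_relative=False)
        assert screen.rho.iloc[0, 1] == pytest.approx(1.0)
        assert screen.p.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_matches_pairwise_scalar_calls(self, rng):
        counts = rng.integers(1, 80, size=(8, 6))
        table = table_from(counts)
        screen = correlation_screen(table)
        rel = table.relative_abundance()
        for i, j in itertools.combinations(range(6), 2):
            rho, p = stats.spearmanr(rel.iloc[:, i], rel.iloc[:, j])
            assert screen.rho.iloc[i, j] == pytest.approx(rho, abs=1e-12)
            assert screen.p.iloc[i, j] == pytest.approx(p, abs=1e-12)

    def test_constant_otu_flagged_and_excluded(self, rng):
        counts = rng.integers(1, 60, size=(8, 4))
        counts[:, 2] = 7
        screen = correlation_screen(table_from(counts), use_relative=False)
        assert screen.undefined_otus == ["o2"]
        assert screen.rho["o2"].isna().all()
        net = build_network(screen)
        assert "o2" not in net.graph.nodes

    def test_null_false_positive_rate(self):
        """Independent columns: the p < 0.01 screen fires on about 1% of
        pairs (checked over many replicates)."""
        rng = np.random.default_rng(7)
        hits = pairs = 0
        for _ in range(40):
            counts = rng.integers(1, 1000, size=(12, 10))
            screen = correlation_screen(table_from(counts), use_relative=False)
            p = screen.p.to_numpy()[np.triu_indices(10, k=1)]
            hits += (p < 0.01).sum()
            pairs += p.size
        assert 0.002 < hits / pairs < 0.03


class TestBuildNetwork:
    def test_boundary_rho_excluded_strictly(self):
        ids = ["a", "b", "c"]
        rho = pd.DataFrame([[1.0, 0.6, 0.95], [0.6, 1.0, 0.2], [0.95, 0.2, 1.0]],
                           index=ids, columns=ids)
        p = pd.DataFrame([[0.0, 1e-5, 1e-5], [1e-5, 0.0, 0.5], [1e-5, 0.5, 0.0]],
                         index=ids, columns=ids)
        from nitronet.network import CorrelationScreen

        screen = CorrelationScreen(ids, rho, p)
        net = build_network(screen)
        assert net.edge_set() == {frozenset(("a", "c"))}  # rho=0.6 exactly: no edge
        assert net.graph.edges["a", "c"]["sign"] == "+"

    def test_edge_criterion_exact_on_toys(self, rng):
        """Emitted edge set equals an exhaustive independent scalar scan."""
        for _ in range(5):
            counts = rng.integers(1, 100, size=(8, 6))
            table = table_from(counts)
            screen = correlation_screen(table)
            net = build_network(screen)
            rel = table.relative_abundance()
            expect = set()
            for i, j in itertools.combinations(range(6), 2):
                rho, p = stats.spearmanr(rel.iloc[:, i], rel.iloc[:, j])
                if p < 0.01 and abs(rho) > 0.6:
                    expect.add(frozenset((f"o{i}", f"o{j}")))
            assert net.edge_set() == expect

    def test_planted_block_recovery(self):
        cfg = SyntheticConfig(replicates_per_treatment=10, dominance_slope=0.0, seed=0)
        table, meta, tax, truth = generate_community(cfg)
        filt = prevalence_filter(table)
        net = build_network(correlation_screen(filt), table=filt, tax=tax)
        truth_pairs = truth.within_block_pairs()
        tp = len(net.edge_set() & truth_pairs)
        assert tp / net.n_edges >= 0.8
        assert tp / len(truth_pairs) >= 0.8


class TestPairedNetworks:
    def test_three_stated_pairs(self):
        cfg = SyntheticConfig(replicates_per_treatment=5, n_otus=40,
                              n_blocks=2, block_size=5, seed=3)
        table, meta, tax, _ = generate_community(cfg)
        pairs = [("N800", "N600"), ("N600", "N400"), ("N400", "N0")]
        nets = paired_networks(table, meta, pairs, tax=tax)
        assert len(nets) == 3
        assert nets[0].label == "Network 1: N800+N600"

    def test_identical_labels_rejected(self):
        cfg = SyntheticConfig(replicates_per_treatment=5, n_otus=30,
                              n_blocks=1, block_size=4, seed=3)
        table, meta, _, _ = generate_community(cfg)
        with pytest.raises(ValueError, match="distinct"):
            paired_networks(table, meta, [("N800", "N800")])

    def test_matches_single_pass_on_pooled_subset(self):
        cfg = SyntheticConfig(replicates_per_treatment=6, n_otus=50,
                              n_blocks=2, block_size=6, seed=4)
        table, meta, tax, _ = generate_community(cfg)
        nets = paired_networks(table, meta, [("N800", "N600"), ("N400", "N0")])
        pooled = table.subset_samples(meta.samples_of("N800", "N600"))
        direct = build_network(correlation_screen(prevalence_filter(pooled)))
        assert nets[0].edge_set() == direct.edge_set()

    def test_unknown_treatment_errors(self):
        cfg = SyntheticConfig(replicates_per_treatment=5, n_otus=30,
                              n_blocks=1, block_size=4, seed=3)
        table, meta, _, _ = generate_community(cfg)
        with pytest.raises(KeyError):
            paired_networks(table, meta, [("N800", "N9999")])


def net_of(edges) -> CooccurrenceNetwork:
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=0.9, sign="+")
    return CooccurrenceNetwork(g, 0.6, 0.01)


class TestTopology:
    def test_triangle(self):
        net = net_of([("a", "b"), ("b", "c"), ("a", "c")])
        topo, part = topology(net)
        assert topo.average_degree == pytest.approx(2.0)
        assert topo.average_clustering_coefficient == pytest.approx(1.0)
        assert topo.n_modules == 1

    def test_path(self):
        net = net_of([("a", "b"), ("b", "c")])
        topo, _ = topology(net)
        assert topo.average_clustering_coefficient == pytest.approx(0.0)
        assert topo.average_degree == pytest.approx(4 / 3)

    def test_two_cliques_bridge_modularity_hand_formula(self):
        cliq1 = [f"a{i}" for i in range(5)]
        cliq2 = [f"b{i}" for i in range(5)]
        edges = list(itertools.combinations(cliq1, 2)) + \
            list(itertools.combinations(cliq2, 2)) + [("a0", "b0")]
        net = net_of(edges)
        topo, part = topology(net)
        # partition must recover the two cliques
        assert len({part[n] for n in cliq1}) == 1
        assert len({part[n] for n in cliq2}) == 1
        assert part["a0"] != part["b0"]
        # hand evaluation of Q = sum_c (e_c/E - (d_c/2E)^2):
        # E = 21, e_c = 10, d_c = 21 per clique
        q_hand = 2 * (10 / 21 - (21 / 42) ** 2)
        assert topo.modularity == pytest.approx(q_hand, abs=1e-12)
        assert topo.n_modules == 2

    def test_edge_sign_fractions(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9, sign="+")
        g.add_edge("b", "c", weight=-0.7, sign="-")
        g.add_edge("c", "d", weight=0.8, sign="+")
        net = CooccurrenceNetwork(g, 0.6, 0.01)
        topo, _ = topology(net)
        assert topo.positive_edge_fraction == pytest.approx(2 / 3)
        assert topo.negative_edge_fraction == pytest.approx(1 / 3)

    def test_average_weighted_degree(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_edge("b", "c", weight=-0.7)
        net = CooccurrenceNetwork(g, 0.6, 0.01)
        topo, _ = topology(net)
        # |w| sums: a: 0.9, b: 1.6, c: 0.7 -> mean 3.2/3
        assert topo.average_weighted_degree == pytest.approx(3.2 / 3)

    def test_partition_deterministic(self):
        cfg = SyntheticConfig(replicates_per_treatment=8, dominance_slope=0.0, seed=5)
        table, _, _, _ = generate_community(cfg)
        net = build_network(correlation_screen(prevalence_filter(table)))
        assert detect_modules(net) == detect_modules(net)


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert natural_connectivity(g) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_closed_form(self):
        g = nx.complete_graph(3)
        expect = math.log((math.e**2 + 2 * math.e**-1) / 3)
        assert natural_connectivity(g) == pytest.approx(expect, abs=1e-9)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_spectrum(self, n):
        # K_n eigenvalues: n-1 once, -1 with multiplicity n-1
        expect = math.log((math.exp(n - 1) + (n - 1) * math.exp(-1)) / n)
        assert natural_connectivity(nx.complete_graph(n)) == pytest.approx(expect, abs=1e-9)


class TestRobustness:
    def test_zero_removal_equals_intact(self):
        g = nx.complete_graph(10)
        curve = robustness(g, fractions=[0.05], n_replicates=5, seed=0)
        row = curve.curve.iloc[0]  # floor(0.05*10) = 0 nodes removed
        assert row["nc_mean"] == natural_connectivity(g)
        assert row["nc_sd"] == 0.0

    def test_complete_graph_residual_degree_closed_form(self):
        n = 12
        g = nx.complete_graph(n)
        curve = robustness(g, fractions=[0.25, 0.5], n_replicates=10, seed=1)
        for _, row in curve.curve.iterrows():
            m = int(np.floor(row["fraction"] * n))
            # any removal of m nodes from K_n leaves K_{n-m}
            assert row["degree_mean"] == pytest.approx(n - 1 - m, abs=1e-12)
            assert row["degree_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_degradation_on_dense_graph(self):
        rng = np.random.default_rng(2)
        g = nx.gnp_random_graph(40, 0.4, seed=3)
        curve = robustness(g, fractions=[0.1, 0.3, 0.5], n_replicates=50, seed=4)
        nc = curve.curve.set_index("fraction")["nc_mean"]
        assert nc[0.1] > nc[0.3] > nc[0.5]

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(20, 0.3, seed=5)
        c1 = robustness(g, fractions=[0.2], n_replicates=20, seed=9)
        c2 = robustness(g, fractions=[0.2], n_replicates=20, seed=9)
        pd.testing.assert_frame_equal(c1.curve, c2.curve)

    def test_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            robustness(nx.complete_graph(4), fractions=[1.0], n_replicates=1, seed=0)


def brute_force_zipi(edges, partition):
    """Independent recomputation of Zi/Pi from the raw edge list."""
    nodes = sorted({u for e in edges for u in e})
    neigh = {v: set() for v in nodes}
    for u, v in edges:
        neigh[u].add(v)
        neigh[v].add(u)
    within = {v: sum(1 for u in neigh[v] if partition[u] == partition[v]) for v in nodes}
    out = {}
    for v in nodes:
        members = [u for u in nodes if partition[u] == partition[v]]
        ks = [within[u] for u in members]
        mu = sum(ks) / len(ks)
        sd = math.sqrt(sum((k - mu) ** 2 for k in ks) / len(ks))
        zi = 0.0 if (sd == 0 or len(members) < 2) else (within[v] - mu) / sd
        k_tot = len(neigh[v])
        if k_tot == 0:
            pi = 0.0
        else:
            per = {}
            for u in neigh[v]:
                per[partition[u]] = per.get(partition[u], 0) + 1
            pi = 1.0 - sum((c / k_tot) ** 2 for c in per.values())
        out[v] = (zi, pi)
    return out


class TestZiPi:
    def two_clique_bridge(self):
        cliq1 = [f"a{i}" for i in range(6)]
        cliq2 = [f"b{i}" for i in range(6)]
        edges = list(itertools.combinations(cliq1, 2)) + \
            list(itertools.combinations(cliq2, 2)) + [("a0", "b0")]
        partition = {v: 0 for v in cliq1} | {v: 1 for v in cliq2}
        return edges, partition

    def test_all_internal_edges_pi_zero(self):
        edges, partition = self.two_clique_bridge()
        res = zipi(net_of(edges), partition).set_index("otu_id")
        assert res.loc["a3", "pi"] == pytest.approx(0.0)

    def test_two_module_split_pi_half(self):
        g = nx.Graph([("x", "m1"), ("x", "m2")])
        partition = {"x": 0, "m1": 0, "m2": 1}
        res = zipi(g, partition).set_index("otu_id")
        assert res.loc["x", "pi"] == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        edges, partition = self.two_clique_bridge()
        res = zipi(net_of(edges), partition).set_index("otu_id")
        oracle = brute_force_zipi(edges, partition)
        for v, (zi_e, pi_e) in oracle.items():
            assert res.loc[v, "zi"] == pytest.approx(zi_e, abs=1e-12)
            assert res.loc[v, "pi"] == pytest.approx(pi_e, abs=1e-12)
            assert res.loc[v, "role"] == classify_role(zi_e, pi_e)

    def test_role_thresholds(self):
        assert classify_role(2.6, 0.7) == "network hub"
        assert classify_role(2.6, 0.62) == "module hub"   # Pi boundary inclusive below
        assert classify_role(2.5, 0.7) == "connector"     # Zi boundary inclusive below
        assert classify_role(0.0, 0.0) == "peripheral"

    def test_missing_partition_entry_errors(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(KeyError):
            zipi(g, {"a": 0})


class TestNetworkComparison:
    def test_identical_networks(self):
        net = net_of([("a", "b"), ("b", "c")])
        assert network_dissimilarity(net, net) == (0.0, 0.0)

    def test_disjoint_networks(self):
        a = net_of([("a", "b")])
        b = net_of([("x", "y")])
        assert network_dissimilarity(a, b) == (1.0, 1.0)

    def test_set_arithmetic_example(self):
        # nodes {a,b,c} vs {a,b,d}: 2 shared of 4; edges share 1 of 5
        a = net_of([("a", "b"), ("b", "c"), ("a", "c")])
        b = net_of([("a", "b"), ("b", "d"), ("a", "d")])
        nd, ed = network_dissimilarity(a, b)
        assert nd == pytest.approx(0.5)
        assert ed == pytest.approx(0.8)


class TestModuleSummary:
    def test_single_module_no_inter_links(self):
        net = net_of([("a", "b"), ("b", "c")])
        summary, inter = module_summary(net, {"a": 0, "b": 0, "c": 0})
        assert summary["size"].tolist() == [3]
        assert (inter.to_numpy() == 0).all()

    def test_bridge_counted_once(self):
        edges, partition = TestZiPi().two_clique_bridge()
        _, inter = module_summary(net_of(edges), partition)
        assert inter.loc[0, 1] == 1 and inter.loc[1, 0] == 1

    def test_phylum_richness_recount(self):
        cfg = SyntheticConfig(replicates_per_treatment=10, dominance_slope=0.0, seed=1)
        table, _, tax, _ = generate_community(cfg)
        net = build_network(correlation_screen(prevalence_filter(table)), tax=tax)
        partition = detect_modules(net)
        summary, _ = module_summary(net, partition, tax)
        by_module = {}
        for node, mod in partition.items():
            by_module.setdefault(mod, set()).add(tax.rank_of(node, "phylum"))
        for _, row in summary.iterrows():
            assert row["phylum_richness"] == len(by_module[row["module_id"]])
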