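import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from droughtnet import networks


def records(rows):
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "q", "link_class"])


def brute_force_zi_pi(net, partition):
    """Double-loop oracle for within-module degree z-score and participation."""
    out = {}
    for node in net.nodes:
        k = net.degree(node)
        counts = {}
        for nb in net.neighbors(node):
            counts[partition[nb]] = counts.get(partition[nb], 0) + 1
        pi = 1 - sum((c / k) ** 2 for c in counts.values())
        out[node] = {"kappa": counts.get(partition[node], 0), "Pi": pi}
    for node in net.nodes:
        mod = partition[node]
        kappas = [out[n]["kappa"] for n in net.nodes if partition[n] == mod]
        sd = np.std(kappas)
        out[node]["Zi"] = 0.0 if sd == 0 else (out[node]["kappa"] - np.mean(kappas)) / sd
    return out


def modularity_formula(g, partition):
    """Q = sum_c [e_c/m - (d_c/2m)^2] computed directly from the formula."""
    m = g.number_of_edges()
    q = 0.0
    for mod in set(partition.values()):
        nodes = {n for n, c in partition.items() if c == mod}
        e_c = sum(1 for u, v in g.edges if u in nodes and v in nodes)
        d_c = sum(g.degree(n) for n in nodes)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def exhaustive_best_partition(g):
    """Enumerate all partitions (<= 8 nodes) and return the best Q."""
    nodes = list(g.nodes)
    best = -np.inf

    def gen(parts, rest):
        nonlocal best
        if not rest:
            partition = {n: i for i, p in enumerate(parts) for n in p}
            best = max(best, modularity_formula(g, partition))
            return
        head, *tail = rest
        for p in parts:
            p.append(head)
            gen(parts, tail)
            p.pop()
        gen(parts + [[head]], tail)

    gen([], nodes)
    return best


class TestBuildNetwork:
    def test_filter_arithmetic(self):
        recs = records([
            ("a", "b", 0.7, 0.01, "BB"),
            ("a", "c", 0.65, 0.2, "BB"),
            ("b", "c", -0.8, 0.001, "BB"),
            ("c", "d", 0.55, 0.01, "BB"),
        ])
        net = networks.build_network(recs)
        assert net.number_of_edges() == 1 and net.has_edge("a", "b")

    def test_rho_boundary_strict(self):
        recs = records([("a", "b", 0.6, 0.001, "BB")])
        assert networks.build_network(recs).number_of_edges() == 0

    def test_all_q_one_empty(self):
        recs = records([("a", "b", 0.9, 1.0, "BB")])
        net = networks.build_network(recs)
        assert net.number_of_nodes() == 0

    def test_isolated_taxa_not_vertices(self):
        recs = records([("a", "b", 0.9, 0.01, "BB"), ("c", "d", 0.1, 0.01, "BB")])
        net = networks.build_network(recs)
        assert set(net.nodes) == {"a", "b"}

    def test_monotone_in_thresholds(self, rng):
        rows = [(f"t{i}", f"t{j}", rng.uniform(-1, 1), rng.uniform(0, 1), "BB")
                for i, j in itertools.combinations(range(12), 2)]
        recs = records(rows)
        loose = networks.build_network(recs, rho_min=0.3, q_max=0.3)
        tight_rho = networks.build_network(recs, rho_min=0.5, q_max=0.3)
        tight_q = networks.build_network(recs, rho_min=0.3, q_max=0.1)
        loose_edges = {frozenset(e) for e in loose.edges}
        for tight in (tight_rho, tight_q):
            assert {frozenset(e) for e in tight.edges} <= loose_edges


class TestSizeStats:
    def test_empty_network_zeros(self):
        assert networks.size_stats(nx.Graph())["n_edges"] == 0

    def test_single_bb_edge(self):
        recs = records([("a", "b", 0.9, 0.01, "BB")])
        tax = pd.DataFrame({"kingdom": ["bacteria", "bacteria"]}, index=["a", "b"])
        stats = networks.size_stats(networks.build_network(recs, tax))
        assert stats["vertices_per_kingdom"]["bacteria"] == 2
        assert stats["edges_per_class"]["BB"] == 1

    def test_sums_consistent(self, rng):
        rows = [(f"t{i}", f"t{j}", 0.9, 0.01, rng.choice(["BB", "FF", "BF"]))
                for i, j in itertools.combinations(range(8), 2)]
        net = networks.build_network(records(rows))
        stats = networks.size_stats(net)
        assert sum(stats["edges_per_class"].values()) == stats["n_edges"]


class TestGreedyModules:
    def two_triangles(self):
        g = nx.Graph(rho_min=0.6, q_max=0.05)
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        return g

    def test_two_disjoint_triangles(self):
        partition, q = networks.greedy_modules(self.two_triangles())
        assert q == pytest.approx(0.5)
        assert {partition["a"], partition["b"], partition["c"]} == {partition["a"]}
        assert partition["a"] != partition["x"]

    def test_single_edge_q_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        _, q = networks.greedy_modules(g)
        assert q == pytest.approx(0.0)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            networks.greedy_modules(nx.Graph())

    def test_q_matches_formula_and_beats_trivial_partition(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            partition, q = networks.greedy_modules(g)
            assert q == pytest.approx(modularity_formula(g, partition))
            trivial = {n: 0 for n in g.nodes}
            assert q >= modularity_formula(g, trivial) - 1e-12

    def test_greedy_near_exhaustive_optimum_on_planted_graphs(self, rng):
        """On small two-block graphs greedy reaches >= 95% of the best Q
        over all partitions."""
        for trial in range(20):
            g = nx.planted_partition_graph(2, 4, 0.9, 0.1,
                                           seed=int(rng.integers(1e6)))
            g = nx.Graph(g)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                continue
            _, q = networks.greedy_modules(g)
            best = exhaustive_best_partition(g)
            assert q >= 0.95 * best - 1e-9

    def test_deterministic(self):
        g = self.two_triangles()
        assert networks.greedy_modules(g) == networks.greedy_modules(g)


class TestZiPi:
    def test_connector_hand_example(self):
        """Node with 3 edges split over 3 modules: Pi = 1 - 3*(1/3)^2 = 2/3."""
        g = nx.Graph()
        g.add_edges_from([("hub", "a"), ("hub", "b"), ("hub", "c"),
                          ("a", "a2"), ("b", "b2"), ("c", "c2")])
        partition = {"hub": 0, "a": 0, "a2": 0, "b": 1, "b2": 1, "c": 2, "c2": 2}
        topo = networks.zi_pi(g, partition)
        assert topo.loc["hub", "Pi"] == pytest.approx(2 / 3)

    def test_internal_node_pi_zero(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")])
        topo = networks.zi_pi(g, {"a": 0, "b": 0, "c": 0})
        assert (topo["Pi"] == 0).all()

    def test_equal_kappa_module_zi_zero(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        topo = networks.zi_pi(g, {"a": 0, "b": 0, "c": 0})
        assert (topo["Zi"] == 0).all() and topo["zi_degenerate"].all()

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 31))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1e9)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            partition = {node: int(rng.integers(0, 4)) for node in g.nodes}
            topo = networks.zi_pi(g, partition)
            oracle = brute_force_zi_pi(g, partition)
            for node in g.nodes:
                assert topo.loc[node, "Zi"] == pytest.approx(oracle[node]["Zi"], abs=1e-9)
                assert topo.loc[node, "Pi"] == pytest.approx(oracle[node]["Pi"], abs=1e-9)

    def test_partition_must_cover(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(ValueError):
            networks.zi_pi(g, {"a": 0})


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi, pi, role",
        [
            (2.54, 0.30, "module_hub"),   # module hub above the Zi cut
            (0.5, 0.643, "connector"),    # connector above the Pi cut
            (0.0, 0.0, "peripheral"),
            (3.0, 0.7, "network_hub"),
            (2.5, 0.62, "peripheral"),    # boundaries are strict
        ],
    )
    def test_threshold_rules(self, zi, pi, role):
        topo = pd.DataFrame({"Zi": [zi], "Pi": [pi]}, index=["n"])
        assert networks.classify_roles(topo).loc["n", "role"] == role


class TestGuildComposition:
    def annotated_net(self, guilds, edges):
        g = nx.Graph()
        for (u, v) in edges:
            g.add_edge(u, v)
        for node, guild in guilds.items():
            g.add_node(node, guild=guild)
        return g

    def test_all_within_one_guild(self):
        net = self.annotated_net(
            {"a": "saprotroph", "b": "saprotroph", "c": "saprotroph"},
            [("a", "b"), ("b", "c")],
        )
        out = networks.guild_edge_composition(net)
        assert out["proportion_between"] == 0

    def test_complete_bipartite_between_guilds(self):
        net = self.annotated_net(
            {"a": "saprotroph", "b": "saprotroph", "x": "pathogen", "y": "pathogen"},
            [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")],
        )
        out = networks.guild_edge_composition(net)
        assert out["proportion_between"] == 1

    def test_proportions_sum_to_one_excluding_unassigned(self):
        net = self.annotated_net(
            {"a": "saprotroph", "b": "pathogen", "c": ""},
            [("a", "b"), ("a", "c")],
        )
        out = networks.guild_edge_composition(net)
        assert out["unassigned"] == 1
        assert out["proportion_within"] + out["proportion_between"] == 1

    def test_new_edges_difference(self):
        before = nx.Graph([("a", "b")])
        after = nx.Graph([("a", "b"), ("b", "c")])
        assert networks.new_edges(before, after) == [("b", "c")]


class TestAmfSubnetwork:
    def build(self):
        recs = records([
            ("amf1", "amf2", 0.9, 0.01, "FF"),
            ("amf1", "f1", 0.8, 0.01, "FF"),
            ("amf1", "b1", 0.7, 0.01, "BF"),
            ("f1", "b1", 0.9, 0.01, "BF"),
        ])
        tax = pd.DataFrame(
            {
                "kingdom": ["fungi", "fungi", "fungi", "bacteria"],
                "amf": [True, True, False, False],
            },
            index=["amf1", "amf2", "f1", "b1"],
        )
        return networks.build_network(recs, tax)

    def test_partition_of_amf_edges(self):
        a, b, amf_amf = networks.amf_subnetwork(self.build())
        assert set(a.edges) == {("amf1", "f1")}
        assert set(b.edges) == {("amf1", "b1")}
        assert amf_amf == 1

    def test_counts_bounded_by_amf_incident_edges(self):
        net = self.build()
        a, b, amf_amf = networks.amf_subnetwork(net)
        incident = sum(1 for u, v in net.edges
                       if net.nodes[u].get("amf") or net.nodes[v].get("amf"))
        assert a.number_of_edges() + b.number_of_edges() <= incident


class TestCompareNetworks:
    def test_identical_networks_unchanged(self):
        recs = records([("a", "b", 0.9, 0.01, "BB")])
        n1 = networks.build_network(recs)
        n2 = networks.build_network(recs)
        out = networks.compare_networks(n1, n2)
        assert (out["status"] == "unchanged").all()

    def test_edge_loss_disrupted(self):
        full = records([("a", "b", 0.9, 0.01, "BB"), ("c", "d", 0.9, 0.01, "FF")])
        empty = records([("a", "b", 0.9, 1.0, "BB")])
        out = networks.compare_networks(
            networks.build_network(full), networks.build_network(empty)
        ).set_index("link_class")
        assert out.loc["BB", "status"] == "disrupted"
        assert out.loc["FF", "status"] == "disrupted"

    def test_threshold_mismatch_rejected(self):
        recs = records([("a", "b", 0.9, 0.01, "BB")])
        n1 = networks.build_network(recs, rho_min=0.6)
        n2 = networks.build_network(recs, rho_min=0.5)
        with pytest.raises(ValueError, match="rho_min"):
            networks.compare_networks(n1, n2)


class TestExport:
    def test_graphml_and_tsvs_written(self, tmp_path):
        recs = records([("a", "b", 0.9, 0.01, "BB"), ("b", "c", 0.8, 0.01, "BB")])
        net = networks.build_network(recs)
        networks.export_network(net, tmp_path / "net")
        assert (tmp_path / "net.graphml").exists()
        edges = pd.read_csv(tmp_path / "net_edges.tsv", sep="\t")
        assert len(edges) == 2
        nodes = pd.read_csv(tmp_path / "net_nodes.tsv", sep="\t")
        assert {"Zi", "Pi", "role"} <= set(nodes.columns)
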