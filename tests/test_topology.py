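import networkx as nx
import numpy as np
import pytest

from meshnet.network import build_bipartite, project_concepts
from meshnet.topology import compute_node_stats, core_periphery, top_ranked


def _weighted(g):
    nx.set_edge_attributes(g, 1, "weight")
    return g


@pytest.fixture
def star6():
    return _weighted(nx.star_graph(5))  # center 0, leaves 1..5


def test_star_graph_closed_form(star6):
    report = compute_node_stats(star6)
    by_label = {ns.label: ns for ns in report.nodes}
    assert by_label["0"].k == 5 and by_label["0"].R == 1
    assert all(by_label[str(i)].k == 1 for i in range(1, 6))
    assert report.density == pytest.approx(1 / 3)
    assert by_label["0"].betweenness == pytest.approx(1.0)
    assert by_label["0"].closeness == pytest.approx(1.0)


def test_complete_graph_closed_form():
    report = compute_node_stats(_weighted(nx.complete_graph(7)))
    assert all(ns.k == 6 for ns in report.nodes)
    assert report.density == pytest.approx(1.0)
    assert report.mean_clustering == pytest.approx(1.0)
    assert all(ns.clustering == pytest.approx(1.0) for ns in report.nodes)


def test_toy_degrees_and_tie_broken_ranks(toy_corpus):
    """Equal-degree nodes get distinct ranks, ties broken by label order."""
    net = project_concepts(build_bipartite(toy_corpus))
    report = compute_node_stats(net)
    got = {ns.label: (ns.k, ns.R) for ns in report.nodes}
    assert got == {
        "Humans": (4, 1),
        "Culture": (3, 2),           # ties with Health Equity; "C" < "H"
        "Health Equity": (3, 3),
        "Trust": (2, 4),             # ties with Vulnerable Populations
        "Vulnerable Populations": (2, 5),
    }
    # strength = sum of incident co-occurrence weights
    assert {ns.label: ns.strength for ns in report.nodes}["Humans"] == 7


def test_empty_network_rejected():
    with pytest.raises(ValueError):
        compute_node_stats(nx.Graph())


def test_isolated_node_closeness_zero():
    g = nx.Graph()
    g.add_node("lonely")
    g.add_edge("a", "b", weight=1)
    report = compute_node_stats(g)
    assert {ns.label: ns.closeness for ns in report.nodes}["lonely"] == 0.0
    assert report.n_components == 2


def test_handshake_and_histogram_on_random_graphs():
    for seed in range(5):
        g = _weighted(nx.gnp_random_graph(30, 0.15, seed=seed))
        report = compute_node_stats(g)
        assert sum(ns.k for ns in report.nodes) == 2 * report.n_edges
        assert sum(report.degree_histogram.values()) == report.n_nodes


def test_rank_is_bijection_and_order_independent():
    rng = np.random.default_rng(0)
    for seed in range(5):
        g = _weighted(nx.gnp_random_graph(25, 0.2, seed=seed))
        report = compute_node_stats(g)
        ranks = [ns.R for ns in report.nodes]
        assert sorted(ranks) == list(range(1, 26))
        ks = [ns.k for ns in report.nodes]
        assert all(a >= b for a, b in zip(ks, ks[1:]))
        # rebuild with permuted node insertion order: identical label→R map
        perm = rng.permutation(list(g.nodes))
        h = nx.Graph()
        h.add_nodes_from(perm.tolist())
        h.add_edges_from(g.edges(data=True))
        report2 = compute_node_stats(h)
        assert {n.label: n.R for n in report2.nodes} == {n.label: n.R for n in report.nodes}


def test_top_ranked_contract(toy_corpus):
    net = project_concepts(build_bipartite(toy_corpus))
    report = compute_node_stats(net)
    assert top_ranked(report, 1)[0].label == "Humans"
    assert len(top_ranked(report, 20)) == 5  # n > |V| → all nodes
    assert [ns.R for ns in top_ranked(report, 3)] == [1, 2, 3]
    with pytest.raises(ValueError):
        top_ranked(report, 0)


class TestCorePeriphery:
    def test_star_top_decile_is_center_only(self, star6):
        labels = core_periphery(compute_node_stats(star6), 0.1)
        assert labels["0"] == "core"
        assert sum(v == "core" for v in labels.values()) == 1

    def test_toy_quantile_04(self, toy_corpus):
        net = project_concepts(build_bipartite(toy_corpus))
        labels = core_periphery(compute_node_stats(net), 0.4)
        core = {lab for lab, side in labels.items() if side == "core"}
        assert core == {"Humans", "Culture", "Health Equity"}
        assert set(labels) == set(str(n) for n in net.nodes)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_quantile_rejected(self, toy_corpus, q):
        net = project_concepts(build_bipartite(toy_corpus))
        with pytest.raises(ValueError):
            core_periphery(compute_node_stats(net), q)


def test_mean_degree_of_random_graphs_matches_expectation():
    """On G(n, p), mean degree ≈ (n−1)p within sampling tolerance."""
    n, p = 200, 0.1
    means = []
    for seed in range(10):
        g = _weighted(nx.gnp_random_graph(n, p, seed=seed))
        report = compute_node_stats(g)
        means.append(2 * report.n_edges / n)
    expected = (n - 1) * p
    sd_mean = np.sqrt((n - 1) * p * (1 - p) * 2 / n / 10)  # crude but generous
    assert abs(np.mean(means) - expected) < 5 * sd_mean


def test_report_exports(tmp_path, toy_corpus):
    net = project_concepts(build_bipartite(toy_corpus))
    report = compute_node_stats(net)
    csv_path = tmp_path / "nodes.csv"
    json_path = tmp_path / "global.json"
    report.write_csv(csv_path)
    report.write_global_json(json_path)
    header = csv_path.read_text().splitlines()[0]
    assert header == "label,k,R,strength,betweenness,closeness,clustering"
    import json

    stats = json.loads(json_path.read_text())
    assert stats["n_nodes"] == 5 and stats["n_edges"] == 7
    assert stats["density"] == pytest.approx(0.7)
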