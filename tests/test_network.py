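import networkx as nx
import numpy as np
import pytest
from scipy import stats

from metoxkit import network
from metoxkit.network import (
    UndefinedAssortativity,
    assortativity,
    build_graph,
    jaccard,
    relabel_null,
    subsample_null,
)
from metoxkit.io import ProteinRecord


def protein(pid, terms, group="ex_vivo"):
    return ProteinRecord(id=pid, sequence="M", group=group,
                         go_terms=frozenset(terms))


def labeled_graph(edges, labels):
    g = nx.Graph()
    for node, label in labels.items():
        g.add_node(node, label=label)
    g.add_edges_from(edges)
    return g


def pearson_over_edge_ends(graph):
    """Oracle: correlate endpoint labels over the ordered edge-end list."""
    labels = nx.get_node_attributes(graph, "label")
    values = sorted(set(labels.values()))
    num = {v: i for i, v in enumerate(values)}
    xs, ys = [], []
    for u, v in graph.edges:
        xs += [num[labels[u]], num[labels[v]]]
        ys += [num[labels[v]], num[labels[u]]]
    return stats.pearsonr(xs, ys).statistic


class TestJaccard:
    @pytest.mark.parametrize(
        "si,sj,expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a", "b", "c", "d"}, {"c", "d", "e", "f"}, 1 / 3),
            (set(), {"a"}, 0.0),
            (set(), set(), 0.0),
        ],
    )
    def test_values(self, si, sj, expected):
        assert jaccard(si, sj) == pytest.approx(expected)
        assert jaccard(sj, si) == pytest.approx(expected)


class TestBuildGraph:
    def test_full_overlap_gives_edge(self):
        g = build_graph([protein("P1", {"a", "b"}), protein("P2", {"a", "b"})])
        assert set(g.edges) == {("P1", "P2")}

    def test_threshold_is_inclusive_at_half(self):
        # Jaccard exactly 0.5: {a,b,c} vs {a,b,c,d,e,f} -> 3/6
        g = build_graph(
            [protein("P1", {"a", "b", "c"}),
             protein("P2", {"a", "b", "c", "d", "e", "f"})]
        )
        assert g.has_edge("P1", "P2")

    def test_no_shared_terms_edgeless_isolated_kept(self):
        g = build_graph([protein("P1", {"a"}), protein("P2", {"b"}),
                         protein("P3", set())])
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 3

    def test_matches_pairwise_jaccard(self):
        rng = np.random.default_rng(4)
        prots = [
            protein(f"P{i}", set(rng.choice(12, size=rng.integers(1, 7),
                                            replace=False).tolist()))
            for i in range(25)
        ]
        g = build_graph(prots)
        for i, pi in enumerate(prots):
            for pj in prots[i + 1:]:
                expected = jaccard(pi.go_terms, pj.go_terms) >= 0.5
                assert g.has_edge(pi.id, pj.id) == expected


class TestAssortativity:
    def test_perfectly_assortative(self):
        g = labeled_graph([(1, 2), (3, 4)], {1: "r", 2: "r", 3: "b", 4: "b"})
        assert assortativity(g) == pytest.approx(1.0)

    def test_perfectly_disassortative(self):
        g = labeled_graph([(1, 3), (2, 4)], {1: "r", 2: "r", 3: "b", 4: "b"})
        assert assortativity(g) == pytest.approx(-1.0)

    def test_red_red_blue_path(self):
        # brute-force Pearson over the 4 edge ends gives -1/3
        g = labeled_graph([(1, 2), (2, 3)], {1: "r", 2: "r", 3: "b"})
        assert assortativity(g) == pytest.approx(-1 / 3)
        assert assortativity(g) == pytest.approx(pearson_over_edge_ends(g))

    def test_label_swap_invariance(self):
        g = labeled_graph([(1, 2), (2, 3), (3, 4)],
                          {1: "r", 2: "b", 3: "b", 4: "r"})
        swapped = labeled_graph([(1, 2), (2, 3), (3, 4)],
                                {1: "b", 2: "r", 3: "r", 4: "b"})
        assert assortativity(g) == pytest.approx(assortativity(swapped))

    def test_undefined_when_single_label(self):
        g = labeled_graph([(1, 2)], {1: "r", 2: "r"})
        with pytest.raises(UndefinedAssortativity):
            assortativity(g)
        with pytest.raises(UndefinedAssortativity):
            assortativity(labeled_graph([], {1: "r", 2: "b"}))

    def test_matches_independent_references_on_random_graphs(self):
        """Dual route: equals networkx's attribute assortativity, the
        edge-end Pearson correlation, and the two-type trace formula
        (tr e - sum a_i^2) / (1 - sum a_i^2) on 100 random graphs."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            labels = {i: ("r" if rng.random() < 0.5 else "b") for i in g.nodes}
            nx.set_node_attributes(g, labels, "label")
            try:
                r = assortativity(g)
            except UndefinedAssortativity:
                continue
            checked += 1
            assert r == pytest.approx(
                nx.attribute_assortativity_coefficient(g, "label"), abs=1e-12
            )
            assert r == pytest.approx(pearson_over_edge_ends(g), abs=1e-9)
            m = g.number_of_edges()
            n_rr = sum(labels[u] == labels[v] == "r" for u, v in g.edges)
            n_bb = sum(labels[u] == labels[v] == "b" for u, v in g.edges)
            e = np.array(
                [[n_bb / m, (m - n_rr - n_bb) / (2 * m)],
                 [(m - n_rr - n_bb) / (2 * m), n_rr / m]]
            )
            a = e.sum(axis=1)
            assert r == pytest.approx(
                (np.trace(e) - (a ** 2).sum()) / (1 - (a ** 2).sum()), abs=1e-12
            )


class TestRelabelNull:
    @pytest.fixture
    def assortative_graph(self):
        rng = np.random.default_rng(3)
        g = nx.Graph()
        labels = {}
        for block, label in [(0, "ex_vivo"), (1, "in_vitro")]:
            nodes = [block * 20 + i for i in range(20)]
            for n in nodes:
                labels[n] = label
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    if rng.random() < 0.3:
                        g.add_edge(u, v)
        nx.set_node_attributes(g, labels, "label")
        return g

    def test_observed_perfect_assortativity_extreme_p(self, assortative_graph):
        null = relabel_null(assortative_graph, n_iter=999, seed=0)
        assert null.observed == pytest.approx(1.0)
        assert null.p_upper == pytest.approx(1 / 1000)

    def test_null_centered_near_zero(self, assortative_graph):
        # a permutation null on a finite graph centers at about -1/(n-1),
        # just below zero, and tightens to that value as n_iter grows
        null = relabel_null(assortative_graph, n_iter=2000, seed=1)
        n_nodes = assortative_graph.number_of_nodes()
        center = -1 / (n_nodes - 1)
        sd = null.values.std()
        assert abs(null.values.mean() - center) < 3 * sd / np.sqrt(2000) + 0.01

    def test_calibration_p_uniform_when_labels_random(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        ps = []
        for seed in range(40):
            labels = {i: ("ex" if rng.random() < 0.5 else "vt") for i in g.nodes}
            nx.set_node_attributes(g, labels, "label")
            try:
                null = relabel_null(g, n_iter=199, seed=seed)
            except UndefinedAssortativity:
                continue
            ps.append(null.p_upper)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bernoulli_mode_runs(self, assortative_graph):
        null = relabel_null(assortative_graph, n_iter=200, seed=0,
                            mode="bernoulli")
        assert null.n_resamples + null.n_skipped == 200


class TestSubsampleNull:
    def test_planted_assortativity_beats_subsample_null(
        self, default_dataset, default_groups
    ):
        _, proteome, _, _ = default_dataset
        a, b = default_groups
        observed_graph = build_graph(a + b)
        r = assortativity(observed_graph)
        full = build_graph(proteome)
        null = subsample_null(full, n_red=len(a), n_blue=len(b),
                              n_iter=300, seed=1, observed=r)
        assert r > null.values.max()
        assert null.p_upper == pytest.approx(1 / (null.n_resamples + 1))

    def test_null_mean_slightly_negative(self, default_dataset):
        # random labelings of a finite graph sit just below r = 0
        _, proteome, _, _ = default_dataset
        full = build_graph(proteome)
        null = subsample_null(full, n_red=400, n_blue=200, n_iter=300, seed=2,
                              observed=0.0)
        assert -0.05 < null.values.mean() < 0.0

    def test_edgeless_proteome_graph_all_undefined(self):
        g = nx.empty_graph(30)
        with pytest.raises(UndefinedAssortativity):
            subsample_null(g, n_red=10, n_blue=5, n_iter=20, seed=0, observed=0.5)
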