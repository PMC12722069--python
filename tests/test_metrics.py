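"""Network descriptives and weighted assortativity against independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from kinnet.fusion import FusedEdge, HouseholdNetwork, Node, NodeRegistry
from kinnet.kinship import CanonicalRelation
from kinnet.metrics import (
    assortativity_categorical,
    assortativity_numeric,
    category_means,
    cohort_assortativity,
    plot_network,
    summarize_networks,
)


def toy_network(nodes, edges, hh="H"):
    """nodes: {id: dict(age=..., sex=..., health=..., effort=...)};
    edges: [(a, b, weight)] -- the weight fills every rating."""
    reg = NodeRegistry(hh)
    for nid, attrs in nodes.items():
        rel = CanonicalRelation.from_label("other", sex=attrs.get("sex"))
        n = Node(f"{hh}:{nid}", rel, False, None, attrs.get("sex"), attrs.get("age"))
        if "health" in attrs:
            n.perceived_health_vals = [attrs["health"]]
        if "effort" in attrs:
            n.perceived_effort_vals = [attrs["effort"]]
        reg.nodes[n.node_id] = n
    es = [
        FusedEdge(f"{hh}:{a}", f"{hh}:{b}", w, w, w, w, w, 1)
        for a, b, w in edges
    ]
    return HouseholdNetwork(registry=reg, edges=es)


def nx_multigraph_oracle(nodes, edges, attr, numeric=True):
    """Independent weighted oracle: replicate each edge `weight` times in a
    MultiGraph and apply networkx's unweighted estimator."""
    G = nx.MultiGraph()
    for nid, attrs in nodes.items():
        G.add_node(nid, **attrs)
    for a, b, w in edges:
        for _ in range(int(w)):
            G.add_edge(a, b)
    if numeric:
        return nx.numeric_assortativity_coefficient(G, attr)
    return nx.attribute_assortativity_coefficient(G, attr)


class TestNumericAssortativity:
    def test_path_graph_equal_weights(self):
        """P3 with ages 1,2,3: ordered-pair Pearson correlation is exactly 0."""
        net = toy_network(
            {0: dict(age=1.0), 1: dict(age=2.0), 2: dict(age=3.0)},
            [(0, 1, 1), (1, 2, 1)],
        )
        assert assortativity_numeric(net, "age") == pytest.approx(0.0, abs=1e-12)

    def test_triangle_equal_weights(self):
        """K3 with ages 1,2,3 has coefficient -1/2 (hand computation)."""
        net = toy_network(
            {0: dict(age=1.0), 1: dict(age=2.0), 2: dict(age=3.0)},
            [(0, 1, 1), (1, 2, 1), (0, 2, 1)],
        )
        assert assortativity_numeric(net, "age") == pytest.approx(-0.5)

    def test_zero_variance_undefined(self):
        net = toy_network(
            {0: dict(age=5.0), 1: dict(age=5.0)}, [(0, 1, 3)]
        )
        assert np.isnan(assortativity_numeric(net, "age"))

    def test_zero_total_weight_undefined(self):
        net = toy_network({0: dict(age=1.0), 1: dict(age=2.0)}, [(0, 1, 0)])
        assert np.isnan(assortativity_numeric(net, "age"))

    def test_weight_scaling_invariance(self):
        nodes = {i: dict(age=float(i * i % 7)) for i in range(5)}
        edges = [(0, 1, 2.0), (1, 2, 1.0), (2, 3, 3.0), (3, 4, 1.5), (0, 4, 2.5)]
        r1 = assortativity_numeric(toy_network(nodes, edges), "age")
        r2 = assortativity_numeric(
            toy_network(nodes, [(a, b, 2.5 * w) for a, b, w in edges]), "age"
        )
        assert r1 == pytest.approx(r2)

    def test_node_relabelling_invariance(self):
        nodes = {i: dict(age=float(i)) for i in range(4)}
        edges = [(0, 1, 2), (1, 2, 1), (2, 3, 3)]
        perm = {0: 3, 1: 0, 2: 2, 3: 1}
        r1 = assortativity_numeric(toy_network(nodes, edges), "age")
        r2 = assortativity_numeric(
            toy_network(
                {perm[i]: a for i, a in nodes.items()},
                [(perm[a], perm[b], w) for a, b, w in edges],
            ),
            "age",
        )
        assert r1 == pytest.approx(r2)


class TestCategoricalAssortativity:
    def test_perfectly_assortative(self):
        net = toy_network(
            {0: dict(sex="m"), 1: dict(sex="m"), 2: dict(sex="f"), 3: dict(sex="f")},
            [(0, 1, 2), (2, 3, 5)],
        )
        assert assortativity_categorical(net, "sex") == pytest.approx(1.0)

    def test_complete_bipartite_disassortative(self):
        """K_{2,3} across sexes with equal weights: mixing matrix gives -1."""
        nodes = {0: dict(sex="m"), 1: dict(sex="m"),
                 2: dict(sex="f"), 3: dict(sex="f"), 4: dict(sex="f")}
        edges = [(a, b, 1) for a in (0, 1) for b in (2, 3, 4)]
        assert assortativity_categorical(toy_network(nodes, edges), "sex") == pytest.approx(-1.0)

    def test_single_category_undefined(self):
        net = toy_network({0: dict(sex="f"), 1: dict(sex="f")}, [(0, 1, 2)])
        assert np.isnan(assortativity_categorical(net, "sex"))


class TestOracleEquivalence:
    """Both estimators match the multigraph-replication oracle on an
    exhaustive sweep of small integer-weight fixtures."""

    def _sweep(self, n_nodes, attr_sets, numeric, max_graphs=None):
        pairs = list(itertools.combinations(range(n_nodes), 2))
        rng = np.random.default_rng(12)
        fn = assortativity_numeric if numeric else assortativity_categorical
        checked = 0
        for mask in range(1, 2 ** len(pairs)):
            present = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
            weights = [int(rng.integers(1, 4)) for _ in present]
            for attrs in attr_sets:
                nodes = {i: dict(attrs[i]) for i in range(n_nodes)}
                edges = [(a, b, w) for (a, b), w in zip(present, weights)]
                ours = fn(toy_network(nodes, edges), "age" if numeric else "sex")
                oracle = nx_multigraph_oracle(
                    nodes, edges, "age" if numeric else "sex", numeric=numeric
                )
                if np.isnan(ours):
                    continue
                assert ours == pytest.approx(oracle, abs=1e-9), (edges, attrs)
                checked += 1
        assert checked > 0

    def test_numeric_all_graphs_up_to_4_nodes(self):
        for n in (3, 4):
            attr_sets = [
                {i: dict(age=float(i + 1)) for i in range(n)},
                {i: dict(age=float((i * 2) % 3)) for i in range(n)},
            ]
            self._sweep(n, attr_sets, numeric=True)

    def test_categorical_all_graphs_up_to_4_nodes(self):
        for n in (3, 4):
            attr_sets = [
                {i: dict(sex="m" if i % 2 else "f") for i in range(n)},
                {i: dict(sex="f" if i < n - 1 else "m") for i in range(n)},
            ]
            self._sweep(n, attr_sets, numeric=False)

    def test_random_graphs_5_and_6_nodes(self):
        rng = np.random.default_rng(3)
        for n in (5, 6):
            for _ in range(25):
                pairs = list(itertools.combinations(range(n), 2))
                keep = [p for p in pairs if rng.random() < 0.5]
                if not keep:
                    continue
                edges = [(a, b, int(rng.integers(1, 4))) for a, b in keep]
                nodes = {
                    i: dict(age=float(rng.integers(0, 5)),
                            sex="m" if rng.random() < 0.5 else "f")
                    for i in range(n)
                }
                ours = assortativity_numeric(toy_network(nodes, edges), "age")
                oracle = nx_multigraph_oracle(nodes, edges, "age", numeric=True)
                if not np.isnan(ours):
                    assert ours == pytest.approx(oracle, abs=1e-9)
                ours_c = assortativity_categorical(toy_network(nodes, edges), "sex")
                oracle_c = nx_multigraph_oracle(nodes, edges, "sex", numeric=False)
                if not np.isnan(ours_c):
                    assert ours_c == pytest.approx(oracle_c, abs=1e-9)

    def test_equal_weights_match_classical_unweighted(self):
        """With unit weights the estimators equal the classical coefficients
        on simple graphs (oracle: networkx on the simple graph)."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 6
            pairs = [p for p in itertools.combinations(range(n), 2) if rng.random() < 0.5]
            if len(pairs) < 2:
                continue
            nodes = {
                i: dict(age=float(rng.integers(1, 6)),
                        sex="m" if rng.random() < 0.5 else "f")
                for i in range(n)
            }
            edges = [(a, b, 1) for a, b in pairs]
            G = nx.Graph(pairs)
            nx.set_node_attributes(G, {i: nodes[i]["age"] for i in G}, "age")
            nx.set_node_attributes(G, {i: nodes[i]["sex"] for i in G}, "sex")
            ours = assortativity_numeric(toy_network(nodes, edges), "age")
            if not np.isnan(ours):
                assert ours == pytest.approx(
                    nx.numeric_assortativity_coefficient(G, "age"), abs=1e-9
                )
            ours_c = assortativity_categorical(toy_network(nodes, edges), "sex")
            if not np.isnan(ours_c):
                assert ours_c == pytest.approx(
                    nx.attribute_assortativity_coefficient(G, "sex"), abs=1e-9
                )


class TestSummaries:
    def test_mean_and_sd_of_sizes(self):
        n1 = toy_network({i: dict(age=1.0 * i) for i in range(8)},
                         [(0, 1, 1)], hh="A")
        n2 = toy_network({i: dict(age=1.0 * i) for i in range(12)},
                         [(0, 1, 1), (1, 2, 2)], hh="B")
        df = summarize_networks([n1, n2]).set_index("household_id")
        assert df.loc["cohort_mean", "n_nodes"] == pytest.approx(10.0)
        assert df.loc["cohort_sd", "n_nodes"] == pytest.approx(2.8284, abs=1e-3)

    def test_single_network_sd_undefined(self):
        n1 = toy_network({0: dict(age=1.0), 1: dict(age=2.0)}, [(0, 1, 1)])
        df = summarize_networks([n1]).set_index("household_id")
        assert np.isnan(df.loc["cohort_sd", "n_nodes"])

    def test_category_counts_sum_to_edges(self, study_networks):
        df = summarize_networks(study_networks)
        per_net = df[~df.household_id.str.startswith("cohort")]
        cat_cols = [c for c in per_net.columns if c.startswith("n_") and c != "n_nodes" and c != "n_edges"]
        assert (per_net[cat_cols].sum(axis=1) == per_net["n_edges"]).all()


class TestCategoryMeans:
    def test_generator_reproduces_strength_ordering(self, study_networks):
        """Spouse > intergenerational > friend in closeness and interaction."""
        cm = category_means(study_networks)
        for measure in ("closeness", "interact_freq"):
            sub = cm[cm.measure == measure].set_index("category")["mean"]
            assert sub["spouse_partner"] > sub["intergenerational"] > sub["friend"]

    def test_absent_category_missing_not_zero(self):
        net = toy_network({0: dict(age=1.0), 1: dict(age=2.0)}, [(0, 1, 3)])
        cm = category_means([net])
        assert set(cm.category) <= {"other"}

    def test_importance_split_by_direction(self, study_networks):
        cm = category_means(study_networks)
        imp = cm[cm.measure == "importance"]
        assert {"intergenerational_target_older", "intergenerational_target_younger"} <= set(imp.category)


class TestCohortAssortativity:
    def test_cross_sex_eating_gives_negative_sex_assortativity(self, study_networks):
        _, summary = cohort_assortativity(study_networks)
        row = summary[(summary.attribute == "sex") & (summary.weight == "eat_freq")]
        assert row["mean"].iloc[0] < 0

    def test_undefined_networks_dropped_and_counted(self):
        good = toy_network({0: dict(age=1.0, sex="m"), 1: dict(age=2.0, sex="f")},
                           [(0, 1, 2)], hh="A")
        bad = toy_network({0: dict(age=3.0, sex="f"), 1: dict(age=3.0, sex="f")},
                          [(0, 1, 2)], hh="B")
        per_net, summary = cohort_assortativity([good, bad], attributes=("age",))
        row = summary[(summary.attribute == "age") & (summary.weight == "eat_freq")]
        assert int(row["n_dropped"].iloc[0]) >= 1


def test_plot_export(tmp_path, study_networks):
    out = tmp_path / "net.png"
    plot_network(study_networks[0], path=out)
    assert out.stat().st_size > 0
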