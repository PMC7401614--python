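import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import aridinet as an


def _bh_oracle(p):
    """Independent step-up implementation (sorted cumulative minimum)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, m * p[i] / rank)
        q[i] = prev
    return q


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert an.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepped_example(self):
        np.testing.assert_allclose(an.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            an.bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_oracle_and_dominates_p(self, ps):
        q = an.bh_fdr(ps)
        np.testing.assert_allclose(q, _bh_oracle(ps), atol=1e-12)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        # monotone in sorted-p order
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCorrelatePairs:
    def test_affine_relation_pearson_one(self):
        x = np.arange(6, dtype=float)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        corr = an.correlate_pairs(df)
        pear = corr[corr["method"] == "pearson"].set_index(["source", "target"])
        assert pear.loc[("x", "y"), "r"] == pytest.approx(1.0)
        assert pear.loc[("x", "z"), "r"] == pytest.approx(-1.0)
        assert pear.loc[("x", "z"), "p"] < 1e-10

    def test_matches_textbook_formula(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        corr = an.correlate_pairs(df, methods=("pearson",)).set_index(["source", "target"])
        for u, v in itertools.combinations("abcd", 2):
            x, y = df[u].to_numpy(), df[v].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r_ref = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert corr.loc[(u, v), "r"] == pytest.approx(r_ref, abs=1e-10)

    def test_zero_variance_features_skipped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=6), "b": np.ones(6), "c": rng.normal(size=6)})
        corr = an.correlate_pairs(df)
        assert "b" not in set(corr["source"]) | set(corr["target"])


def _brute_force_edges(values, r_min, alpha, p_mode, combine="or"):
    """Independent all-pairs filter used as the network oracle."""
    names = [c for c in values.columns if values[c].std() > 0]
    per_method = {}
    for method, fn in (("pearson", stats.pearsonr), ("spearman", stats.spearmanr)):
        rows = {}
        pairs = list(itertools.combinations(names, 2))
        ps = []
        for u, v in pairs:
            r, p = fn(values[u], values[v])
            rows[(u, v)] = (r, p)
            ps.append(p)
        qs = _bh_oracle(ps)
        per_method[method] = {
            pair: (rows[pair][0], qs[i] if p_mode == "bh" else rows[pair][1])
            for i, pair in enumerate(pairs)
        }
    edges = set()
    for pair in itertools.combinations(names, 2):
        hits = [
            m for m in per_method
            if abs(per_method[m][pair][0]) >= r_min and per_method[m][pair][1] <= alpha
        ]
        if (combine == "or" and hits) or (combine == "and" and len(hits) == 2):
            edges.add(pair)
    return edges


class TestCooccurrenceNetwork:
    @pytest.fixture
    def features(self, rng):
        """<=30 correlated features over 12 sites."""
        latent = rng.normal(size=12)
        cols = {}
        for i in range(18):
            w = rng.uniform(-1, 1)
            cols[f"f{i:02d}"] = w * latent + rng.normal(size=12) * 0.6
        return pd.DataFrame(cols)

    @pytest.mark.parametrize("r_min,alpha,p_mode", [
        (0.5, 0.1, "bh"), (0.7, 0.05, "bh"), (0.5, 0.05, "raw"), (0.9, 0.05, "bh"),
    ])
    def test_equals_brute_force_filter(self, features, r_min, alpha, p_mode):
        model = an.build_network(features, r_min=r_min, alpha=alpha, p_mode=p_mode)
        got = {tuple(sorted(e)) for e in model.graph_.edges}
        want = {tuple(sorted(e)) for e in _brute_force_edges(features, r_min, alpha, p_mode)}
        assert got == want

    def test_and_rule_subset_of_or_rule(self, features):
        or_net = an.build_network(features, r_min=0.5, alpha=0.1, combine="or")
        and_net = an.build_network(features, r_min=0.5, alpha=0.1, combine="and")
        assert set(and_net.graph_.edges) <= set(or_net.graph_.edges)
        want = {tuple(sorted(e))
                for e in _brute_force_edges(features, 0.5, 0.1, "bh", combine="and")}
        assert {tuple(sorted(e)) for e in and_net.graph_.edges} == want

    def test_edge_sign_matches_r(self, features):
        model = an.build_network(features, r_min=0.5, alpha=0.1)
        for _, row in model.edges_.iterrows():
            assert row["sign"] == ("+" if row["r"] > 0 else "-")

    def test_threshold_monotonicity(self, features):
        """Raising r_min or tightening alpha never adds edges."""
        base = set(an.build_network(features, r_min=0.5, alpha=0.1).graph_.edges)
        tighter_r = set(an.build_network(features, r_min=0.8, alpha=0.1).graph_.edges)
        tighter_a = set(an.build_network(features, r_min=0.5, alpha=0.01).graph_.edges)
        assert tighter_r <= base and tighter_a <= base

    def test_simple_graph_no_self_edges(self, features):
        g = an.build_network(features, r_min=0.5, alpha=0.1).graph_
        assert all(u != v for u, v in g.edges)


class TestSplitSubnetworks:
    def _toy_graph(self):
        g = nx.Graph()
        classes = {
            "i1": "rhizo_increased", "i2": "endo_increased",
            "d1": "rhizo_decreased", "d2": "endo_decreased",
            "K": "soil_parameter", "Fe": "soil_parameter", "Ca": "soil_parameter",
        }
        for n, c in classes.items():
            g.add_node(n, feature_class=c, taxonomy="")
        for u, v, sign in [("i1", "i2", "+"), ("d1", "d2", "+"), ("i1", "d1", "-"),
                           ("i2", "K", "-"), ("d1", "Fe", "+"), ("K", "Fe", "-")]:
            g.add_edge(u, v, sign=sign, r=0.95 if sign == "+" else -0.95)
        return g

    def test_blocks_partition_edges(self):
        g = self._toy_graph()
        split = an.split_subnetworks(g)
        total = (split.increased.number_of_edges() + split.decreased.number_of_edges()
                 + len(split.between_edges) + len(split.soil_soil_edges))
        assert total == g.number_of_edges()

    def test_soil_attached_to_both_classes_appears_in_both(self):
        g = self._toy_graph()
        g.add_edge("Ca", "i1", sign="+", r=0.92)
        g.add_edge("Ca", "d2", sign="+", r=0.92)
        split = an.split_subnetworks(g)
        assert "Ca" in split.increased and "Ca" in split.decreased

    def test_single_class_network(self):
        g = nx.Graph()
        g.add_node("i1", feature_class="rhizo_increased")
        g.add_node("i2", feature_class="endo_increased")
        g.add_edge("i1", "i2", sign="+")
        split = an.split_subnetworks(g)
        assert split.decreased.number_of_edges() == 0
        assert not any(an.split_subnetworks(g).decreased.nodes)

    def test_partition_identity_on_random_graphs(self, rng):
        classes = ["rhizo_increased", "endo_increased", "rhizo_decreased",
                   "endo_decreased", "soil_parameter"]
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1 << 30)))
            for n in g.nodes:
                g.nodes[n]["feature_class"] = classes[n % len(classes)]
            for u, v in g.edges:
                g.edges[u, v]["sign"] = "+"
            split = an.split_subnetworks(g)
            total = (split.increased.number_of_edges() + split.decreased.number_of_edges()
                     + len(split.between_edges) + len(split.soil_soil_edges))
            assert total == g.number_of_edges()


class TestRankHubs:
    def test_star_center_is_sole_hub(self):
        g = nx.star_graph(5)
        for n in g.nodes:
            g.nodes[n]["feature_class"] = "rhizo_increased"
        hubs = an.rank_hubs(g, min_degree=5, top_k=1)
        assert hubs["node"].tolist() == [0] and hubs["degree"].tolist() == [5]

    def test_empty_when_all_below_threshold(self):
        g = nx.path_graph(4)
        hubs = an.rank_hubs(g, min_degree=56)
        assert hubs.empty

    def test_degrees_match_incidence_count(self, rng):
        g = nx.gnp_random_graph(20, 0.25, seed=4)
        hubs = an.rank_hubs(g, min_degree=0, top_k=20)
        incidence = {n: 0 for n in g.nodes}
        for u, v in g.edges:
            incidence[u] += 1
            incidence[v] += 1
        for row in hubs.itertuples(index=False):
            assert row.degree == incidence[row.node]
        assert (hubs["degree"].diff().dropna() <= 0).all()


class TestExport:
    def _net(self, rng):
        latent = rng.normal(size=10)
        df = pd.DataFrame({f"f{i}": latent * (1 if i % 2 else -1) + rng.normal(size=10) * 0.3
                           for i in range(8)})
        return an.build_network(df, r_min=0.6, alpha=0.1)

    def test_graphml_round_trip(self, tmp_path, rng):
        g = self._net(rng).graph_
        from aridinet.network import read_graphml

        path = tmp_path / "net.graphml"
        an.export_graph(g, tmp_path, formats=("graphml",), stem="net")
        back = read_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert {tuple(sorted(e)) for e in back.edges} == {tuple(sorted(e)) for e in g.edges}
        for u, v in g.edges:
            assert back.edges[u, v]["sign"] == g.edges[u, v]["sign"]

    def test_sif_lines(self, tmp_path):
        g = nx.Graph()
        g.add_node("a"), g.add_node("b"), g.add_node("lonely")
        g.add_edge("a", "b", sign="+")
        from aridinet.network import write_sif

        p = tmp_path / "n.sif"
        write_sif(g, p)
        lines = p.read_text().splitlines()
        assert "a\tpos\tb" in lines
        assert "lonely" in lines

    def test_empty_network_exports_valid_files(self, tmp_path):
        g = nx.Graph()
        paths = an.export_graph(g, tmp_path, stem="empty")
        for p in paths:
            assert p.exists()
        from aridinet.network import read_graphml

        assert read_graphml(tmp_path / "empty.graphml").number_of_nodes() == 0
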