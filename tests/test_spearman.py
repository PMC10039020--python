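import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import sedanet as sn
from sedanet.io import InputError


def brute_force_bh(p, m=None):
    """Literal step-up definition: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    m = m or n
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_i in range(n):
        q[order[rank_i]] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, n)), 1.0)
    return q


def hand_ranks(x):
    """Average ranks computed by explicit comparison counting (no scipy)."""
    x = np.asarray(x, dtype=float)
    r = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        eq = np.sum(x == v)
        r[i] = less + (eq + 1) / 2
    return r


class TestBHAdjust:
    def test_hand_computation(self):
        out = sn.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sn.bh_adjust([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(sn.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_against_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(
                sn.bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                atol=1e-12)

    def test_custom_family_size(self):
        out = sn.bh_adjust([0.01, 0.5], m=10)
        np.testing.assert_allclose(out, brute_force_bh([0.01, 0.5], m=10))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            sn.bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, p):
        q = sn.bh_adjust(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1.0)).all()


class TestPairwiseSpearman:
    def test_self_correlation_unit_diagonal(self, small_community):
        cm = small_community[0]
        cr = sn.pairwise_spearman(cm.counts.iloc[:, :10].astype(float))
        np.testing.assert_allclose(np.diag(cr.rho), 1.0)
        np.testing.assert_allclose(cr.rho, cr.rho.T)
        np.testing.assert_allclose(cr.p_adj, cr.p_adj.T)

    def test_reversal_gives_minus_one(self):
        x = np.array([1.0, 2, 3, 4, 5])
        df = pd.DataFrame({"a": x, "b": x[::-1]})
        cr = sn.pairwise_spearman(df)
        assert cr.rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_tied_fixture_matches_hand_rank_oracle(self):
        df = pd.DataFrame({
            "a": [1.0, 1.0, 2.0, 3.0, 3.0, 4.0],
            "b": [2.0, 1.0, 1.0, 5.0, 5.0, 5.0],
            "c": [9.0, 7.0, 7.0, 3.0, 2.0, 1.0]})
        cr = sn.pairwise_spearman(df)
        for i in df.columns:
            for j in df.columns:
                ri, rj = hand_ranks(df[i]), hand_ranks(df[j])
                num = np.sum((ri - ri.mean()) * (rj - rj.mean()))
                den = np.sqrt(np.sum((ri - ri.mean()) ** 2)
                              * np.sum((rj - rj.mean()) ** 2))
                assert cr.rho.loc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random(size=(10, 4)), columns=list("abcd"))
        cr1 = sn.pairwise_spearman(df)
        df2 = df.copy()
        df2["a"] = np.exp(5 * df2["a"])  # strictly increasing transform
        cr2 = sn.pairwise_spearman(df2)
        np.testing.assert_allclose(cr1.rho, cr2.rho, atol=1e-12)

    def test_constant_column_excluded(self):
        df = pd.DataFrame({"a": np.arange(6.0), "b": np.ones(6),
                           "c": np.arange(6.0)[::-1]})
        cr = sn.pairwise_spearman(df)
        assert np.isnan(cr.rho.loc["a", "b"])
        assert np.isnan(cr.p_adj.loc["a", "b"])
        assert cr.rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_too_few_samples(self):
        with pytest.raises(InputError):
            sn.pairwise_spearman(pd.DataFrame(np.ones((3, 3))))


class TestBuildNetwork:
    def _cr(self, rho, p):
        idx = [f"f{i}" for i in range(rho.shape[0])]
        adj = p.copy()
        return sn.CorrelationResult(
            pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx),
            pd.DataFrame(adj, index=idx, columns=idx))

    def test_no_pair_passes_empty(self):
        rho = np.array([[1, 0.2], [0.2, 1.0]])
        p = np.array([[0, 0.5], [0.5, 0]])
        net = sn.build_network(self._cr(rho, p))
        assert net.number_of_edges() == 0

    def test_engineered_fixture_edge_set(self):
        # hand enumeration: (0,1) passes both; (0,2) rho too low;
        # (1,3) p too high; (2,3) passes
        rho = np.eye(4)
        p = np.zeros((4, 4))
        pairs = {(0, 1): (0.9, 0.01), (0, 2): (0.3, 0.01),
                 (0, 3): (0.5, 0.5), (1, 2): (-0.9, 0.01),
                 (1, 3): (0.45, 0.2), (2, 3): (0.41, 0.09)}
        for (i, j), (r, q) in pairs.items():
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = q
        net = sn.build_network(self._cr(rho, p), rho_min=0.4, alpha=0.1)
        assert set(map(frozenset, net.edges)) == {
            frozenset(("f0", "f1")), frozenset(("f2", "f3"))}
        assert net.edges["f0", "f1"]["weight"] == pytest.approx(0.9)

    def test_negative_variant(self):
        rho = np.eye(2)
        rho[0, 1] = rho[1, 0] = -0.9
        p = np.zeros((2, 2))
        pos = sn.build_network(self._cr(rho, p), sign="positive")
        neg = sn.build_network(self._cr(rho, p), sign="negative")
        assert pos.number_of_edges() == 0 and neg.number_of_edges() == 1

    def test_edge_count_monotone_in_thresholds(self, small_community):
        cm = small_community[0]
        cr = sn.pairwise_spearman(cm.counts.iloc[:, :20].astype(float))
        e1 = sn.build_network(cr, rho_min=0.4, alpha=0.1).number_of_edges()
        e2 = sn.build_network(cr, rho_min=0.6, alpha=0.1).number_of_edges()
        e3 = sn.build_network(cr, rho_min=0.4, alpha=0.01).number_of_edges()
        assert e2 <= e1 and e3 <= e1

    def test_no_isolated_nodes(self, small_community):
        cm = small_community[0]
        cr = sn.pairwise_spearman(cm.counts.iloc[:, :20].astype(float))
        net = sn.build_network(cr)
        assert all(d > 0 for _, d in net.degree())


class TestModulesLayout:
    def test_two_triangles_two_modules(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        mods = sn.find_modules(g)
        assert len(set(mods.values())) == 2
        assert mods[0] == mods[1] == mods[2]
        assert mods[3] == mods[4] == mods[5]

    def test_path_graph_one_module(self):
        mods = sn.find_modules(nx.path_graph(5))
        assert set(mods.values()) == {0}

    def test_empty_network(self):
        assert sn.find_modules(nx.Graph()) == {}

    def test_layout_deterministic(self):
        g = nx.path_graph(6)
        a = sn.fr_layout(g, seed=4)
        b = sn.fr_layout(g, seed=4)
        for n in g:
            np.testing.assert_allclose(a[n], b[n])
            assert np.isfinite(a[n]).all()

    def test_single_node_at_origin(self):
        g = nx.empty_graph(1)
        pos = sn.fr_layout(g, seed=0)
        np.testing.assert_allclose(pos[0], [0.0, 0.0])

    def test_two_block_layout_separation(self):
        """Connected pairs end up closer on average than unconnected ones."""
        rng = np.random.default_rng(0)
        g = nx.random_partition_graph([8, 8], 0.9, 0.02, seed=3)
        pos = sn.fr_layout(g, seed=1)
        d_conn, d_unconn = [], []
        nodes = list(g)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                d = np.linalg.norm(pos[u] - pos[v])
                (d_conn if g.has_edge(u, v) else d_unconn).append(d)
        assert np.mean(d_conn) < np.mean(d_unconn)


class TestNeighborComposition:
    def test_star_hand_tally(self, toy_annotation):
        g = nx.star_graph(["center", "famA", "famB", "famC"])
        tbl = toy_annotation.table.copy()
        tbl.loc["center"] = ["pelagic", "fish", "heterotrophic"]
        tbl.loc["famB", "functional_group"] = "centric diatoms"
        ann = sn.TaxonAnnotation(tbl)
        rep = sn.neighbor_composition(g, ["center"], ann)
        assert rep.table.to_dict() == {"centric diatoms": 2, "bivalves": 1}
        assert rep.n_neighbor_families == 3
        assert rep.n_links == 3
        np.testing.assert_allclose(rep.shares().sum(), 100.0)

    def test_empty_seed_set(self, toy_annotation):
        g = nx.path_graph(["famA", "famB"])
        rep = sn.neighbor_composition(g, [], toy_annotation)
        assert rep.n_links == 0 and len(rep.table) == 0

    def test_unknown_seed_family(self, toy_annotation):
        g = nx.path_graph(["famA", "famB"])
        with pytest.raises(InputError, match="ghost"):
            sn.neighbor_composition(g, ["ghost"], toy_annotation)


class TestCompareDegrees:
    def test_identical_multisets(self):
        g = nx.Graph()
        for i, d in enumerate([1, 2, 3, 1, 2, 3]):
            for k in range(d):
                g.add_edge(f"n{i}", f"aux{i}_{k}")
        rep = sn.compare_degrees(g, ["n0", "n1", "n2"], ["n3", "n4", "n5"])
        assert rep.t == pytest.approx(0.0)
        assert rep.p == pytest.approx(1.0)

    def test_separated_degrees_welch(self):
        g = nx.Graph()
        hubs = []
        for i in range(4):
            leaf = f"l{i}"
            g.add_edge(leaf, "hub0")  # leaves have degree 1
        for h in range(4):
            hub = f"hub{h}"
            hubs.append(hub)
            for k in range(10):
                g.add_edge(hub, f"x{h}_{k}")
        leaves = [f"l{i}" for i in range(4)]
        rep = sn.compare_degrees(g, leaves, hubs)
        assert rep.mean_a < rep.mean_b
        assert rep.p < 0.01

    def test_null_p_uniform(self):
        """Random label splits of one degree pool give uniform p (KS)."""
        from scipy import stats
        rng = np.random.default_rng(9)
        pool = rng.integers(1, 12, size=30)
        ps = []
        for _ in range(200):
            perm = rng.permutation(pool).astype(float)
            res = stats.ttest_ind(perm[:15], perm[15:], equal_var=False)
            ps.append(res.pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_set_rejected(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.raises(InputError):
            sn.compare_degrees(g, ["a"], ["b", "c"])
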