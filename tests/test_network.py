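import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from musclenet import (
    Block,
    ConfigurationError,
    SyntheticConfig,
    build_network,
    calibrate_threshold,
    correlation_partners,
    default_grid,
    generate_null_dataset,
    generate_two_group_dataset,
    network_summary,
    pearson_matrix,
    shuffle_surrogate,
)
from .conftest import make_matrix


def null_pearson_tail(tau: float, n: int) -> float:
    """P(r > tau) for independent Gaussian data at n samples:
    t = r·sqrt((n−2)/(1−r²)) is Student t with n−2 df."""
    t = tau * np.sqrt((n - 2) / (1 - tau**2))
    return float(stats.t.sf(t, n - 2))


class TestPearsonMatrix:
    def test_duplicate_gene_r_one_and_negation_minus_one(self):
        x = np.array([1.0, 2.0, 4.0, 3.5])
        m = make_matrix(np.vstack([x, x, -x]))
        r = pearson_matrix(m).data
        assert r.loc["G1", "G2"] == pytest.approx(1.0)
        assert r.loc["G1", "G3"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = np.array([1, 2, 3, 4.0])
        y = np.array([2, 4, 5, 9.0])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        m = make_matrix(np.vstack([x, y]))
        assert pearson_matrix(m).data.loc["G1", "G2"] == pytest.approx(r_hand, rel=1e-12)

    def test_constant_gene_flagged_and_zeroed(self):
        m = make_matrix([[1, 1, 1, 1], [1, 2, 3, 4.0]])
        corr = pearson_matrix(m)
        assert corr.constant_genes == ("G1",)
        assert corr.data.loc["G1", "G2"] == 0
        assert corr.data.loc["G1", "G1"] == 1

    def test_needs_three_samples(self):
        with pytest.raises(ConfigurationError, match="3 samples"):
            pearson_matrix(make_matrix([[1, 2], [3, 4.0]]))


class TestShuffleSurrogate:
    def test_per_gene_marginals_exactly_preserved(self, toy_matrix):
        rng = np.random.default_rng(0)
        surr = shuffle_surrogate(toy_matrix, rng)
        np.testing.assert_array_equal(
            np.sort(surr.values, axis=1), np.sort(toy_matrix.values, axis=1)
        )
        np.testing.assert_allclose(surr.values.mean(axis=1), toy_matrix.values.mean(axis=1))

    def test_destroys_planted_correlation(self):
        cfg = SyntheticConfig(
            n_genes=40, n_per_group=7, n_de=0, blocks=(Block(40, 0.99, "case"),), seed=1,
        )
        m, ann, _ = generate_two_group_dataset(cfg)
        case = m.select_samples(ann.samples_in("case"))
        before = pearson_matrix(case).upper_triangle()
        rates = []
        for i in range(300):
            surr = shuffle_surrogate(case, np.random.default_rng([5, i]))
            rates.append(np.mean(np.abs(pearson_matrix(surr).upper_triangle())))
        assert np.mean(np.abs(before)) > 0.9
        # null E|r| for n=7 is ~0.35; far below the planted 0.99
        assert np.mean(rates) < 0.45


class TestCalibration:
    def test_counts_monotone_and_bounded(self):
        cfg = SyntheticConfig(n_genes=30, n_per_group=7, n_de=0, blocks=(), seed=3)
        m, ann, _ = generate_null_dataset(cfg)
        cal = calibrate_threshold(
            m.select_samples(ann.samples_in("case")), n_surrogates=50, seed=3
        )
        assert (np.diff(cal.original_counts) <= 0).all()
        assert (np.diff(cal.surrogate_mean) <= 1e-9).all()
        n_pairs = 30 * 29 // 2
        assert (cal.original_counts <= n_pairs).all()
        assert (cal.surrogate_mean <= n_pairs).all()

    def test_null_data_selects_nothing(self):
        cfg = SyntheticConfig(n_genes=60, n_per_group=7, n_de=0, blocks=(), seed=2)
        m, ann, _ = generate_null_dataset(cfg)
        cal = calibrate_threshold(
            m.select_samples(ann.samples_in("case")), n_surrogates=200, seed=2
        )
        assert cal.selected is None

    def test_planted_block_selects_a_threshold(self):
        cfg = SyntheticConfig(
            n_genes=100, n_per_group=7, n_de=0, blocks=(Block(22, 0.99, "case"),), seed=4,
        )
        m, ann, truth = generate_two_group_dataset(cfg)
        case = m.select_samples(ann.samples_in("case"))
        cal = calibrate_threshold(case, n_surrogates=200, seed=4)
        assert cal.selected is not None
        net = build_network(pearson_matrix(case), 0.95)
        block = truth.block_genes("block1")
        within = [e for e in net.graph.edges if set(e) <= block]
        assert len(within) >= 150  # most of the 231 block pairs connect
        i = list(cal.grid).index(0.95)
        assert cal.surrogate_mean[i] < 10

    def test_deterministic_per_seed(self, toy_matrix):
        a = calibrate_threshold(toy_matrix, n_surrogates=25, seed=9)
        b = calibrate_threshold(toy_matrix, n_surrogates=25, seed=9)
        np.testing.assert_array_equal(a.surrogate_mean, b.surrogate_mean)

    def test_empty_grid_rejected(self, toy_matrix):
        with pytest.raises(ConfigurationError, match="grid"):
            calibrate_threshold(toy_matrix, grid=np.array([]), n_surrogates=5)

    def test_surrogate_rate_matches_analytic_null_tail(self):
        cfg = SyntheticConfig(n_genes=100, n_per_group=7, n_de=0, blocks=(), seed=6)
        m, ann, _ = generate_null_dataset(cfg)
        case = m.select_samples(ann.samples_in("case"))
        cal = calibrate_threshold(case, n_surrogates=400, seed=6)
        n_pairs = 100 * 99 // 2
        for tau in (0.90, 0.95):
            i = list(cal.grid).index(tau)
            rate = cal.surrogate_mean[i] / n_pairs
            expect = null_pearson_tail(tau, 7)
            assert rate == pytest.approx(expect, rel=0.30)


class TestBuildNetwork:
    def test_threshold_one_like_gives_empty_graph(self, toy_matrix):
        net = build_network(pearson_matrix(toy_matrix), 0.999999)
        assert net.n_edges == 0
        assert net.average_degree == 0
        assert net.n_isolated == net.n_nodes

    def test_ad_formula_known_value(self):
        # 100 nodes, engineered 10 edges → AD = 0.2
        n = 100
        r = np.eye(n)
        pairs = [(2 * i, 2 * i + 1) for i in range(10)]
        for i, j in pairs:
            r[i, j] = r[j, i] = 0.99
        df = pd.DataFrame(r, index=[f"G{i}" for i in range(n)], columns=[f"G{i}" for i in range(n)])
        from musclenet import CorrelationMatrix

        corr = CorrelationMatrix(data=df, n_samples=7)
        net = build_network(corr, 0.95)
        assert net.n_edges == 10
        assert net.average_degree == pytest.approx(0.2)

    def test_components_against_bfs_oracle(self):
        # 6 genes: first three form a clique, rest isolated
        genes = list("abcdef")
        r = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    r[i, j] = 0.99
        from musclenet import CorrelationMatrix

        corr = CorrelationMatrix(
            data=pd.DataFrame(r, index=genes, columns=genes), n_samples=7
        )
        net = build_network(corr, 0.9)

        def bfs_components(nodes, edges):
            adj = {u: set() for u in nodes}
            for u, v in edges:
                adj[u].add(v)
                adj[v].add(u)
            seen, comps = set(), []
            for start in nodes:
                if start in seen:
                    continue
                queue, comp = [start], set()
                while queue:
                    u = queue.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    queue.extend(adj[u] - comp)
                seen |= comp
                comps.append(frozenset(comp))
            return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))

        oracle = bfs_components(genes, list(net.graph.edges))
        assert net.components == oracle
        assert len(net.largest_component) == 3
        assert net.n_isolated == 3

    def test_absolute_rule_counts_negative_correlations(self):
        x = np.array([1, 2, 4, 3.5, 5, 0.5, 2.2])
        m = make_matrix(np.vstack([x, -x, x * 0 + np.random.default_rng(1).normal(size=7)]))
        corr = pearson_matrix(m)
        assert build_network(corr, 0.9, "positive").n_edges == 0
        assert build_network(corr, 0.9, "absolute").n_edges == 1

    def test_invalid_tau_rejected(self, toy_matrix):
        corr = pearson_matrix(toy_matrix)
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ConfigurationError):
                build_network(corr, bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_ad_identity_fuzzed(self, seed):
        """AD·N = 2·C exactly on random thresholded correlation graphs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        x = rng.normal(0, 1, (n, 5))
        corr = pearson_matrix(make_matrix(x))
        tau = float(rng.uniform(0.05, 0.95))
        net = build_network(corr, tau)
        # handshake identity in exact integer arithmetic, then AD itself
        assert int(net.degrees.sum()) == 2 * net.n_edges
        assert net.average_degree == 2 * net.n_edges / net.n_nodes

    def test_edge_count_non_increasing_in_tau(self, toy_matrix):
        corr = pearson_matrix(toy_matrix)
        counts = [build_network(corr, t).n_edges for t in np.linspace(0.05, 0.95, 10)]
        assert (np.diff(counts) <= 0).all()


class TestSummaryAndPartners:
    def test_identical_networks_zero_difference(self, toy_matrix):
        corr = pearson_matrix(toy_matrix)
        a, b = build_network(corr, 0.5), build_network(corr, 0.5)
        cmp = network_summary(a, b)
        assert cmp.loc["edges_only_here", "case"] == 0
        assert cmp.loc["edges_only_here", "control"] == 0

    def test_superset_edges_monotone_ad(self, toy_matrix):
        corr = pearson_matrix(toy_matrix)
        low, high = build_network(corr, 0.3), build_network(corr, 0.7)
        cmp = network_summary(low, high)
        assert cmp.loc["average_degree", "case"] >= cmp.loc["average_degree", "control"]

    def test_mismatched_nodes_rejected(self, toy_matrix):
        corr = pearson_matrix(toy_matrix)
        sub = pearson_matrix(toy_matrix.select_genes(toy_matrix.gene_ids[:5]))
        with pytest.raises(ConfigurationError, match="node set"):
            network_summary(build_network(corr, 0.5), build_network(sub, 0.5))

    def test_planted_case_block_dominates_comparison(self):
        cfg = SyntheticConfig(
            n_genes=100, n_per_group=7, n_de=0, blocks=(Block(22, 0.97, "case"),), seed=14,
        )
        m, ann, truth = generate_two_group_dataset(cfg)
        net_case = build_network(pearson_matrix(m.select_samples(ann.samples_in("case"))), 0.95)
        net_ctrl = build_network(pearson_matrix(m.select_samples(ann.samples_in("control"))), 0.95)
        cmp = network_summary(net_case, net_ctrl)
        assert cmp.loc["average_degree", "case"] > cmp.loc["average_degree", "control"]
        block = truth.block_genes("block1")
        lc = net_case.largest_component
        assert len(lc & block) / len(lc) >= 0.8

    def test_duplicate_query_ranks_first(self):
        x = np.random.default_rng(3).normal(0, 1, (9, 6))
        x[4] = x[0]
        m = make_matrix(x)
        partners = correlation_partners(m, "G1")
        assert partners.iloc[0].gene_id == "G5"
        assert partners.iloc[0].r == pytest.approx(1.0)

    def test_rank_order_matches_brute_force(self):
        rng = np.random.default_rng(15)
        m = make_matrix(rng.normal(0, 1, (10, 8)))
        partners = correlation_partners(m, "G3")
        brute = {
            g: np.corrcoef(m.data.loc["G3"], m.data.loc[g])[0, 1]
            for g in m.gene_ids
            if g != "G3"
        }
        expected = sorted(brute, key=lambda g: -brute[g])
        assert list(partners.gene_id) == expected
        np.testing.assert_allclose(partners.r.values, [brute[g] for g in expected])

    def test_unknown_gene_rejected(self, toy_matrix):
        with pytest.raises(KeyError):
            correlation_partners(toy_matrix, "nope")
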