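"""Graphical lasso fits, StARS selection, pruning, serialization."""

import itertools
import math

import numpy as np
import pytest

from ctdnet import (CoPerturbationNetwork, NetworkConfig, PrecisionMatrix,
                    default_lambda_path, differential_prune, glasso_fit,
                    learn_disease_network, learn_treatment_network,
                    prune_nodes, read_network, stars_select,
                    to_partial_correlation, write_network)

from conftest import make_ids


def _offdiag_support_count(theta, tol=1e-12):
    off = np.abs(theta) > tol
    np.fill_diagonal(off, False)
    return int(off.sum()) // 2


class TestGlassoFit:
    def test_large_penalty_gives_empty_support(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 10))
        pm = glasso_fit(X, lam=0.5)
        assert _offdiag_support_count(pm.theta) == 0

    def test_small_penalty_approaches_inverse_covariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 5)) * 0.3 + np.eye(5)
        X = rng.normal(size=(2000, 5)) @ A.T
        pm = glasso_fit(X, lam=1e-5)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        target = np.linalg.inv(np.corrcoef(Z.T))
        assert np.abs(pm.theta - target).max() < 1e-3

    def test_chain_graph_drops_shielded_edge(self):
        # X -> Y -> Z: X and Z conditionally independent given Y
        rng = np.random.default_rng(2)
        x = rng.normal(size=3000)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.normal(size=3000)
        z = 0.5 * y + math.sqrt(1 - 0.25) * rng.normal(size=3000)
        pm = glasso_fit(np.column_stack([x, y, z]), lam=0.1,
                        metabolite_ids=["x", "y", "z"])
        net = to_partial_correlation(pm)
        assert net.has_edge("x", "y") and net.has_edge("y", "z")
        assert not net.has_edge("x", "z")

    def test_support_shrinks_along_path(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 12))
        X[:, 1] += X[:, 0]
        X[:, 2] += X[:, 1]
        counts = [_offdiag_support_count(glasso_fit(X, lam).theta)
                  for lam in default_lambda_path(X, n_lambdas=10)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_nonfinite_and_tiny_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            glasso_fit(np.array([[1.0, np.nan]] * 5), 0.1)
        with pytest.raises(ValueError, match="at least 3 samples"):
            glasso_fit(np.zeros((2, 4)), 0.1)


class TestStars:
    def test_pure_noise_selects_near_empty_graph(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(1000, 20))
        sel = stars_select(X, seed=0)
        pm = glasso_fit(X, sel.selected_lambda)
        density = _offdiag_support_count(pm.theta) / (20 * 19 / 2)
        assert density < 0.02

    def test_zero_threshold_forces_sparsest_end(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        X[:, 1] += 2 * X[:, 0]
        sel = stars_select(X, instability_threshold=0.0, seed=0)
        # only penalties with exactly zero instability qualify; the largest
        # lambda is the fallback when even those are absent
        qualifying = sel.lambda_path[sel.instability_per_lambda <= 0.0]
        if sel.all_unstable:
            assert sel.selected_lambda == sel.lambda_path[0]
        else:
            assert sel.selected_lambda == qualifying.min()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 10))
        X[:, 3] += X[:, 2]
        a = stars_select(X, seed=123)
        b = stars_select(X, seed=123)
        assert a.selected_lambda == b.selected_lambda
        assert np.array_equal(a.instability_per_lambda,
                              b.instability_per_lambda)

    def test_instabilities_within_range_and_lambda_on_path(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        sel = stars_select(X, seed=1)
        assert ((sel.instability_per_lambda >= 0)
                & (sel.instability_per_lambda <= 0.5)).all()
        assert sel.selected_lambda in sel.lambda_path


class TestPartialCorrelation:
    def test_two_by_two_closed_form(self):
        pm = PrecisionMatrix(["a", "b"], np.array([[2.0, -1.0], [-1.0, 2.0]]))
        net = to_partial_correlation(pm)
        assert net.weight("a", "b") == pytest.approx(0.5)

    def test_diagonal_theta_gives_edgeless_network(self):
        pm = PrecisionMatrix(["a", "b", "c"], np.diag([1.0, 2.0, 3.0]))
        assert to_partial_correlation(pm).n_edges() == 0

    def test_matches_elementwise_formula_on_random_spd(self):
        rng = np.random.default_rng(8)
        B = rng.normal(size=(8, 8)) * (rng.random((8, 8)) < 0.3)
        theta = B @ B.T + np.eye(8) * 8
        ids = make_ids(8)
        net = to_partial_correlation(PrecisionMatrix(ids, theta))
        for i, j in itertools.combinations(range(8), 2):
            expected = -theta[i, j] / np.sqrt(theta[i, i] * theta[j, j])
            if abs(theta[i, j]) > 1e-12:
                assert net.weight(ids[i], ids[j]) == pytest.approx(expected)
            else:
                assert not net.has_edge(ids[i], ids[j])

    def test_asymmetric_theta_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            PrecisionMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestPruning:
    def _net(self, ids, pairs):
        net = CoPerturbationNetwork(ids)
        for a, b in pairs:
            net.add_edge(a, b, 0.5)
        return net

    def test_shared_edges_removed_nodes_kept(self):
        ids = ["A", "B", "C"]
        target = self._net(ids, [("A", "B"), ("B", "C")])
        background = self._net(ids, [("B", "C")])
        out = differential_prune(target, background)
        assert set(out.edges()) == {("A", "B")}
        assert out.nodes() == target.nodes()

    def test_self_prune_empties_and_empty_background_is_identity(self):
        ids = make_ids(5)
        target = self._net(ids, [("n00", "n01"), ("n02", "n03")])
        assert differential_prune(target, target).n_edges() == 0
        kept = differential_prune(target, CoPerturbationNetwork(ids))
        assert kept.edges() == target.edges()

    def test_prune_ignores_weight_differences(self):
        ids = ["A", "B"]
        target = self._net(ids, [("A", "B")])
        background = CoPerturbationNetwork(ids)
        background.add_edge("A", "B", -0.123)  # different weight, same pair
        assert differential_prune(target, background).n_edges() == 0

    def test_random_networks_match_set_difference_oracle(self):
        rng = np.random.default_rng(9)
        ids = make_ids(30)
        all_pairs = list(itertools.combinations(ids, 2))
        t_pairs = [p for p in all_pairs if rng.random() < 0.2]
        b_pairs = [p for p in all_pairs if rng.random() < 0.2]
        out = differential_prune(self._net(ids, t_pairs),
                                 self._net(ids, b_pairs))
        assert set(out.edges()) == set(t_pairs) - set(b_pairs)

    def test_prune_nodes_triangle_and_noop(self):
        tri = self._net(["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])
        out = prune_nodes(tri, {"C"})
        assert set(out.edges()) == {("A", "B")} and out.nodes() == ("A", "B")
        same = prune_nodes(tri, set())
        assert same.edges() == tri.edges() and same.nodes() == tri.nodes()
        assert prune_nodes(tri, {"ZZ"}).edges() == tri.edges()

    def test_prune_nodes_matches_induced_subgraph_oracle(self):
        rng = np.random.default_rng(10)
        ids = make_ids(20)
        pairs = [p for p in itertools.combinations(ids, 2)
                 if rng.random() < 0.3]
        net = self._net(ids, pairs)
        drop = set(rng.choice(ids, size=10, replace=False))
        out = prune_nodes(net, drop)
        import networkx as nx

        g = net.to_networkx()
        g.remove_nodes_from(drop)
        assert set(out.edges()) == {tuple(sorted(e)) for e in g.edges()}
        assert set(out.nodes()) == set(g.nodes())


class TestSerialization:
    def test_network_round_trips_exactly(self, tmp_path):
        rng = np.random.default_rng(11)
        ids = make_ids(12)
        net = CoPerturbationNetwork(
            ids, provenance={"condition_label": "demo", "lambda_selected": 0.3})
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.25:
                net.add_edge(a, b, float(rng.uniform(-1, 1)))
        edge_path = tmp_path / "net.edges.tsv"
        sidecar = tmp_path / "net.json"
        write_network(net, edge_path, sidecar)
        back = read_network(edge_path, sidecar)
        assert back == net
        assert back.provenance["condition_label"] == "demo"

    def test_edge_list_alone_implies_node_set(self, tmp_path):
        net = CoPerturbationNetwork(["a", "b", "c"])
        net.add_edge("a", "b", 0.25)
        p = tmp_path / "n.tsv"
        write_network(net, p)
        back = read_network(p)
        assert set(back.nodes()) == {"a", "b"}
        assert back.weight("a", "b") == 0.25


class TestLearnNetworks:
    def test_too_few_samples_rejected(self, small_profiles):
        two = small_profiles.select_samples(["s0", "s1"])
        with pytest.raises(ValueError, match="at least 3"):
            learn_disease_network(two, small_profiles)
        with pytest.raises(ValueError, match="at least 3"):
            learn_treatment_network(small_profiles,
                                    small_profiles.select_samples([]),
                                    small_profiles)

    def test_surrogate_count_recorded_in_provenance(self):
        from ctdnet import CohortSpec, make_cohort

        matrix, meta = make_cohort(CohortSpec(
            n_metabolites=12, n_disease=6, n_reference=12, seed=2,
            module_nodes=tuple(f"met{i:03d}" for i in range(4))))
        dis = matrix.select_samples(
            [m.sample_id for m in meta if m.role == "disease"])
        ref = matrix.select_samples(
            [m.sample_id for m in meta if m.role == "reference"])
        config = NetworkConfig(seed=0, n_surrogates=4, n_lambdas=8)
        with pytest.warns(UserWarning):
            net = learn_disease_network(dis, ref, config)
        assert net.provenance["n_surrogates"] == 4
        assert net.provenance["lambda_selected"] > 0
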