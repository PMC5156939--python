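"""Sparse local graphical model: node regressions, penalty selection,
network assembly, module extraction, export."""

import numpy as np
import networkx as nx
import pytest

from uromet.network import (
    NetworkPair,
    _lambda_max,
    _node_design,
    _path_fits,
    build_networks,
    export_network,
    extract_module,
    node_lasso,
    read_sif,
    select_lambda,
)
from uromet.preprocess import autoscale, log2_transform
from uromet.synthetic_data import SyntheticSpec, edge_recovery, generate_dataset


def autoscaled(values):
    v = np.asarray(values, dtype=float)
    return (v - v.mean(0)) / v.std(0, ddof=1)


def synthetic_scaled(seed, n_case=250, n_control=250, p=10, n_common=5, n_diff=0,
                     strength=0.4):
    spec = SyntheticSpec(
        n_case=n_case, n_control=n_control, p_known=p, p_unknown=0,
        n_common_edges=n_common, n_diff_edges=n_diff, edge_strength=strength,
        seed=seed,
    )
    matrix, truth = generate_dataset(spec)
    scaled = autoscale(log2_transform(matrix))
    return scaled, truth


class TestNodeLasso:
    def test_zero_penalty_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        X = autoscaled(rng.standard_normal((100, 5)))
        y = np.array([0, 1] * 50)
        fit = node_lasso(0, X, y, 0.0, 0.0)
        Z, target, *_ = _node_design(0, X, y)
        ols, *_ = np.linalg.lstsq(Z, target, rcond=None)
        est = np.concatenate([fit.alpha, [fit.beta_0], fit.beta])
        assert np.abs(est - ols).max() <= 1e-6

    def test_large_penalty_zeroes_all_penalized_coefficients(self):
        rng = np.random.default_rng(1)
        X = autoscaled(rng.standard_normal((60, 6)))
        y = np.array([0, 1] * 30)
        Z, target, _, pen_a, pen_b = _node_design(0, X, y)
        lam_max = _lambda_max(Z, target, (pen_a + pen_b) > 0)
        fit = node_lasso(0, X, y, lam_max, lam_max)
        assert np.all(np.abs(fit.alpha) <= 1e-10)
        assert np.all(np.abs(fit.beta) <= 1e-10)

    def test_no_group_effect_leaves_beta_empty(self):
        # identical precisions: the interaction block should be selected
        # empty at the BIC-chosen penalty in >= 18/20 seeds
        empty = 0
        for seed in range(20):
            scaled, _ = synthetic_scaled(seed)
            la, lb = select_lambda(0, scaled.values, scaled.y)
            fit = node_lasso(0, scaled.values, scaled.y, la, lb)
            empty += int(np.count_nonzero(np.abs(fit.beta) > 1e-8) == 0)
        assert empty >= 18

    def test_nonbinary_labels_rejected(self):
        rng = np.random.default_rng(2)
        X = autoscaled(rng.standard_normal((20, 4)))
        with pytest.raises(ValueError, match="binary"):
            node_lasso(0, X, np.arange(20), 0.1, 0.1)

    def test_lambda_monotone_support_along_path(self):
        rng = np.random.default_rng(3)
        scaled, _ = synthetic_scaled(3, n_case=100, n_control=100)
        Z, target, _, pen_a, pen_b = _node_design(0, scaled.values, scaled.y)
        pen = pen_a + pen_b
        lam_max = _lambda_max(Z, target, pen > 0)
        lambdas = np.geomspace(lam_max, lam_max * 0.01, 10)
        fits = _path_fits(Z, target, pen, lambdas)
        supports = [frozenset(np.flatnonzero(np.abs(t) > 1e-8)) for t in fits]
        for big, small in zip(supports[:-1], supports[1:]):
            assert big <= small


class TestSelectLambda:
    def test_pure_noise_selects_nearly_nothing(self):
        nnz = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = autoscaled(rng.standard_normal((100, 6)))
            y = np.array([0, 1] * 50)
            la, lb = select_lambda(0, X, y)
            fit = node_lasso(0, X, y, la, lb)
            nnz.append(
                np.count_nonzero(np.abs(fit.alpha) > 1e-8)
                + np.count_nonzero(np.abs(fit.beta) > 1e-8)
            )
        assert np.mean(nnz) <= 1.0

    def test_strong_predictor_survives(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((100, 6))
            X[:, 0] = 5 * X[:, 1] + 0.1 * rng.standard_normal(100)
            X = autoscaled(X)
            y = np.array([0, 1] * 50)
            la, lb = select_lambda(0, X, y)
            fit = node_lasso(0, X, y, la, lb)
            assert abs(fit.alpha[0]) > 1e-8  # predictor 1 is first "other"

    def test_deterministic(self):
        scaled, _ = synthetic_scaled(5, n_case=100, n_control=100)
        a = select_lambda(2, scaled.values, scaled.y, method="bic")
        b = select_lambda(2, scaled.values, scaled.y, method="bic")
        assert a == b
        c = select_lambda(2, scaled.values, scaled.y, method="cv", seed=4)
        d = select_lambda(2, scaled.values, scaled.y, method="cv", seed=4)
        assert c == d

    def test_unknown_method_rejected(self):
        scaled, _ = synthetic_scaled(6, n_case=20, n_control=20)
        with pytest.raises(ValueError, match="method"):
            select_lambda(0, scaled.values, scaled.y, method="aic")


class TestBuildNetworks:
    def test_common_edges_recovered_and_no_false_differentials(self):
        scaled, truth = synthetic_scaled(7, n_case=250, n_control=250)
        net = build_networks(scaled.values, scaled.y, scaled.feature_ids)
        rec, prec = edge_recovery(net.common_edges, truth.common_edges,
                                  scaled.feature_ids)
        assert rec >= 0.8
        n_pairs = 10 * 9 / 2
        assert len(net.diff_edges) / n_pairs <= 0.05

    def test_differential_edges_recovered(self):
        scaled, truth = synthetic_scaled(8, n_case=500, n_control=500, p=20,
                                         n_common=10, n_diff=5)
        net = build_networks(scaled.values, scaled.y, scaled.feature_ids)
        rec, prec = edge_recovery(net.diff_edges, truth.diff_edges,
                                  scaled.feature_ids)
        assert rec >= 0.8 and prec >= 0.7

    def test_and_rule_subset_of_or_rule(self):
        scaled, _ = synthetic_scaled(9, n_case=150, n_control=150)
        net_or = build_networks(scaled.values, scaled.y, scaled.feature_ids,
                                symmetrize="or")
        net_and = build_networks(scaled.values, scaled.y, scaled.feature_ids,
                                 symmetrize="and")
        assert net_and.edge_set("common") <= net_or.edge_set("common")
        assert net_and.edge_set("diff") <= net_or.edge_set("diff")

    def test_feature_relabeling_invariance(self):
        scaled, _ = synthetic_scaled(10, n_case=150, n_control=150, p=8, n_common=4)
        net = build_networks(scaled.values, scaled.y, scaled.feature_ids)
        perm = np.random.default_rng(0).permutation(8)
        ids_p = tuple(scaled.feature_ids[j] for j in perm)
        net_p = build_networks(scaled.values[:, perm], scaled.y, ids_p)
        assert net.edge_set("common") == net_p.edge_set("common")
        assert net.edge_set("diff") == net_p.edge_set("diff")

    def test_recovery_improves_with_sample_size(self):
        recalls = []
        for n in (100, 250, 500):
            per_seed = []
            for seed in (1, 2, 3):
                scaled, truth = synthetic_scaled(
                    100 + seed, n_case=n, n_control=n, p=10, n_common=4, n_diff=3
                )
                net = build_networks(scaled.values, scaled.y, scaled.feature_ids)
                rec, _ = edge_recovery(net.diff_edges, truth.diff_edges,
                                       scaled.feature_ids)
                per_seed.append(rec)
            recalls.append(np.median(per_seed))
        assert recalls[0] <= recalls[1] <= recalls[2] or recalls[2] == 1.0


def chain_network():
    return NetworkPair(
        nodes=("a", "b", "c", "d"),
        common_edges=(("a", "d", 0.5),),
        diff_edges=(("a", "b", 0.4), ("b", "c", -0.3)),
    )


class TestExtractModule:
    def test_connected_component(self):
        mod = extract_module(chain_network(), "a", mode="component")
        assert set(mod.nodes) == {"a", "b", "c"}
        assert len(mod.edges) == 2

    def test_radius_one(self):
        mod = extract_module(chain_network(), "a", mode="radius1")
        assert set(mod.nodes) == {"a", "b"}

    def test_isolated_seed_single_node(self):
        mod = extract_module(chain_network(), "d", mode="component")
        assert mod.nodes == ("d",)
        assert mod.edges == ()

    def test_upregulated_flags_joined(self):
        mod = extract_module(
            chain_network(), "a", upregulated={"a": True, "b": False}
        )
        assert mod.upregulated == {"a": True, "b": False, "c": False}

    def test_missing_seed_rejected(self):
        with pytest.raises(KeyError):
            extract_module(chain_network(), "zzz")


class TestExport:
    def test_sif_edges_and_isolated_nodes(self, tmp_path):
        path = tmp_path / "net.sif"
        export_network(chain_network(), "sif", path)
        nodes, edges = read_sif(path)
        assert nodes == {"a", "b", "c", "d"}
        assert ("a", "common", "d") in edges
        assert ("a", "diff", "b") in edges
        assert len(edges) == 3

    def test_empty_network_lists_singletons(self, tmp_path):
        net = NetworkPair(nodes=("x", "y"), common_edges=(), diff_edges=())
        path = tmp_path / "empty.sif"
        export_network(net, "sif", path)
        nodes, edges = read_sif(path)
        assert nodes == {"x", "y"} and edges == []

    def test_graphml_round_trip(self, tmp_path):
        path = tmp_path / "net.graphml"
        net = chain_network()
        export_network(net, "graphml", path)
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(net.nodes)
        got = {frozenset(e) for e in g.edges}
        want = {frozenset((a, b)) for a, b, _ in net.common_edges + net.diff_edges}
        assert got == want
        assert g.edges["a", "b"]["layer"] == "diff"
        assert g.edges["a", "b"]["weight"] == pytest.approx(0.4)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(chain_network(), "xgmml", tmp_path / "x")
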