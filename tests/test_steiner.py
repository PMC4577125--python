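"""Tests for prize-collecting Steiner tree construction and solvers."""

import itertools
import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crossomics import (ConfigurationError, combine_edge_evidence, calibrate_lambda,
                        find_module, node_prize, pcst_exact, pcst_heuristic,
                        select_candidates)
from crossomics.steiner import build_prize_graph, pcst_exact_sweep


def brute_force_pcst(G, lam):
    """Independent oracle: itertools subsets + networkx connectivity/MST."""
    best = (0.0, frozenset())
    nodes = list(G.nodes)
    for k in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, k):
            H = G.subgraph(subset)
            if not nx.is_connected(H):
                continue
            cost = sum(d["cost"] for _, _, d in
                       nx.minimum_spanning_tree(H, weight="cost").edges(data=True))
            prize = sum(G.nodes[n]["prize"] for n in subset)
            obj = cost - lam * prize
            if obj < best[0] - 1e-12:
                best = (obj, frozenset(subset))
    return best


def random_prize_graph(rng, n=None):
    n = n or int(rng.integers(5, 13))
    G = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
    H = nx.Graph()
    for v in G.nodes:
        H.add_node(f"n{v:02d}", prize=float(-math.log(max(rng.uniform(), 1e-6))))
    for u, v in G.edges:
        H.add_edge(f"n{u:02d}", f"n{v:02d}", cost=float(rng.uniform(0.05, 1.0)))
    return H


class TestGraphConstruction:
    def test_select_candidates_union_counts_once(self):
        tbl = pd.DataFrame({"p_inte": [0.001, 0.01, 0.3], "q_inte": [0.01, 0.4, 0.9]},
                           index=["a", "b", "c"])
        pw = pd.DataFrame({"significant": [True]}, index=["pw1"])
        cand = select_candidates(tbl, pw, {"pw1": {"a", "b"}})
        assert cand == {"a", "b"}

    def test_empty_candidates_is_an_error(self):
        tbl = pd.DataFrame({"p_inte": [0.5], "q_inte": [0.9]}, index=["a"])
        with pytest.raises(ConfigurationError):
            select_candidates(tbl, None, None, q_thresh=0.0, p_thresh=0.0)

    @pytest.mark.parametrize("string, corr, use_corr, cost", [
        (0.9, 0.0, False, 0.1),
        (0.9, -0.5, True, 1 - 0.9 * 0.5),
        (0.0, 0.8, True, 1.0),
    ])
    def test_edge_cost_product_form(self, string, corr, use_corr, cost):
        _, c = combine_edge_evidence(string, corr, use_corr=use_corr)
        assert c == pytest.approx(cost, abs=1e-12)

    def test_edge_evidence_range_errors(self):
        with pytest.raises(ConfigurationError):
            combine_edge_evidence(1.2, 0.0)
        with pytest.raises(ConfigurationError):
            combine_edge_evidence(0.5, 1.5)

    @pytest.mark.parametrize("p, b", [(1.0, 0.0), (0.05, 2.996), (1e-16, 36.84)])
    def test_node_prize_natural_log(self, p, b):
        assert node_prize(p) == pytest.approx(b, abs=5e-3)

    def test_prize_floor_applies_below_1e16(self):
        assert node_prize(1e-30) == pytest.approx(-math.log(1e-16), rel=1e-9)

    def test_invalid_p_is_an_error(self):
        with pytest.raises(ConfigurationError):
            node_prize(1.5)


class TestExactSolver:
    def test_single_positive_prize_node(self):
        G = build_prize_graph({"a": 2.0}, [])
        mod = pcst_exact(G, 0.5)
        assert mod.nodes == ("a",)
        assert mod.objective == pytest.approx(-1.0)

    def test_lambda_zero_returns_highest_prize_singleton(self):
        G = build_prize_graph({"a": 1.0, "b": 5.0, "c": 2.0},
                              [("a", "b", 0.5), ("b", "c", 0.5)])
        mod = pcst_exact(G, 0.0)
        assert mod.nodes == ("b",)
        assert mod.objective == 0.0

    def test_four_node_fixture_matches_bruteforce(self):
        # triangle a-b-c plus pendant d; prizes favour the a-b pair
        G = build_prize_graph(
            {"a": 3.0, "b": 3.0, "c": 0.1, "d": 0.1},
            [("a", "b", 0.4), ("b", "c", 0.9), ("a", "c", 0.8), ("c", "d", 0.3)])
        mod = pcst_exact(G, 0.62)
        obj, nodes = brute_force_pcst(G, 0.62)
        assert mod.objective == pytest.approx(obj, abs=1e-12)
        assert set(mod.nodes) == set(nodes)

    def test_returns_empty_when_everything_costs(self):
        G = build_prize_graph({"a": 0.0, "b": 0.0}, [("a", "b", 0.9)])
        mod = pcst_exact(G, 0.5)
        assert mod.is_empty and mod.objective == 0.0

    def test_module_is_always_a_tree(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            G = random_prize_graph(rng, n=8)
            mod = pcst_exact(G, 0.5)
            assert len(mod.edges) == max(0, len(mod.nodes) - 1)

    def test_node_limit_error(self):
        G = build_prize_graph({f"n{i}": 1.0 for i in range(16)}, [])
        with pytest.raises(ConfigurationError):
            pcst_exact(G, 0.5)

    def test_collected_prize_monotone_in_lambda(self):
        rng = np.random.default_rng(23)
        G = random_prize_graph(rng, n=10)
        sols = pcst_exact_sweep(G, np.arange(0.1, 1.01, 0.1))
        prizes = [sols[l].prize_total for l in sorted(sols)]
        assert all(a <= b + 1e-12 for a, b in zip(prizes, prizes[1:]))


class TestHeuristicSolver:
    def test_never_worse_than_best_singleton(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            G = random_prize_graph(rng)
            lam = float(rng.uniform(0.1, 1.0))
            mod = pcst_heuristic(G, lam)
            best_singleton = min(-lam * G.nodes[v]["prize"] for v in G.nodes)
            assert mod.objective <= best_singleton + 1e-12

    def test_deterministic(self):
        G = random_prize_graph(np.random.default_rng(5))
        a = pcst_heuristic(G, 0.4)
        b = pcst_heuristic(G, 0.4)
        assert a.nodes == b.nodes and a.objective == b.objective

    def test_exact_on_trees(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            T = nx.random_labeled_tree(9, seed=int(rng.integers(2**31)))
            G = nx.Graph()
            for v in T.nodes:
                G.add_node(f"n{v}", prize=float(-math.log(max(rng.uniform(), 1e-6))))
            for u, v in T.edges:
                G.add_edge(f"n{u}", f"n{v}", cost=float(rng.uniform(0.05, 1.0)))
            lam = float(rng.uniform(0.1, 0.9))
            assert pcst_heuristic(G, lam).objective == pytest.approx(
                pcst_exact(G, lam).objective, abs=1e-9)


class TestCalibrateLambda:
    def test_zero_target_returns_first_sweep_value(self):
        lam, _ = calibrate_lambda(12, 0.2, 4, recovery_target=0.0,
                                  lambdas=[0.01, 0.5], n_sim=2, seed=0)
        assert lam == 0.01

    def test_unattainable_target_returns_max_with_warning(self):
        with pytest.warns(UserWarning):
            lam, _ = calibrate_lambda(12, 0.2, 4, recovery_target=1.01,
                                      lambdas=[0.1, 0.9], n_sim=2, seed=0)
        assert lam == 0.9

    def test_reproducible_and_self_consistent(self):
        lam1, rep1 = calibrate_lambda(20, 0.1, 6, n_sim=3, seed=7)
        lam2, rep2 = calibrate_lambda(20, 0.1, 6, n_sim=3, seed=7)
        assert lam1 == lam2
        pd.testing.assert_frame_equal(rep1, rep2)
        hit = rep1.loc[rep1["lambda"] == lam1, "mean_recovery"].iloc[0]
        assert hit >= 0.70


class TestFindModule:
    def test_tiny_lambda_gives_singleton(self, small_dataset):
        from crossomics import integrate
        from crossomics.io import edge_list_to_graph
        tbl = integrate({"exp": small_dataset.expression,
                         "methy": small_dataset.methylation}, seed=3)
        cands = set(tbl.index[tbl["p_inte"] <= 0.05])
        mod, _ = find_module(cands, edge_list_to_graph(small_dataset.interactome),
                             small_dataset.expression, tbl, lam=1e-6)
        assert len(mod) <= 1

    def test_disconnected_candidates_without_linkers(self):
        tbl = pd.DataFrame({"p_inte": [0.001, 0.002], "q_inte": [0.01, 0.01]},
                           index=["a", "b"])
        inter = nx.Graph()
        inter.add_edge("a", "x", reliability=0.9)
        inter.add_edge("x", "b", reliability=0.9)
        mod, _ = find_module({"a", "b"}, inter, None, tbl, lam=0.5,
                             allow_linkers=False)
        assert len(mod) == 1  # best singleton: no direct a-b edge

    def test_linkers_bridge_disconnected_candidates(self):
        tbl = pd.DataFrame({"p_inte": [0.001, 0.002], "q_inte": [0.01, 0.01]},
                           index=["a", "b"])
        inter = nx.Graph()
        inter.add_edge("a", "x", reliability=0.9)
        inter.add_edge("x", "b", reliability=0.9)
        mod, G = find_module({"a", "b"}, inter, None, tbl, lam=0.5,
                             allow_linkers=True)
        assert set(mod.nodes) == {"a", "b", "x"}
        assert G.nodes["x"]["prize"] == 0.0

    def test_candidates_absent_from_interactome_error(self):
        tbl = pd.DataFrame({"p_inte": [0.01], "q_inte": [0.05]}, index=["zz"])
        with pytest.raises(ConfigurationError):
            find_module({"zz"}, nx.Graph([("a", "b", {"reliability": 0.5})]),
                        None, tbl, lam=0.5)
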