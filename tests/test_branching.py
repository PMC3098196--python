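"""Galton-Watson tree generation and the mean-field occupation theory."""

import io

import numpy as np
import pytest
from hypothesis import given, strategies as st

from toolboxnet import (
    BranchingParams,
    algebraic_growth_curve,
    criticality_profile,
    layer_stats,
    mean_field_iterate,
    read_tree,
    sample_tree,
    steady_state_fraction,
    write_tree,
)
from toolboxnet.branching import LayeredTree
from toolboxnet.errors import BudgetExceededError, SamplingFailureError

CRITICAL = BranchingParams(0.25, 0.5, 0.25)
SUPER = BranchingParams(0.15, 0.60, 0.25)


class TestBranchingParams:
    def test_mean_offspring_and_criticality(self):
        assert CRITICAL.mean_offspring == pytest.approx(1.0)
        assert CRITICAL.is_critical
        assert SUPER.mean_offspring == pytest.approx(1.1)
        assert SUPER.is_supercritical

    @pytest.mark.parametrize("probs", [(-0.1, 0.6, 0.5), (0.4, 0.4, 0.4)])
    def test_invalid_probabilities_rejected(self, probs):
        with pytest.raises(ValueError):
            BranchingParams(*probs)


class TestSampleTree:
    def test_all_extinct_gives_single_root(self):
        tree = sample_tree(BranchingParams(1.0, 0.0, 0.0), seed=0)
        assert tree.n_nodes == 1
        assert tree.n_leaves == 1  # the root is its own leaf

    def test_pure_path(self):
        tree = sample_tree(BranchingParams(0.0, 1.0, 0.0), depth=5, seed=0)
        assert tree.n_nodes == 6
        assert tree.depth == 5
        assert tree.n_leaves == 1
        M, L, B = layer_stats(tree)
        assert np.array_equal(M, np.ones(6, dtype=int))
        assert np.array_equal(L, [0, 0, 0, 0, 0, 1])
        assert not B.any()

    def test_ensemble_mean_layer_size_is_one_for_critical(self):
        """E[M_d] = Lambda**d = 1: the martingale property of the process."""
        rng_seed = 1234
        depth = 6
        counts = np.zeros(depth + 1)
        n = 10_000
        for k in range(n):
            tree = sample_tree(CRITICAL, depth=depth, seed=rng_seed + k)
            M = np.bincount(tree.depths, minlength=depth + 1)
            counts += M
        mean = counts / n
        # per-level standard error of M_d grows with d; variance of M_d for
        # a critical binary process is Var = sigma^2 * d (sigma^2 = 0.5)
        for d in range(1, depth + 1):
            se = np.sqrt(0.5 * d / n)
            assert abs(mean[d] - 1.0) < 3 * se

    def test_size_conditioning_window(self):
        tree = sample_tree(CRITICAL, size=500, tol=0.1, seed=3)
        assert 450 <= tree.n_nodes <= 550

    def test_unreachable_size_window_raises(self):
        with pytest.raises(SamplingFailureError):
            # a pure-extinction process only produces single-node trees
            sample_tree(BranchingParams(1.0, 0.0, 0.0), size=50, tol=0.1,
                        max_attempts=20, seed=0)

    def test_supercritical_without_depth_exceeds_budget(self):
        with pytest.raises(BudgetExceededError):
            sample_tree(BranchingParams(0.0, 0.0, 1.0), node_budget=1000, seed=0)


class TestLayerStats:
    def test_full_binary_tree_depth_two(self):
        parents = np.array([-1, 0, 0, 1, 1, 2, 2])
        depths = np.array([0, 1, 1, 2, 2, 2, 2])
        M, L, B = layer_stats(LayeredTree(parents, depths))
        assert np.array_equal(M, [1, 2, 4])
        assert np.array_equal(L, [0, 0, 4])
        assert np.array_equal(B, [1, 2, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_conservation_on_sampled_trees(self, seed):
        tree = sample_tree(CRITICAL, size=300, tol=0.3, seed=seed)
        M, L, B = layer_stats(tree)
        assert np.array_equal(M[1:], M[:-1] - L[:-1] + B[:-1])
        assert M.sum() == tree.n_nodes
        assert L.sum() == tree.n_leaves


class TestCriticalityProfile:
    @pytest.mark.parametrize(
        "M, expected",
        [
            (np.ones(5), np.ones(4)),
            (2.0 ** np.arange(5), 2 * np.ones(4)),
            (np.arange(1, 6), np.array([2, 3 / 2, 4 / 3, 5 / 4])),
        ],
    )
    def test_ratio_examples(self, M, expected):
        assert criticality_profile(M) == pytest.approx(expected)

    def test_linear_growth_matches_reference_curve(self):
        d = np.arange(1, 5)
        assert criticality_profile(np.arange(1, 6)) == pytest.approx(
            algebraic_growth_curve(d)
        )

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            criticality_profile([5.0])


class TestMeanField:
    def test_full_acquisition_occupies_everything(self):
        tree = sample_tree(CRITICAL, size=400, tol=0.2, seed=7)
        prof = mean_field_iterate(layer_stats(tree), 1.0)
        assert prof.p == pytest.approx(np.ones_like(prof.p))
        assert prof.m == pytest.approx(layer_stats(tree).M.astype(float))

    def test_zero_acquisition_occupies_nothing(self):
        tree = sample_tree(CRITICAL, size=400, tol=0.2, seed=7)
        prof = mean_field_iterate(layer_stats(tree), 0.0)
        assert not prof.m.any()

    @pytest.mark.parametrize("x", [0.01, 0.25, 0.81])
    def test_critical_bulk_converges_to_sqrt_x(self, x):
        prof = mean_field_iterate(CRITICAL, x, depth=500)
        assert prof.p_bulk == pytest.approx(np.sqrt(x), abs=1e-6)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            mean_field_iterate(CRITICAL, 1.5, depth=10)


class TestSteadyState:
    def test_critical_is_sqrt(self):
        assert steady_state_fraction(CRITICAL, 0.16) == pytest.approx(0.4)

    def test_supercritical_onset(self):
        # x -> 0+ limit of the first-order-like transition: 1 - p0/p2
        assert steady_state_fraction(SUPER, 1e-15) == pytest.approx(0.4, abs=1e-6)

    @pytest.mark.parametrize("params", [CRITICAL, SUPER, BranchingParams(0.5, 0.2, 0.3)])
    def test_everything_at_x_one(self, params):
        assert steady_state_fraction(params, 1.0) == pytest.approx(1.0)

    def test_pure_path_fraction_is_x(self):
        assert steady_state_fraction(BranchingParams(0.0, 1.0, 0.0), 0.3) == 0.3

    @given(
        x1=st.floats(0, 1), x2=st.floats(0, 1),
        p0=st.floats(0.01, 0.45), p2=st.floats(0.01, 0.45),
    )
    def test_monotone_in_x(self, x1, x2, p0, p2):
        params = BranchingParams(p0, 1.0 - p0 - p2, p2)
        lo, hi = sorted((x1, x2))
        assert steady_state_fraction(params, lo) <= steady_state_fraction(params, hi) + 1e-12

    def test_agrees_with_mean_field_bulk(self):
        for params in (CRITICAL, SUPER):
            for x in (0.05, 0.3, 0.7):
                bulk = mean_field_iterate(params, x, depth=600).p_bulk
                assert bulk == pytest.approx(steady_state_fraction(params, x), abs=1e-5)


class TestSerialization:
    def test_round_trip_exact(self):
        tree = sample_tree(CRITICAL, size=200, tol=0.3, seed=9)
        tree.meta["seed"] = 9
        buf = io.StringIO()
        write_tree(tree, buf)
        buf.seek(0)
        back = read_tree(buf)
        assert np.array_equal(back.parents, tree.parents)
        assert np.array_equal(back.depths, tree.depths)
        assert back.meta == tree.meta

    def test_round_trip_with_labels(self):
        tree = LayeredTree(
            np.array([-1, 0, 1]), np.array([0, 1, 2]), labels=["root", "a", "b"]
        )
        buf = io.StringIO()
        write_tree(tree, buf)
        buf.seek(0)
        assert read_tree(buf).labels == ["root", "a", "b"]


class TestMeanFieldProperties:
    @given(
        x=st.floats(0.0, 1.0),
        p0=st.floats(0.05, 0.45),
        p2=st.floats(0.05, 0.45),
    )
    def test_occupation_profile_stays_in_unit_interval(self, x, p0, p2):
        params = BranchingParams(p0, 1.0 - p0 - p2, p2)
        prof = mean_field_iterate(params, x, depth=60)
        assert np.all(prof.p >= 0.0) and np.all(prof.p <= 1.0)
        assert prof.lam == pytest.approx(x * np.asarray(
            __import__("toolboxnet").expected_layer_stats(params, 60).L))
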