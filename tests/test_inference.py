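import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

import phenotrans as pt
from phenotrans.inference import (
    RawRootMatrix,
    average_estimates,
    clip_and_renormalize,
    estimate_root,
    extract_graph,
    fit_root_by_optimization,
    principal_root,
    regularize,
)
from phenotrans.io import ProportionMatrix
from phenotrans.simulate import random_reversible_chain


def _wn(space, p, n):
    return ProportionMatrix(np.linalg.matrix_power(p, n), t=n, space=space)


class TestEstimateRoot:
    def test_identity_snapshot_gives_identity(self, space4, identity_w0):
        raw = estimate_root(identity_w0(space4), _wn(space4, np.eye(4), 5))
        assert np.abs(raw.values - np.eye(4)).max() < 1e-12

    def test_recovers_two_state_chain_from_square(self, space2, identity_w0):
        p_true = np.array([[0.9, 0.1], [0.2, 0.8]])
        wn = _wn(space2, p_true, 2)
        assert np.allclose(wn.values, [[0.83, 0.17], [0.34, 0.66]])
        raw = estimate_root(identity_w0(space2), wn)
        assert np.abs(raw.values - p_true).max() < 1e-10

    def test_sixteen_state_shape_and_realness(self, space16, identity_w0):
        rng = np.random.default_rng(0)
        p = random_reversible_chain(16, 0.8, rng)
        raw = estimate_root(identity_w0(space16), _wn(space16, p, 20))
        assert raw.values.shape == (16, 16)
        assert raw.values.dtype.kind == "f"
        assert raw.max_imag < 1e-8

    def test_singular_w0_rejected(self, space2):
        w0 = ProportionMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]), t=0, space=space2)
        with pytest.raises(ValueError, match="singular"):
            estimate_root(w0, _wn(space2, np.eye(2), 3))

    def test_matches_scipy_fractional_power_oracle(self, space16, identity_w0):
        # independent oracle: Schur-Pade fractional matrix power
        rng = np.random.default_rng(7)
        p = random_reversible_chain(16, 0.7, rng)
        n = 12
        raw = estimate_root(identity_w0(space16), _wn(space16, p, n))
        oracle = scipy.linalg.fractional_matrix_power(
            np.linalg.matrix_power(p, n), 1.0 / n
        )
        assert np.abs(raw.values - np.real(oracle)).max() < 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 30))
    def test_oracle_recovery_across_horizons(self, seed, n):
        # real positive spectrum => principal root of P^n is exactly P;
        # laziness keeps every mode above double-precision rounding at n=30
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        p = random_reversible_chain(k, 0.8, rng)
        values, max_imag, ok = principal_root(np.linalg.matrix_power(p, n), n)
        assert ok
        assert np.abs(clip_and_renormalize(values) - p).max() < 1e-8

    def test_permutation_equivariance(self, space4, identity_w0):
        rng = np.random.default_rng(3)
        p = random_reversible_chain(4, 0.6, rng)
        perm = rng.permutation(4)
        pi_mat = np.eye(4)[perm]
        raw = estimate_root(identity_w0(space4), _wn(space4, p, 6))
        raw_p = estimate_root(
            identity_w0(space4), _wn(space4, pi_mat @ p @ pi_mat.T, 6)
        )
        assert np.abs(pi_mat @ raw.values @ pi_mat.T - raw_p.values).max() < 1e-9

    def test_defective_matrix_falls_back_to_optimizer(self, space2, identity_w0):
        # Jordan block scaled into a (non-stochastic) defective matrix
        a = np.array([[0.5, 0.5], [0.0, 0.5]])
        wn = ProportionMatrix.__new__(ProportionMatrix)
        wn.values, wn.t, wn.space, wn.condition = a, 4, space2, None
        raw = estimate_root(identity_w0(space2), wn)
        assert raw.fallback_used
        assert np.isfinite(raw.values).all()


class TestRegularize:
    def test_stochastic_input_is_fixed_point(self, space2):
        v = np.array([[0.9, 0.1], [0.2, 0.8]])
        out = regularize(RawRootMatrix(v, t=1, space=space2))
        assert np.array_equal(out.values, v)

    def test_clip_then_renormalize(self, space4):
        v = np.eye(4)
        v[0] = [0.5, -0.1, 0.7, 0.0]
        out = regularize(RawRootMatrix(v, t=1, space=space4))
        assert np.allclose(out.values[0], [5 / 12, 0, 7 / 12, 0])

    def test_dead_row_becomes_self_transition(self, space2):
        v = np.array([[-0.2, -0.3], [0.1, 0.9]])
        out = regularize(RawRootMatrix(v, t=1, space=space2))
        assert np.array_equal(out.values[0], [1.0, 0.0])

    def test_idempotent(self, space4):
        rng = np.random.default_rng(1)
        v = rng.normal(0.2, 0.5, size=(4, 4))
        once = regularize(RawRootMatrix(v, t=1, space=space4))
        twice = regularize(RawRootMatrix(once.values, t=1, space=space4))
        assert np.array_equal(once.values, twice.values)

    def test_non_finite_rejected(self, space2):
        with pytest.raises(ValueError, match="non-finite"):
            regularize(RawRootMatrix(np.array([[np.nan, 1], [0, 1]]), t=1, space=space2))


class TestAverage:
    def test_single_estimate_is_itself(self, chain2):
        assert np.array_equal(average_estimates([chain2]).values, chain2.values)

    def test_hand_mean(self, space2):
        a = pt.TransitionMatrix(np.eye(2), space=space2)
        b = pt.TransitionMatrix(np.array([[0.8, 0.2], [0.4, 0.6]]), space=space2)
        out = average_estimates([a, b])
        assert np.allclose(out.values, [[0.9, 0.1], [0.2, 0.8]])
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_and_mismatched_rejected(self, chain2, space4):
        with pytest.raises(ValueError):
            average_estimates([])
        other = pt.TransitionMatrix(np.eye(4), space=space4)
        with pytest.raises(ValueError):
            average_estimates([chain2, other])


class TestOptimizer:
    def test_exact_power_reaches_tiny_residual(self, space4):
        rng = np.random.default_rng(2)
        p_true = random_reversible_chain(4, 0.6, rng)
        wn = _wn(space4, p_true, 6)
        fit = fit_root_by_optimization(wn, n=6, seed=0)
        info = fit.provenance[-1][1]
        assert info["residual"] < 1e-6
        assert np.abs(fit.values - p_true).max() < 1e-4

    def test_identity_target(self, space2):
        fit = fit_root_by_optimization(_wn(space2, np.eye(2), 3), n=3, seed=1)
        assert np.abs(fit.values - np.eye(2)).max() < 1e-6

    def test_seeded_determinism_bit_identical(self, space4):
        rng = np.random.default_rng(4)
        wn = _wn(space4, random_reversible_chain(4, 0.6, rng), 5)
        a = fit_root_by_optimization(wn, n=5, seed=42)
        b = fit_root_by_optimization(wn, n=5, seed=42)
        assert np.array_equal(a.values, b.values)


class TestGraph:
    def test_possible_transitions_count(self, space16):
        p = pt.TransitionMatrix(np.full((16, 16), 1 / 16), space=space16)
        g = extract_graph(p, tau=0.0)
        assert g.n_possible == 240
        assert g.n_edges == 240

    def test_identity_has_no_edges(self, space4):
        g = extract_graph(pt.TransitionMatrix(np.eye(4), space=space4), tau=0.0)
        assert g.n_edges == 0

    def test_edges_enumerated_with_weights(self, space4):
        v = np.eye(4) * 0.94
        v[0, 1] = 0.06
        v[1, 2] = 0.04
        v[1, 3] = 0.02
        v[2, 0] = 0.06
        v[3, 0] = 0.06
        p = pt.TransitionMatrix(v, space=space4)
        g = extract_graph(p, tau=0.05)
        assert sorted(g.edges()) == [("P1", "P2", 0.06), ("P3", "P1", 0.06),
                                     ("P4", "P1", 0.06)]

    def test_negative_tau_rejected(self, chain2):
        with pytest.raises(ValueError):
            extract_graph(chain2, tau=-0.1)
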