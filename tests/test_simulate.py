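import numpy as np
import pytest

import phenotrans as pt
from phenotrans.io import build_proportion_matrix
from phenotrans.simulate import (
    gated_marker_chain,
    generate_ground_truth,
    random_reversible_chain,
    recovery_benchmark,
    simulate_experiment,
)


class TestGroundTruth:
    def test_same_seed_identical_model(self):
        a = generate_ground_truth(k=8, seed=5)
        b = generate_ground_truth(k=8, seed=5)
        assert np.array_equal(a.p_true.values, b.p_true.values)

    def test_reversible_default_has_real_positive_spectrum(self):
        model = generate_ground_truth(k=16, seed=1)
        ev = np.linalg.eigvals(model.p_true.values)
        assert np.abs(ev.imag).max() < 1e-10
        assert ev.real.min() > 0

    def test_kronecker_structure_reconstructs(self):
        model = generate_ground_truth(
            structure="kronecker-independent", markers=["A", "B"], seed=2
        )
        prod = np.kron(model.factors[0], model.factors[1])
        assert np.abs(model.p_true.values - prod).max() < 1e-14

    def test_transient_state_has_zero_incoming_mass(self):
        model = generate_ground_truth(k=8, structure="with-transient", seed=3)
        i = model.space.index(model.transient_state)
        col = model.p_true.values[:, i].copy()
        col[i] = 0.0
        assert np.all(col == 0.0)
        assert model.p_true.values[i, i] < 1.0

    def test_tree_structure_only_parent_to_child(self):
        model = generate_ground_truth(k=8, structure="tree-hierarchy", seed=4)
        v = model.p_true.values
        for i in range(8):
            for j in range(8):
                if i != j and v[i, j] > 0:
                    assert model.tree_parents[j] == i

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_ground_truth(k=6, seed=0)  # not a power of two
        with pytest.raises(ValueError):
            generate_ground_truth(k=4, structure="bogus", seed=0)
        with pytest.raises(ValueError):
            generate_ground_truth(k=4, self_mass=1.0, seed=0)
        with pytest.raises(ValueError):
            generate_ground_truth(k=4, doubling_times=[2, 2, 0, 2], seed=0)


class TestSimulate:
    def test_identity_chain_composition_constant(self, space4):
        model = pt.GroundTruthModel(
            p_true=pt.TransitionMatrix(np.eye(4), space=space4),
            structure="irreducible", seed=0, space=space4,
        )
        exp = simulate_experiment(model, days=[3, 9], mode="expected")
        for (start, day), x in exp.compositions.items():
            assert np.array_equal(x, np.eye(4)[space4.index(start)])

    def test_expected_mode_matches_matrix_power_oracle(self):
        model = generate_ground_truth(k=8, seed=6)
        exp = simulate_experiment(model, days=[4, 11], mode="expected")
        for (start, day), x in exp.compositions.items():
            oracle = np.eye(8)[model.space.index(start)] @ np.linalg.matrix_power(
                model.p_true.values, day
            )
            assert np.abs(x - oracle).max() < 1e-12

    def test_expected_mode_with_proliferation_biases_toward_fast_states(self, space2):
        p = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = pt.GroundTruthModel(
            p_true=pt.TransitionMatrix(p, space=space2),
            structure="irreducible", seed=0, space=space2,
            doubling_times=np.array([1.0, 10.0]),  # state 1 divides much faster
        )
        exp = simulate_experiment(model, days=[30], mode="expected")
        x = exp.compositions[("P2", 30)]
        # symmetric chain alone would give 0.5/0.5; selection favors state 1
        assert x[0] > 0.8

    def test_per_cell_within_binomial_bounds_of_expected(self):
        model = generate_ground_truth(k=4, seed=7)
        n = 100_000
        days = [5, 15]
        exp = simulate_experiment(model, days=days, n_cells=n, mode="per-cell", seed=1)
        expd = simulate_experiment(model, days=days, mode="expected")
        for key, counts in exp.compositions.items():
            frac = counts / counts.sum()
            mean = expd.compositions[key]
            # process noise adds to sampling noise; 4 sd of the binomial plus drift slack
            bound = 4 * np.sqrt(mean * (1 - mean) / n) + 4 * key[1] * np.sqrt(1.0 / n)
            assert np.all(np.abs(frac - mean) <= bound)

    def test_per_cell_day0_exact_and_census_conserved(self):
        model = generate_ground_truth(k=4, seed=8)
        exp = simulate_experiment(model, days=[0, 6], n_cells=500, mode="per-cell",
                                  seed=2, n0=500)
        for lab in model.space.labels:
            c0 = exp.compositions[(lab, 0)]
            assert c0.sum() == 500
            assert c0[model.space.index(lab)] == 500  # exactly pure at day 0
            assert exp.compositions[(lab, 6)].sum() == 500  # no proliferation

    def test_per_cell_determinism_and_seed_splitting(self):
        model = generate_ground_truth(k=4, seed=9)
        a = simulate_experiment(model, days=[5], n_cells=1000, mode="per-cell", seed=3)
        b = simulate_experiment(model, days=[5], n_cells=1000, mode="per-cell", seed=3)
        c = simulate_experiment(model, days=[5], n_cells=1000, mode="per-cell", seed=4)
        ka = sorted(a.compositions)
        assert all(np.array_equal(a.compositions[k], b.compositions[k]) for k in ka)
        assert any(not np.array_equal(a.compositions[k], c.compositions[k]) for k in ka)

    def test_emitted_table_round_trips_through_io(self):
        model = generate_ground_truth(k=4, seed=10)
        exp = simulate_experiment(model, days=[5], n_cells=2000, mode="per-cell", seed=0)
        w = build_proportion_matrix(exp.table, model.space, t=5, condition="sim")
        counts = {k: v for k, v in exp.compositions.items() if k[1] == 5}
        for lab, c in counts.items():
            i = model.space.index(lab[0])
            assert np.allclose(w.values[i], c / c.sum())

    def test_admixture_design(self):
        model = generate_ground_truth(k=4, seed=11)
        mixes = {"mixA": np.array([0.5, 0.5, 0.0, 0.0])}
        exp = simulate_experiment(model, days=[2], mode="expected",
                                  design="admixture", admixtures=mixes)
        x = exp.compositions[("mixA", 2)]
        oracle = mixes["mixA"] @ np.linalg.matrix_power(model.p_true.values, 2)
        assert np.abs(x - oracle).max() < 1e-12


class TestRecovery:
    def test_noiseless_recovery_is_exact(self):
        model = generate_ground_truth(k=8, seed=12)
        summ = recovery_benchmark(model, days=[20, 30, 70], mode="expected", seeds=[0])
        assert summ["max_abs_error"] < 1e-6
        assert summ["max_tv_stationary"] < 1e-6

    def test_error_decreases_with_cells(self):
        model = generate_ground_truth(k=4, seed=13)
        errs = [
            recovery_benchmark(model, days=[10, 20], n_cells=n,
                               seeds=[0, 1, 2])["mean_abs_error"]
            for n in (1_000, 10_000, 100_000)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_tree_ground_truth_keeps_hierarchy_through_pipeline(self):
        model = generate_ground_truth(k=8, structure="tree-hierarchy", seed=14)
        exp = simulate_experiment(model, days=[5, 10], mode="expected")
        snaps = [build_proportion_matrix(exp.table, model.space, t=d, condition="sim")
                 for d in (5, 10)]
        p_hat, _ = pt.estimate_transition_matrix(snaps)
        rep = pt.krackhardt_hierarchy(pt.extract_graph(p_hat, tau=1e-9))
        assert rep.score == 1.0

    def test_unequal_doubling_times_bias_grows_with_spread(self):
        # violating the equal-proliferation assumption biases the estimate
        base = generate_ground_truth(k=4, seed=15)

        def with_doublings(dts):
            return pt.GroundTruthModel(
                p_true=base.p_true, structure=base.structure, seed=base.seed,
                space=base.space, doubling_times=np.asarray(dts, float),
            )

        errs = []
        for dts in ([3, 3, 3, 3], [2, 3, 4, 5], [1, 3, 6, 12]):
            summ = recovery_benchmark(with_doublings(dts), days=[10, 20],
                                      mode="expected", seeds=[0])
            errs.append(summ["mean_abs_error"])
        assert errs[0] < 1e-6  # equal rates cancel out of the proportions
        assert errs[0] < errs[1] < errs[2]


def test_gated_marker_chain_is_valid_and_dependent():
    p = gated_marker_chain()
    assert np.allclose(p.values.sum(axis=1), 1.0)
    # A's switching genuinely depends on B: compare conditional loss rates
    space = p.space
    i_pp = space.signs.index((1, 1))
    i_pm = space.signs.index((1, -1))
    loss_when_bplus = p.values[i_pp, space.signs.index((-1, 1))] + \
        p.values[i_pp, space.signs.index((-1, -1))]
    loss_when_bminus = p.values[i_pm, space.signs.index((-1, 1))] + \
        p.values[i_pm, space.signs.index((-1, -1))]
    assert loss_when_bplus > 0.3 and loss_when_bminus == 0.0


def test_random_reversible_chain_detailed_balance():
    rng = np.random.default_rng(16)
    p = random_reversible_chain(8, 0.7, rng)
    w, v = np.linalg.eig(p.T)
    pi = np.abs(v[:, np.argmin(np.abs(w - 1))].real)
    pi /= pi.sum()
    flux = pi[:, None] * p
    assert np.abs(flux - flux.T).max() < 1e-12
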