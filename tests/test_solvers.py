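"""Direct and iterative least-squares solvers and their cost accounting."""

import numpy as np
import pytest
from scipy.sparse.linalg import LinearOperator

import rpgrappa as rg
from rpgrappa.solvers import StepSizeRules

from conftest import random_complex_system


class TestPinv:
    def test_orthonormal_columns_give_adjoint_solution(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(20, 5)) + 1j * rng.normal(size=(20, 5)))
        T = rng.normal(size=(20, 2)) + 1j * rng.normal(size=(20, 2))
        ws = rg.solve_pinv(q, T)
        assert np.allclose(ws.W, q.conj().T @ T, atol=1e-12)

    def test_recovers_planted_solution(self, rng):
        S = rng.normal(size=(40, 6)) + 1j * rng.normal(size=(40, 6))
        W0 = rng.normal(size=(6, 3)) + 1j * rng.normal(size=(6, 3))
        ws = rg.solve_pinv(S, S @ W0)
        assert np.abs(ws.W - W0).max() < 1e-10

    def test_rank_deficient_warns_and_returns_min_norm(self, rng):
        S = rng.normal(size=(30, 4)) + 0j
        S = np.hstack([S, S[:, :1]])          # duplicated column
        T = rng.normal(size=(30, 1)) + 0j
        with pytest.warns(UserWarning, match="rank deficient"):
            ws = rg.solve_pinv(S, T)
        assert ws.rank_deficient

    def test_normal_equations_mode_matches_on_well_conditioned(self, rng):
        S, T = random_complex_system(rng, 60, 8, 2)
        w1 = rg.solve_pinv(S, T, mode="stable").W
        w2 = rg.solve_pinv(S, T, mode="normal_equations").W
        assert np.allclose(w1, w2, atol=1e-10)


class TestCGLS:
    def test_identity_system_solved_in_one_iteration(self):
        S = np.eye(5, dtype=complex)
        b = np.arange(1.0, 6.0) + 0j
        ws = rg.solve_cgls(S, b, rg.SolverConfig(max_iter=1))
        assert np.allclose(ws.W, b, atol=1e-12)

    def test_finite_termination_matches_pinv_oracle(self, rng):
        """On a well-conditioned 60x8 system CGLS reaches the least-squares
        solution within n=8 iterations (Krylov finite termination)."""
        S, T = random_complex_system(rng, 60, 8, 4)
        wp = rg.solve_pinv(S, T).W
        wc = rg.solve_cgls(S, T, rg.SolverConfig(max_iter=8)).W
        assert np.abs(wc - wp).max() < 1e-8 * np.abs(wp).max()

    def test_residual_monotone_nonincreasing(self, rng):
        """Krylov optimality: the residual never increases, 50 random systems."""
        for _ in range(50):
            m, n = sorted(rng.integers(5, 40, size=2))[::-1]
            S, T = random_complex_system(rng, max(m, n + 1), n, 2)
            ws = rg.solve_cgls(S, T, rg.SolverConfig(max_iter=15))
            for hist in ws.residual_history:
                h = np.array(hist)
                assert np.all(np.diff(h) <= 1e-10 * h[0] + 1e-14)

    def test_block_equals_column_mode(self, rng):
        S, T = random_complex_system(rng, 50, 7, 5)
        cfg = rg.SolverConfig(max_iter=12)
        wb = rg.solve_cgls(S, T, cfg, mode="block").W
        wc = rg.solve_cgls(S, T, cfg, mode="column").W
        assert np.abs(wb - wc).max() < 1e-10

    def test_pinv_block_equals_column(self, rng):
        S, T = random_complex_system(rng, 50, 7, 5)
        wb = rg.solve_pinv(S, T).W
        wc = np.column_stack([rg.solve_pinv(S, T[:, j]).W for j in range(5)])
        assert np.abs(wb - wc).max() < 1e-12 * np.abs(wb).max()

    def test_tolerance_stopping(self, rng):
        # consistent system: the relative residual can actually reach tol
        S = rng.normal(size=(60, 8)) + 1j * rng.normal(size=(60, 8))
        T = S @ (rng.normal(size=(8, 1)) + 1j * rng.normal(size=(8, 1)))
        ws = rg.solve_cgls(S, T, rg.SolverConfig(max_iter=100, tol=1e-6))
        assert ws.iterations_used < 100

    def test_operator_interface_never_materializes_normal_matrix(self, rng):
        """The solver works through matvec handles alone; the counter proves
        exactly two products per iteration and no access to the array."""
        S, T = random_complex_system(rng, 40, 6, 1)
        calls = {"mv": 0, "rmv": 0}

        def mv(v):
            calls["mv"] += 1
            return S @ v

        def rmv(v):
            calls["rmv"] += 1
            return S.conj().T @ v

        op = LinearOperator(S.shape, matvec=mv, rmatvec=rmv, dtype=complex)
        it = 10
        ws = rg.solve_cgls(S=op, T=T, cfg=rg.SolverConfig(max_iter=it), mode="column")
        wp = rg.solve_pinv(S, T).W
        assert np.abs(ws.W - wp).max() < 1e-8
        # one initial residual/gradient pair plus one (Sp, S^H r) pair per iteration
        assert calls["mv"] <= it + 2
        assert calls["rmv"] <= it + 2


class TestHGD:
    def test_one_dimensional_closed_form(self):
        """S=[2], b=[4]: the iteration converges to x = b/S = 2."""
        ws = rg.solve_hgd(np.array([[2.0 + 0j]]), np.array([4.0 + 0j]),
                          rg.SolverConfig(max_iter=5000, tol=1e-8))
        assert abs(ws.W[0] - 2.0) < 1e-6

    def test_stationary_start_returns_immediately(self, rng):
        S, T = random_complex_system(rng, 30, 5, 1)
        x_star = rg.solve_pinv(S, T).W
        ws = rg.solve_hgd(S, T, rg.SolverConfig(max_iter=50), x0=x_star)
        # the gradient at the least-squares solution is ~0: no real steps taken
        assert np.abs(ws.W - x_star).max() < 1e-10

    def test_residual_close_to_pinv_after_500_iterations(self, rng):
        for _ in range(5):
            S, T = random_complex_system(rng, 40, 6, 2)
            ws = rg.solve_hgd(S, T, rg.SolverConfig(max_iter=500))
            rp = np.linalg.norm(T - S @ rg.solve_pinv(S, T).W, axis=0)
            rh = np.array([h[-1] for h in ws.residual_history])
            assert np.all(rh - rp < 1e-4 * np.linalg.norm(T, axis=0))

    def test_two_matvecs_per_iteration(self, rng):
        S, T = random_complex_system(rng, 30, 5, 1)
        calls = {"mv": 0, "rmv": 0}

        def mv(v):
            calls["mv"] += 1
            return S @ v

        def rmv(v):
            calls["rmv"] += 1
            return S.conj().T @ v

        op = LinearOperator(S.shape, matvec=mv, rmatvec=rmv, dtype=complex)
        it = 25
        rg.solve_hgd(op, T, rg.SolverConfig(max_iter=it))
        assert calls["mv"] <= it + 1    # initial residual + one per iteration
        assert calls["rmv"] <= it + 1   # gradient-scale probe + one per iteration

    def test_divergence_aborts_with_diagnostic(self, rng):
        S, T = random_complex_system(rng, 20, 4, 1)
        with pytest.raises(rg.NumericalFailure, match="column 0"):
            rg.solve_hgd(S, T, rg.SolverConfig(max_iter=500, mu0=1e9,
                                               eta_mode="literal"))

    def test_eta_modes_differ(self, rng):
        # literal mode needs a small mu to be stable (eta = mu * ||e||)
        S, T = random_complex_system(rng, 30, 4, 1)
        cfg_n = rg.SolverConfig(max_iter=10, mu0=1e-4)
        cfg_l = rg.SolverConfig(max_iter=10, mu0=1e-4, eta_mode="literal")
        wa = rg.solve_hgd(S, T, cfg_n).W
        wb = rg.solve_hgd(S, T, cfg_l).W
        assert not np.allclose(wa, wb)


class TestStepSizeRules:
    def test_four_consecutive_decreases_fire_increase_once(self):
        rules = StepSizeRules()
        factors = [rules.update(True) for _ in range(4)]
        assert factors == [1.0, 1.0, 1.0, 1.1]
        # counters reset: four more decreases needed before the next bump
        factors = [rules.update(True) for _ in range(4)]
        assert factors == [1.0, 1.0, 1.0, 1.1]

    def test_two_increase_decrease_combinations_fire_decrease(self):
        rules = StepSizeRules()
        factors = [rules.update(v) for v in (False, True, False, True)]
        assert factors == [1.0, 1.0, 1.0, 0.9]

    def test_mixed_history_no_spurious_fires(self):
        rules = StepSizeRules()
        seq = [True, True, False, True, True, False, False, True]
        factors = [rules.update(v) for v in seq]
        assert all(f == 1.0 for f in factors)

    def test_rules_drive_mu_inside_solver(self, rng):
        """After a run, the recorded residual pattern implies at least one
        rule firing; mu adaptation is exercised end to end."""
        S, T = random_complex_system(rng, 30, 4, 1)
        ws = rg.solve_hgd(S, T, rg.SolverConfig(max_iter=60))
        hist = np.array(ws.residual_history[0])
        decreases = np.diff(hist) < 0
        assert decreases.any() and (~decreases).any()


class TestCostAccounting:
    @pytest.mark.parametrize("solver", ["cgls", "hgd"])
    def test_flop_scale(self, solver):
        rep = rg.operations_per_iteration(solver, k=500, n=200)
        assert rep["complex_multiplies_per_iteration"] == 200_000
        assert rep["working_storage_vectors"] == {"n_vectors": 2, "k_vectors": 2}

    def test_halving_k_halves_count(self):
        full = rg.operations_per_iteration("cgls", 500, 200)
        half = rg.operations_per_iteration("cgls", 250, 200)
        assert half["complex_multiplies_per_iteration"] * 2 == \
            full["complex_multiplies_per_iteration"]
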