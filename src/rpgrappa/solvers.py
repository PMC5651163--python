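"""Least-squares solvers for the GRAPPA calibration system.

Three routes to ``W = argmin ||S W - T||_F`` are provided:

``solve_pinv``
    Direct solution.  The default mode uses a numerically stable
    least-squares factorization (SVD-backed ``lstsq``); an optional
    ``normal_equations`` mode forms ``(S^H S)^{-1} S^H T`` literally, which
    reproduces the classic ill-conditioning pathology — the normal matrix
    squares the condition number, ``κ(S^H S) = κ(S)²``.

``solve_cgls``
    Conjugate gradient for least squares.  Works on ``S`` and ``S^H`` only
    through matrix-vector products (two per iteration), never forming
    ``S^H S``; the i-th iterate minimizes ``||S x - b||`` over the growing
    Krylov subspace, so the residual is nonincreasing and — in exact
    arithmetic — the solver terminates in at most ``n`` steps.

``solve_hgd``
    Heuristic-rule gradient descent: steepest descent on the least-squares
    objective with a step of length ``mu`` along the normalized gradient
    (``eta = mu / ||e||``), where ``mu`` is adapted by two counters —
    increased by 1.1× after four consecutive residual decreases and
    decreased by 0.9× after two consecutive increase/decrease alternations.

Both iterative solvers accept plain arrays or anything convertible to a
``scipy.sparse.linalg.LinearOperator``; internally they only ever call
``v -> S v`` and ``v -> S^H v`` (asserted by the test suite), which is what
makes the ``O(k n)`` per-iteration cost of the sketched system real.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.sparse.linalg import LinearOperator, aslinearoperator

from .exceptions import NumericalFailure, ParameterError

__all__ = [
    "WeightSet",
    "SolverConfig",
    "StepSizeRules",
    "solve_pinv",
    "solve_cgls",
    "solve_hgd",
    "operations_per_iteration",
]


@dataclass
class WeightSet:
    """Estimated GRAPPA reconstruction coefficients with solver diagnostics."""

    W: np.ndarray                       # (n, l) complex
    solver: str                         # 'pinv' | 'cgls' | 'hgd'
    iterations_used: int = 0
    residual_history: list = field(default_factory=list)  # per column, ||b - S x||
    rank_deficient: bool = False


@dataclass
class SolverConfig:
    """Iterative-solver settings.

    ``tol`` is a relative-residual stopping tolerance (0 disables it; the
    default stopping rule is the fixed iteration budget ``max_iter``).  The
    step-size adaptation factors are part of the method definition and
    should normally be left at 1.1 / 0.9.
    """

    max_iter: int = 30
    tol: float = 0.0
    mu0: float = 0.1
    increase_factor: float = 1.1
    decrease_factor: float = 0.9
    eta_mode: str = "normalized"   # 'normalized': eta = mu/||e||; 'literal': mu*||e||

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ParameterError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.mu0 <= 0:
            raise ParameterError(f"mu0 must be positive, got {self.mu0}")
        if self.eta_mode not in ("normalized", "literal"):
            raise ParameterError(f"unknown eta_mode {self.eta_mode!r}")


def _as_operator(S) -> tuple:
    """Return (matvec, rmatvec, shape) from an array or LinearOperator."""
    if isinstance(S, np.ndarray):
        op = aslinearoperator(S)
    elif isinstance(S, LinearOperator):
        op = S
    else:
        op = aslinearoperator(S)
    return op.matvec, op.rmatvec, op.shape


# ---------------------------------------------------------------------------
# Direct solution
# ---------------------------------------------------------------------------

def solve_pinv(S: np.ndarray, T: np.ndarray, mode: str = "stable") -> WeightSet:
    """Least-squares solution of ``S W = T``.

    ``mode='stable'`` (default) uses an SVD-based least-squares solve and
    returns the minimum-norm solution with a warning when ``S`` is rank
    deficient.  ``mode='normal_equations'`` forms and inverts ``S^H S``
    literally — numerically fragile by design, provided to expose the
    condition-number-squaring pathology of the direct method.
    """
    T = np.atleast_2d(np.asarray(T))
    squeeze = False
    if T.shape[0] != S.shape[0] and T.T.shape[0] == S.shape[0]:
        T, squeeze = T.T, True
    if mode == "normal_equations":
        G = S.conj().T @ S
        W = np.linalg.solve(G, S.conj().T @ T)
        rank_deficient = False
    elif mode == "stable":
        W, _, rank, _ = np.linalg.lstsq(S, T, rcond=None)
        rank_deficient = rank < S.shape[1]
        if rank_deficient:
            warnings.warn(
                f"source matrix is rank deficient (rank {rank} < {S.shape[1]}); "
                "returning the minimum-norm least-squares solution", stacklevel=2)
    else:
        raise ParameterError(f"unknown pinv mode {mode!r}")
    residual = [float(np.linalg.norm(T - S @ W))]
    if squeeze:
        W = W.ravel()
    return WeightSet(W=W, solver="pinv", iterations_used=1,
                     residual_history=[residual], rank_deficient=rank_deficient)


# ---------------------------------------------------------------------------
# CGLS
# ---------------------------------------------------------------------------

def _cgls_column(matvec, rmatvec, b, n, max_iter, tol, x0=None):
    x = np.zeros(n, dtype=complex) if x0 is None \
        else np.asarray(x0, dtype=complex).copy()
    r = b - matvec(x)
    s = rmatvec(r)
    p = s.copy()
    gamma = np.vdot(s, s).real
    b_norm = np.linalg.norm(b)
    history = [float(np.linalg.norm(r))]
    iters = 0
    for _ in range(max_iter):
        if gamma == 0.0:
            break
        q = matvec(p)
        qq = np.vdot(q, q).real
        if qq == 0.0:
            break
        alpha = gamma / qq
        x += alpha * p
        r -= alpha * q
        iters += 1
        res = float(np.linalg.norm(r))
        history.append(res)
        if not np.isfinite(res):
            raise NumericalFailure("CGLS produced non-finite residual")
        if tol > 0 and b_norm > 0 and res / b_norm <= tol:
            break
        s = rmatvec(r)
        gamma_new = np.vdot(s, s).real
        beta = gamma_new / gamma
        p = s + beta * p
        gamma = gamma_new
    return x, history, iters


def solve_cgls(S, T, cfg: SolverConfig | None = None, mode: str = "block") -> WeightSet:
    """CGLS on each target column of ``T`` (vectorized block or per-column loop).

    Starts from ``x0 = 0``; runs ``cfg.max_iter`` iterations or stops early
    at relative residual ``cfg.tol`` (disabled by default).  ``S`` may be an
    ndarray or a LinearOperator; only ``S v`` / ``S^H v`` products are used.
    The block and column modes perform identical per-column arithmetic.
    """
    cfg = cfg or SolverConfig()
    matvec, rmatvec, (mdim, ndim) = _as_operator(S)
    T2 = np.atleast_2d(np.asarray(T, dtype=complex))
    squeeze = T2.shape != np.shape(T)
    if squeeze:
        T2 = T2.T
    l = T2.shape[1]
    W = np.zeros((ndim, l), dtype=complex)
    histories: list = []
    iters_max = 0
    if mode == "column":
        for j in range(l):
            try:
                xj, hist, it = _cgls_column(matvec, rmatvec, T2[:, j], ndim,
                                            cfg.max_iter, cfg.tol)
            except NumericalFailure as exc:
                raise NumericalFailure(f"CGLS failed on target column {j}: {exc}") from exc
            W[:, j] = xj
            histories.append(hist)
            iters_max = max(iters_max, it)
    elif mode == "block":
        # identical recurrences, all columns advanced together with
        # per-column scalars; columns hitting tol are frozen
        X = np.zeros((ndim, l), dtype=complex)
        mv = lambda M: np.stack([matvec(M[:, j]) for j in range(M.shape[1])], axis=1)
        rmv = lambda M: np.stack([rmatvec(M[:, j]) for j in range(M.shape[1])], axis=1)
        if isinstance(S, np.ndarray):
            mv = lambda M: S @ M
            rmv = lambda M: S.conj().T @ M
        R = T2 - mv(X)
        Sg = rmv(R)
        P = Sg.copy()
        gamma = np.einsum("ij,ij->j", Sg.conj(), Sg).real
        b_norm = np.linalg.norm(T2, axis=0)
        hist = [np.linalg.norm(R, axis=0)]
        active = np.ones(l, dtype=bool)
        for it in range(cfg.max_iter):
            if not active.any():
                break
            Q = mv(P)
            qq = np.einsum("ij,ij->j", Q.conj(), Q).real
            upd = active & (gamma > 0) & (qq > 0)
            if not upd.any():
                break
            alpha = np.zeros(l)
            alpha[upd] = gamma[upd] / qq[upd]
            X += alpha * P
            R -= alpha * Q
            iters_max = it + 1
            res = np.linalg.norm(R, axis=0)
            hist.append(res)
            if not np.all(np.isfinite(res[upd])):
                bad = int(np.flatnonzero(~np.isfinite(res))[0])
                raise NumericalFailure(f"CGLS failed on target column {bad}: "
                                       "non-finite residual")
            if cfg.tol > 0:
                active &= ~((b_norm > 0) & (res / np.maximum(b_norm, 1e-300) <= cfg.tol))
            Sg = rmv(R)
            gamma_new = np.einsum("ij,ij->j", Sg.conj(), Sg).real
            beta = np.zeros(l)
            beta[upd] = gamma_new[upd] / gamma[upd]
            P = Sg + beta * P
            gamma = gamma_new
        W = X
        H = np.stack(hist, axis=0)  # (iters+1, l)
        histories = [list(H[:, j]) for j in range(l)]
    else:
        raise ParameterError(f"unknown CGLS mode {mode!r}")
    if squeeze:
        W = W.ravel()
    return WeightSet(W=W, solver="cgls", iterations_used=iters_max,
                     residual_history=histories)


# ---------------------------------------------------------------------------
# HGD
# ---------------------------------------------------------------------------

class StepSizeRules:
    """The two heuristic step-size rules, isolated for unit testing.

    ``update(decreased)`` feeds one residual comparison (True if the
    residual decreased) and returns the factor applied to ``mu`` this step
    (1.0 when no rule fires).  Rule (i): four consecutive decreases →
    ×increase_factor.  Rule (ii): two consecutive (increase, decrease)
    combinations — the pattern up, down, up, down — ×decrease_factor.
    Counters reset after each adjustment.
    """

    def __init__(self, increase_factor: float = 1.1, decrease_factor: float = 0.9):
        self.increase_factor = increase_factor
        self.decrease_factor = decrease_factor
        self._signs: list[bool] = []

    def update(self, decreased: bool) -> float:
        self._signs.append(bool(decreased))
        tail = self._signs[-4:]
        if len(tail) == 4 and all(tail):
            self._signs.clear()
            return self.increase_factor
        if len(tail) == 4 and tail == [False, True, False, True]:
            self._signs.clear()
            return self.decrease_factor
        return 1.0


def _hgd_column(matvec, rmatvec, b, n, cfg: SolverConfig, x0=None):
    x = np.zeros(n, dtype=complex) if x0 is None else np.asarray(x0, dtype=complex).copy()
    mu = cfg.mu0
    rules = StepSizeRules(cfg.increase_factor, cfg.decrease_factor)
    r = b - matvec(x)
    res = float(np.linalg.norm(r))
    history = [res]
    res0 = res if res > 0 else 1.0
    iters = 0
    b_norm = np.linalg.norm(b)
    grad_scale = float(np.linalg.norm(rmatvec(b)))  # gradient magnitude at x = 0
    for _ in range(cfg.max_iter):
        e = -rmatvec(r)                     # gradient of 1/2 ||b - S x||^2
        e_norm = float(np.linalg.norm(e))
        if e_norm <= 1e-12 * grad_scale:    # stationary: already optimal
            break
        eta = mu / e_norm if cfg.eta_mode == "normalized" else mu * e_norm
        x = x - eta * e
        r = b - matvec(x)
        res = float(np.linalg.norm(r))
        iters += 1
        if not np.isfinite(res) or res > 1e6 * res0:
            raise NumericalFailure(
                f"HGD diverged: residual {res:.3e} vs initial {res0:.3e}")
        mu *= rules.update(res < history[-1])
        history.append(res)
        if cfg.tol > 0 and b_norm > 0 and res / b_norm <= cfg.tol:
            break
    return x, history, iters


def solve_hgd(S, T, cfg: SolverConfig | None = None, x0=None) -> WeightSet:
    """Heuristic-rule gradient descent on each target column.

    Each iteration costs exactly two matrix-vector products (``S x`` and
    ``S^H r``).  The residual after every update is recorded and drives the
    step-size rules; see :class:`StepSizeRules`.
    """
    cfg = cfg or SolverConfig()
    matvec, rmatvec, (_, n) = _as_operator(S)
    T2 = np.atleast_2d(np.asarray(T, dtype=complex))
    squeeze = T2.shape != np.shape(T)
    if squeeze:
        T2 = T2.T
    l = T2.shape[1]
    W = np.zeros((n, l), dtype=complex)
    histories = []
    iters_max = 0
    X0 = None
    if x0 is not None:
        X0 = np.atleast_2d(np.asarray(x0, dtype=complex))
        if X0.shape != (n, l):
            X0 = X0.reshape(n, l)
    for j in range(l):
        try:
            xj, hist, it = _hgd_column(matvec, rmatvec, T2[:, j], n, cfg,
                                       None if X0 is None else X0[:, j])
        except NumericalFailure as exc:
            raise NumericalFailure(f"HGD failed on target column {j}: {exc}") from exc
        W[:, j] = xj
        histories.append(hist)
        iters_max = max(iters_max, it)
    if squeeze:
        W = W.ravel()
    return WeightSet(W=W, solver="hgd", iterations_used=iters_max,
                     residual_history=histories)


# ---------------------------------------------------------------------------
# Complexity accounting
# ---------------------------------------------------------------------------

def operations_per_iteration(solver: str, k: int, n: int) -> dict:
    """Per-iteration cost of an iterative solver on a ``k × n`` system.

    Both CGLS and HGD perform two complex matrix-vector products per
    iteration (``S p``/``S x`` and ``S^H r``), i.e. ``2 k n`` complex
    multiplies, with working storage of two n-vectors and two k-vectors.
    """
    if solver not in ("cgls", "hgd"):
        raise ParameterError(f"operations_per_iteration: unknown solver {solver!r}")
    return {
        "solver": solver,
        "k": k,
        "n": n,
        "complex_multiplies_per_iteration": 2 * k * n,
        "working_storage_vectors": {"n_vectors": 2, "k_vectors": 2},
        "working_storage_complex_values": 2 * n + 2 * k,
    }
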