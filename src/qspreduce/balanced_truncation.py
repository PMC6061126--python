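"""Balanced truncation of stable linear state-space models.

Pipeline: solve the two continuous Lyapunov equations for the
controllability and observability Gramians P and Q,

    A P + P A' + B B' = 0,        A' Q + Q A + C' C = 0,

factor them (square-root algorithm), balance so both Gramians become
diag(sigma) of Hankel singular values, and truncate to the leading k
balanced states.  The retained transformation columns provide output
recovery (approximate original outputs from the reduced state) and the
discarded tail yields the a-priori H-infinity error bound 2 * sum_{i>k}
sigma_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import (DoseRegimen, LinearStateSpaceModel, Trajectory,
                   is_asymptotically_stable, simulate)
from .errors import ConfigurationError, StabilityError
from .metrics import ErrorReport, maximal_relative_error

__all__ = [
    "GramianPair",
    "BalancingResult",
    "ReducedLinearModel",
    "gramians",
    "balance",
    "truncate",
    "reduce_linear",
]

#: Relative residual tolerance for the Lyapunov solutions.
LYAPUNOV_RTOL = 1e-8


@dataclass
class GramianPair:
    """Controllability (P) and observability (Q) Gramians of a stable system."""

    P: np.ndarray
    Q: np.ndarray

    def residuals(self, model: LinearStateSpaceModel) -> tuple[float, float]:
        A, B, C = model.A, model.B, model.C
        rp = np.linalg.norm(A @ self.P + self.P @ A.T + B @ B.T)
        rq = np.linalg.norm(A.T @ self.Q + self.Q @ A + C.T @ C)
        return rp, rq


@dataclass
class BalancingResult:
    """Balancing transformation and Hankel singular values.

    In balanced coordinates z = T_inv x both Gramians equal
    diag(hankel_singular_values).
    """

    hankel_singular_values: np.ndarray
    T: np.ndarray        # x = T z
    T_inv: np.ndarray    # z = T_inv x
    A: np.ndarray        # balanced realisation
    B: np.ndarray
    C: np.ndarray
    model: LinearStateSpaceModel


@dataclass
class ReducedLinearModel:
    """Order-k balanced-truncation reduction with output recovery.

    ``model`` simulates the reduced dynamics directly (its C is the
    reduced output map, so its outputs are the approximations ybar of the
    original outputs); ``state_recovery`` (n x k, the retained columns of
    T) lifts reduced states back to approximate original states.
    """

    model: LinearStateSpaceModel
    state_recovery: np.ndarray
    error_bound: float
    hankel_singular_values: np.ndarray
    order: int

    def recover_states(self, reduced_states: np.ndarray) -> np.ndarray:
        """Approximate original states from reduced ones (rows = time points)."""
        return reduced_states @ self.state_recovery.T


def _sym_factor(M: np.ndarray, name: str) -> np.ndarray:
    """Factor a PSD matrix as M = F F'.

    Cholesky when positive definite; falls back to a symmetric eigenvalue
    square root for matrices semidefinite to machine precision.
    """
    M = 0.5 * (M + M.T)
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        tol = np.max(np.abs(w)) * 1e-13 if len(w) else 0.0
        if np.any(w < -max(tol, 1e-300)):
            warnings.warn(f"{name} has negative eigenvalue {w.min():.3g}; clipped",
                          stacklevel=3)
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)


def gramians(model: LinearStateSpaceModel) -> GramianPair:
    """Solve the Lyapunov equations for the Gramian pair of a Hurwitz system.

    Raises
    ------
    StabilityError
        If A is not Hurwitz; the offending eigenvalues are attached.
    """
    if not is_asymptotically_stable(model):
        eig = np.linalg.eigvals(model.A)
        bad = eig[eig.real >= -1e-9]
        raise StabilityError(
            f"A is not Hurwitz; eigenvalues with non-negative real part: {bad}",
            eigenvalues=bad)
    A, B, C = model.A, model.B, model.C
    P = linalg.solve_continuous_lyapunov(A, -B @ B.T)
    Q = linalg.solve_continuous_lyapunov(A.T, -C.T @ C)
    P = 0.5 * (P + P.T)
    Q = 0.5 * (Q + Q.T)
    pair = GramianPair(P=P, Q=Q)
    rp, rq = pair.residuals(model)
    if rp > LYAPUNOV_RTOL * max(np.linalg.norm(B @ B.T), 1e-300) * 10:
        warnings.warn(f"controllability Lyapunov residual {rp:.3g} is large",
                      stacklevel=2)
    if rq > LYAPUNOV_RTOL * max(np.linalg.norm(C.T @ C), 1e-300) * 10:
        warnings.warn(f"observability Lyapunov residual {rq:.3g} is large",
                      stacklevel=2)
    return pair


def balance(model: LinearStateSpaceModel,
            gram: GramianPair | None = None) -> BalancingResult:
    """Square-root balancing: equalise and diagonalise the Gramians.

    Factor P = U U', Q = L L'; SVD of L' U = Z Sigma Y' gives the Hankel
    singular values sigma = diag(Sigma) and the transformation
    T = U Y Sigma^{-1/2}, T_inv = Sigma^{-1/2} Z' L'.  States beyond the
    numerical rank of L' U cannot be balanced; they are dropped from the
    transformation with a warning (reduced effective order).
    """
    if gram is None:
        gram = gramians(model)
    U = _sym_factor(gram.P, "controllability Gramian")
    L = _sym_factor(gram.Q, "observability Gramian")
    Z, s, Yt = np.linalg.svd(L.T @ U)
    n = model.n_states
    rank = int(np.sum(s > max(s[0], 1e-300) * 1e-13)) if len(s) else 0
    if rank < n:
        warnings.warn(
            f"Gramian product numerically rank deficient: effective order "
            f"{rank} < {n}; balancing restricted to the leading {rank} states",
            stacklevel=2)
    s_r = s[:rank]
    sqrt_inv = 1.0 / np.sqrt(s_r)
    T = U @ Yt[:rank].T * sqrt_inv            # n x rank
    T_inv = (Z[:, :rank] * sqrt_inv).T @ L.T  # rank x n
    Ab = T_inv @ model.A @ T
    Bb = T_inv @ model.B
    Cb = model.C @ T
    return BalancingResult(hankel_singular_values=s_r, T=T, T_inv=T_inv,
                           A=Ab, B=Bb, C=Cb, model=model)


def truncate(balancing: BalancingResult, k: int) -> ReducedLinearModel:
    """Keep the leading k balanced states.

    The a-priori bound on the H-infinity transfer-function error is
    2 * sum_{i>k} sigma_i.  Truncating inside a cluster of (numerically)
    equal singular values is refused with a warning: the cut is moved past
    the cluster, since the split between equal-sigma states is arbitrary.
    The reduced initial state is T_inv[:k] @ x0 (exact when x0 = 0).
    """
    s = balancing.hankel_singular_values
    n_eff = len(s)
    if not 1 <= k <= n_eff:
        raise ConfigurationError(
            f"reduction order k={k} outside [1, {n_eff}]")
    if k < n_eff and np.isclose(s[k - 1], s[k], rtol=1e-9, atol=0.0):
        k_new = k
        while k_new < n_eff and np.isclose(s[k - 1], s[k_new], rtol=1e-9, atol=0.0):
            k_new += 1
        warnings.warn(
            f"sigma_{k} == sigma_{k + 1}: truncation inside an equal-sigma "
            f"cluster is ill-defined; truncating after the cluster at k={k_new}",
            stacklevel=2)
        k = k_new

    orig = balancing.model
    x0r = balancing.T_inv[:k] @ orig.initial_state
    reduced = LinearStateSpaceModel(
        A=balancing.A[:k, :k], B=balancing.B[:k], C=balancing.C[:, :k],
        state_names=[f"bt_{i + 1}" for i in range(k)],
        input_names=list(orig.input_names),
        output_names=list(orig.output_names),
        initial_state=x0r,
    )
    bound = 2.0 * float(np.sum(s[k:]))
    return ReducedLinearModel(model=reduced, state_recovery=balancing.T[:, :k],
                              error_bound=bound, hankel_singular_values=s,
                              order=k)


def reduce_linear(model: LinearStateSpaceModel, k: int,
                  doses: DoseRegimen | None = None,
                  time_grid: np.ndarray | None = None,
                  ) -> tuple[ReducedLinearModel, ErrorReport]:
    """Gramians -> balance -> truncate -> simulate both -> error report."""
    bal = balance(model)
    red = truncate(bal, k)
    ref = simulate(model, doses, time_grid)
    approx = simulate(red.model, doses, time_grid)
    report = maximal_relative_error(ref, approx)
    return red, report
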