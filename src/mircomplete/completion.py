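"""Truncated Schatten p-norm matrix completion of the heterogeneous network.

The target matrix stacks the fused miRNA similarity MM, the binary
association block A and the fused disease similarity DD::

    H = [[MM,  A ],
         [A^T, DD]]

Observed entries (the set Omega) are every entry of the two similarity
blocks plus the known 1-entries of the association blocks; association
zeros are unverified candidates, not observations.  The completed matrix X
minimizes the truncated Schatten p-norm  sum_{i>r} sigma_i(X)^p  subject to
a quadratic data-fit penalty on Omega and the box constraint X in [0, 1].

The non-convex norm is handled by a two-level scheme: an outer loop fixes
the truncation factors (A, B) = (U_r^T, V_r^T) from the current SVD and
linearizes the Schatten term into a weighted nuclear norm with weights

    w_i = p * (1 - sigma_i(B^T A)) * sigma_i(X)^(p-1),

which are ~0 for the r retained singular values and positive for the tail;
an inner ADMM then alternates a box-constrained data-fit update (T), a
weighted singular-value thresholding update (X) and a dual ascent step (E).
With r = 0, p = 1 every weight is 1 and the scheme reduces exactly to
nuclear-norm ADMM with box constraints.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.linalg import svd as _svd, svdvals

from .io import AssociationMatrix, LabeledMatrix, Role

logger = logging.getLogger(__name__)

__all__ = [
    "HeterogeneousSystem",
    "SolverConfig",
    "SolverState",
    "CompletionResult",
    "DivergenceError",
    "build_target_matrix",
    "project",
    "truncation_factors",
    "compute_weights",
    "weighted_svt",
    "update_T",
    "update_X",
    "update_E",
    "admm_inner",
    "solve",
    "extract_association_scores",
]


class DivergenceError(RuntimeError):
    """The ADMM iteration produced non-finite values."""


@dataclass
class HeterogeneousSystem:
    """Target matrix H, boolean observation mask and block layout."""

    H: np.ndarray
    mask: np.ndarray  # boolean, True on Omega
    block_layout: tuple[int, int]  # (nm, nd)
    mirna_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.block_layout[0] + self.block_layout[1]
        if self.H.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("H/mask shape inconsistent with block layout")


@dataclass
class SolverConfig:
    """Solver hyperparameters.

    alpha
        Equilibrium coefficient weighting the data-fit term on Omega.
    beta
        ADMM penalty parameter; 1/beta is the singular-value threshold.
    p
        Schatten exponent in (0, 1]; p = 1 gives the truncated nuclear norm.
    r
        Truncation rank: number of leading singular values exempt from
        shrinkage.
    outer_iters / reweight_iters
        Outer truncation-factor updates (default 4) and weight refreshes per
        outer step (default 1).
    eps1, eps2
        Inner stopping tolerances on the relative change of X and on the
        change of that statistic.
    sigma_floor
        Lower clamp on singular values inside the weight formula; keeps the
        p < 1 weights finite at zero singular values.
    """

    alpha: float = 20.0
    beta: float = 5.0
    p: float = 1.0
    r: int = 5
    outer_iters: int = 4
    reweight_iters: int = 1
    eps1: float = 2e-3
    eps2: float = 1e-5
    max_inner: int = 200
    sigma_floor: float = 1e-10

    def validate(self, n: int | None = None) -> "SolverConfig":
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.r < 0 or (n is not None and self.r >= n):
            raise ValueError(f"truncation rank r={self.r} out of range")
        return self


@dataclass
class SolverState:
    """Iterates and convergence statistics of the inner ADMM."""

    X: np.ndarray
    T: np.ndarray
    E: np.ndarray
    weights: np.ndarray | None = None
    rel_change: float = np.inf          # ||X_{k+1}-X_k||_F / ||X_k||_F
    rel_change_delta: float = np.inf    # |S1_{k+1}-S1_k| / max(|S1_k|, 1)
    inner_iter: int = 0
    outer_iter: int = 0
    converged: bool = False
    trace: list[float] = field(default_factory=list)


@dataclass
class CompletionResult:
    """Completed matrix split back into its blocks."""

    H_star: np.ndarray
    A_star: LabeledMatrix
    MM_star: np.ndarray
    DD_star: np.ndarray
    converged: bool
    iterations: list[int]  # inner iterations per outer step
    trace: list[float]


# ---------------------------------------------------------------------------
# system construction


def build_target_matrix(
    MM: LabeledMatrix, A: AssociationMatrix, DD: LabeledMatrix
) -> HeterogeneousSystem:
    """Assemble H = [[MM, A], [A^T, DD]] and its observation mask.

    Omega covers both similarity blocks entirely and only the 1-entries of
    the association blocks (zeros are unobserved candidate pairs).
    """
    if MM.row_ids != A.mirna_ids or DD.row_ids != A.disease_ids:
        raise ValueError("similarity and association labels are inconsistent")
    nm, nd = A.shape
    n = nm + nd
    H = np.zeros((n, n))
    H[:nm, :nm] = MM.values
    H[nm:, nm:] = DD.values
    H[:nm, nm:] = A.values
    H[nm:, :nm] = A.values.T
    mask = np.zeros((n, n), dtype=bool)
    mask[:nm, :nm] = True
    mask[nm:, nm:] = True
    ones = A.values == 1.0
    mask[:nm, nm:] = ones
    mask[nm:, :nm] = ones.T
    return HeterogeneousSystem(H, mask, (nm, nd), list(A.mirna_ids), list(A.disease_ids))


def project(M: np.ndarray, omega: np.ndarray | Iterable[tuple[int, int]]) -> np.ndarray:
    """P_Omega: keep entries on the observation set, zero elsewhere."""
    if isinstance(omega, np.ndarray) and omega.dtype == bool:
        if omega.shape != M.shape:
            raise ValueError("mask shape does not match matrix")
        return np.where(omega, M, 0.0)
    out = np.zeros_like(M)
    for i, j in omega:
        if not (0 <= i < M.shape[0] and 0 <= j < M.shape[1]):
            raise IndexError(f"index ({i}, {j}) out of range for shape {M.shape}")
        out[i, j] = M[i, j]
    return out


# ---------------------------------------------------------------------------
# truncation factors and weights


def truncation_factors(X: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-r left/right singular vectors, transposed to r x n factors."""
    n = min(X.shape)
    if r > n:
        raise ValueError(f"truncation rank r={r} exceeds matrix rank budget {n}")
    if r == 0:
        return np.zeros((0, X.shape[0])), np.zeros((0, X.shape[1]))
    U, _, Vt = _svd(X, full_matrices=False)
    return U[:, :r].T, Vt[:r, :]


def compute_weights(
    sigma_x: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    p: float,
    sigma_floor: float = 1e-10,
) -> np.ndarray:
    """Linearized Schatten weights w_i = p (1 - sigma_i(B^T A)) sigma_i^(p-1).

    sigma_i(B^T A) is 1 for the r retained indices and 0 beyond, so for
    p = 1 the weights are exactly 0 (head) and 1 (tail).  Negative values
    arising from numerical noise are clamped to 0.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    sigma_x = np.asarray(sigma_x, dtype=float)
    n = sigma_x.size
    if A.shape[0] == 0:
        s_ba = np.zeros(n)
    else:
        s_ba = np.zeros(n)
        vals = svdvals(B.T @ A)
        s_ba[: vals.size] = vals
    floored = np.maximum(sigma_x, sigma_floor)
    w = p * (1.0 - s_ba) * floored ** (p - 1.0)
    return np.maximum(w, 0.0)


# ---------------------------------------------------------------------------
# ADMM updates


def weighted_svt(Q: np.ndarray, W: np.ndarray, tau: float) -> np.ndarray:
    """Weighted singular-value contraction U max(S - tau diag(W), 0) V^T.

    Requires a non-decreasing weight sequence aligned with the descending
    singular values; that ordering is what makes the closed form the exact
    proximal mapping of the weighted nuclear norm.

    A symmetric input is contracted in its eigenbasis (singular values are
    the eigenvalue magnitudes).  This is the same mapping, but where two
    singular values collide at the truncation boundary the SVD basis is
    arbitrary while the eigendecomposition still separates the +/- pair,
    so the output stays exactly symmetric.
    """
    W = np.asarray(W, dtype=float)
    if np.any(np.diff(W) < -1e-12):
        raise ValueError("weight sequence must be non-decreasing")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if tau == 0:
        return Q.copy()
    if Q.shape[0] == Q.shape[1] and np.abs(Q - Q.T).max() <= 1e-11 * max(1.0, np.abs(Q).max()):
        lam, V = np.linalg.eigh(Q)
        order = np.argsort(-np.abs(lam), kind="stable")
        lam, V = lam[order], V[:, order]
        shrunk = np.maximum(np.abs(lam) - tau * W[: lam.size], 0.0) * np.sign(lam)
        return (V * shrunk) @ V.T
    U, s, Vt = _svd(Q, full_matrices=False)
    shrunk = np.maximum(s - tau * W[: s.size], 0.0)
    return (U * shrunk) @ Vt


def update_T(
    X: np.ndarray,
    E: np.ndarray,
    system: HeterogeneousSystem,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Box-constrained data-fit update.

    Solves the quadratic subproblem in closed form via the diagonal
    resolvent of the sampling operator, then clips to [0, 1].
    """
    G = E / beta + (alpha / beta) * project(system.H, system.mask) + X
    T_bar = G - (alpha / (alpha + beta)) * project(G, system.mask)
    return np.clip(T_bar, 0.0, 1.0)


def update_X(T: np.ndarray, E: np.ndarray, W: np.ndarray, beta: float) -> np.ndarray:
    """Low-rank update: weighted SVT of T - E/beta at threshold 1/beta."""
    return weighted_svt(T - E / beta, W, 1.0 / beta)


def update_E(E: np.ndarray, X: np.ndarray, T: np.ndarray, beta: float) -> np.ndarray:
    """Dual ascent on the multiplier of the X = T constraint."""
    return E + beta * (X - T)


def admm_inner(
    system: HeterogeneousSystem,
    W: np.ndarray,
    cfg: SolverConfig,
    state: SolverState,
) -> SolverState:
    """Run T -> X -> E sweeps with fixed weights until the relative change
    of X and its increment both fall below tolerance."""
    X, T, E = state.X, state.T, state.E
    s1_prev: float | None = None
    state.converged = False
    tiny = np.finfo(float).tiny
    for it in range(1, cfg.max_inner + 1):
        T = update_T(X, E, system, cfg.alpha, cfg.beta)
        X_new = update_X(T, E, W, cfg.beta)
        E = update_E(E, X_new, T, cfg.beta)
        if not (np.isfinite(X_new).all() and np.isfinite(E).all()):
            raise DivergenceError(f"non-finite iterate at inner iteration {it}")
        s1 = float(np.linalg.norm(X_new - X) / max(np.linalg.norm(X), tiny))
        s2 = np.inf if s1_prev is None else abs(s1 - s1_prev) / max(abs(s1_prev), 1.0)
        state.trace.append(s1)
        X = X_new
        state.inner_iter = it
        state.rel_change, state.rel_change_delta = s1, s2
        s1_prev = s1
        if s1 <= cfg.eps1 and s2 <= cfg.eps2:
            state.converged = True
            break
    state.X, state.T, state.E = X, T, E
    state.weights = W
    return state


# ---------------------------------------------------------------------------
# full solve


def solve(system: HeterogeneousSystem, cfg: SolverConfig | None = None) -> CompletionResult:
    """Two-level truncated Schatten p-norm completion of H.

    Outer iterations refresh the truncation factors from the SVD of the
    current X; each then recomputes the weight sequence and runs the inner
    ADMM warm-started from the previous iterates.  The outer loop stops
    early once X itself moves by less than eps1 in relative Frobenius norm.
    """
    cfg = (cfg or SolverConfig()).validate(n=system.H.shape[0])
    logger.info(
        "solver config: alpha=%g beta=%g p=%g r=%d outer=%d reweight=%d "
        "eps1=%g eps2=%g max_inner=%d",
        cfg.alpha, cfg.beta, cfg.p, cfg.r, cfg.outer_iters,
        cfg.reweight_iters, cfg.eps1, cfg.eps2, cfg.max_inner,
    )
    X = system.H.copy()
    state = SolverState(X=X, T=X.copy(), E=np.zeros_like(X))
    iterations: list[int] = []
    tiny = np.finfo(float).tiny
    converged = False
    for l in range(1, cfg.outer_iters + 1):
        state.outer_iter = l
        X_prev = state.X.copy()
        A, B = truncation_factors(state.X, cfg.r)
        for _ in range(cfg.reweight_iters):
            sigma_x = svdvals(state.X)
            W = compute_weights(sigma_x, A, B, cfg.p, cfg.sigma_floor)
            assert np.all(np.diff(W) >= -1e-12), "weights must be non-decreasing"
            state = admm_inner(system, W, cfg, state)
        iterations.append(state.inner_iter)
        outer_rel = float(
            np.linalg.norm(state.X - X_prev) / max(np.linalg.norm(X_prev), tiny)
        )
        logger.info(
            "outer %d: inner_iters=%d rel_change=%.3g outer_rel=%.3g",
            l, state.inner_iter, state.rel_change, outer_rel,
        )
        if outer_rel <= cfg.eps1:
            converged = True
            break
    converged = converged or state.converged
    H_star = np.clip(state.X, 0.0, 1.0)
    nm, nd = system.block_layout
    result = CompletionResult(
        H_star=H_star,
        A_star=_score_block(H_star, system),
        MM_star=H_star[:nm, :nm],
        DD_star=H_star[nm:, nm:],
        converged=converged,
        iterations=iterations,
        trace=list(state.trace),
    )
    return result


def _score_block(H_star: np.ndarray, system: HeterogeneousSystem) -> LabeledMatrix:
    nm, nd = system.block_layout
    block = (H_star[:nm, nm:] + H_star[nm:, :nm].T) / 2.0
    mirna_ids = system.mirna_ids or [f"row{i}" for i in range(nm)]
    disease_ids = system.disease_ids or [f"col{j}" for j in range(nd)]
    return LabeledMatrix(mirna_ids, disease_ids, block, Role.SCORES)


def extract_association_scores(
    result: CompletionResult, layout: tuple[int, int] | None = None
) -> LabeledMatrix:
    """The completed association block, averaged with its transpose twin.

    Entries are probabilities of candidate miRNA-disease associations.
    """
    scores = result.A_star
    assert scores.values.min() >= 0.0 and scores.values.max() <= 1.0
    return scores
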