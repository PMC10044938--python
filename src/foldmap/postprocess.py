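"""Decode a base-pairing score map into a feasible secondary structure.

Structure prediction is posed as a constrained optimization over binary
contact maps P in {0,1}^{L x L}:

    maximize   <S, P> - rho * ||P||_1
    subject to P symmetric, supported on the constraint mask,
               (1/2) (P + P^T) 1 <= 1   (at most one partner per base)

where the mask admits only canonical (A-U, C-G) and wobble (G-U) pairs at
sequence separation |i - j| >= 4, and rho >= 0 trades structure size for
sparsity. Because feasibility involves only per-base degree constraints and
not nesting, crossing (pseudoknotted) pair sets are first-class solutions.

The continuous relaxation (entries in [0, 1]) is solved by a primal-dual
scheme: projected gradient ascent on P against non-negative multipliers that
price row-sum violations. The relaxed solution is then rounded by a
threshold-plus-greedy rule that guarantees feasibility unconditionally.

The integer program restricted to the mask is a maximum-weight matching on
the graph of allowed cells with edge weight 2*(s_ij - rho); an exhaustive
oracle over matchings (:func:`brute_force_optimum`) is provided for
validation at small L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Set, Tuple

import numpy as np

from .sequence import RnaSequence

#: Admissible unordered base pairs: Watson-Crick plus the G-U wobble.
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

#: Minimum sequence separation of a pair; |i-j| < 4 is masked out.
MIN_SEPARATION = 4

_SYMMETRY_TOL = 1e-4


@dataclass
class SolverConfig:
    """Hyperparameters of the relaxed primal-dual decoder.

    rho is the L1 coefficient (sparsity penalty per unit of ||P||_1); the
    remaining fields are plumbing of the iterative solve, not part of the
    optimization model.
    """

    rho: float = 0.01
    step_primal: float = 0.05
    step_dual: float = 0.05
    iterations: int = 200
    binarize_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")


def build_constraint_mask(seq: RnaSequence) -> np.ndarray:
    """Binary L x L mask of admissible pairings.

    ``mask[i, j] == 1`` iff {b_i, b_j} is canonical/wobble and |i - j| >= 4.
    Symmetric with an all-zero band of width 2*MIN_SEPARATION-1 around the
    diagonal.
    """
    L = len(seq)
    b = seq.indices()
    # pairable[x, y] over base indices A=0 C=1 G=2 U=3
    pairable = np.zeros((4, 4), dtype=bool)
    for x, y in CANONICAL_PAIRS:
        pairable["ACGU".index(x), "ACGU".index(y)] = True
    mask = pairable[b[:, None], b[None, :]]
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    mask &= sep >= MIN_SEPARATION
    return mask.astype(np.uint8)


def relaxed_primal_dual_solve(
    S: np.ndarray, mask: np.ndarray, cfg: SolverConfig | None = None
) -> np.ndarray:
    """Solve the box/degree-relaxed program; returns P_hat in [0, 1]^{L x L}.

    Each primal step ascends <S, P> - rho*||P||_1 - lambda^T (P 1 - 1) and
    projects back onto the symmetric box supported on the mask; each dual
    step ascends the row-sum violations and clips the multipliers at zero.
    """
    cfg = cfg or SolverConfig()
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"score map must be square, got shape {S.shape}")
    if np.max(np.abs(S - S.T), initial=0.0) > _SYMMETRY_TOL:
        raise ValueError("score map is not symmetric within tolerance")
    if mask.shape != S.shape:
        raise ValueError("mask/score shape mismatch")

    m = mask.astype(bool)
    L = S.shape[0]
    P = np.zeros((L, L))
    lam = np.zeros(L)
    grad_const = S - cfg.rho  # d/dP of the regularized objective on [0,1]
    for _ in range(cfg.iterations):
        # primal ascent; the multiplier of cell (i,j) prices both row i and row j
        grad = grad_const - 0.5 * (lam[:, None] + lam[None, :])
        P += cfg.step_primal * grad
        P = 0.5 * (P + P.T)
        np.clip(P, 0.0, 1.0, out=P)
        P[~m] = 0.0
        # dual ascent on row-sum violations
        lam += cfg.step_dual * (P.sum(axis=1) - 1.0)
        np.clip(lam, 0.0, None, out=lam)
    return P


def discretize(relaxed: np.ndarray, mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Round a relaxed solution to a feasible binary contact map.

    Candidate cells (upper triangle, on-mask, value >= threshold) are accepted
    greedily in descending relaxed value — ties broken by smallest (i, j) —
    skipping any cell whose row or column is already occupied. The output
    satisfies all contact-map invariants for arbitrary input.
    """
    L = relaxed.shape[0]
    m = mask.astype(bool)
    iu, ju = np.triu_indices(L, k=1)
    keep = m[iu, ju] & (relaxed[iu, ju] >= threshold)
    iu, ju = iu[keep], ju[keep]
    vals = relaxed[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    used = np.zeros(L, dtype=bool)
    P = np.zeros((L, L), dtype=np.uint8)
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        P[i, j] = P[j, i] = 1
    return P


def greedy_complete(
    P: np.ndarray, S: np.ndarray, mask: np.ndarray, rho: float
) -> np.ndarray:
    """Add positive-gain pairs the rounding left on the table.

    Any admissible cell with s_ij - rho > 0 whose two bases are still free
    strictly increases the objective; such cells are accepted in descending
    score order (ties by smallest (i, j)). A pure improvement step: the
    output is feasible whenever the input is, and its objective is >= the
    input's. It recovers pairs whose relaxed mass was split between
    competitors and fell below the rounding threshold.
    """
    P = P.copy()
    L = P.shape[0]
    used = P.sum(axis=1) > 0
    iu, ju = np.triu_indices(L, k=1)
    keep = mask.astype(bool)[iu, ju] & (S[iu, ju] - rho > 0) & (P[iu, ju] == 0)
    iu, ju = iu[keep], ju[keep]
    order = np.lexsort((ju, iu, -S[iu, ju]))
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if not used[i] and not used[j]:
            used[i] = used[j] = True
            P[i, j] = P[j, i] = 1
    return P


def predict_structure(
    seq: RnaSequence, S: np.ndarray, cfg: SolverConfig | None = None
) -> np.ndarray:
    """Full decode: constraint mask -> primal-dual relaxation -> rounding.

    The rounded map is finished with :func:`greedy_complete`, which only ever
    adds objective-improving pairs. Returns the binary symmetric contact
    map. Crossing pairs are returned whenever they are optimal; no nesting
    restriction is imposed.
    """
    cfg = cfg or SolverConfig()
    if S.shape[0] != len(seq):
        raise ValueError(
            f"score map size {S.shape[0]} does not match sequence length {len(seq)}"
        )
    mask = build_constraint_mask(seq)
    relaxed = relaxed_primal_dual_solve(S, mask, cfg)
    P = discretize(relaxed, mask, cfg.binarize_threshold)
    return greedy_complete(P, np.asarray(S, dtype=np.float64), mask, cfg.rho)


def contact_map_to_pairs(P: np.ndarray) -> Set[Tuple[int, int]]:
    """0-based (i, j) pairs with i < j from a binary contact map."""
    iu, ju = np.nonzero(np.triu(P, k=1))
    return {(int(i), int(j)) for i, j in zip(iu, ju)}


def pairs_to_contact_map(pairs, L: int) -> np.ndarray:
    """Binary symmetric contact map from 0-based (i, j) pairs."""
    P = np.zeros((L, L), dtype=np.uint8)
    for i, j in pairs:
        P[i, j] = P[j, i] = 1
    return P


def integer_objective(S: np.ndarray, P: np.ndarray, rho: float) -> float:
    """<S, P> - rho*||P||_1 for a binary contact map P."""
    return float((S * P).sum() - rho * P.sum())


def brute_force_optimum(
    S: np.ndarray, mask: np.ndarray, rho: float, max_length: int = 14
) -> Tuple[float, np.ndarray]:
    """Exact optimum of the integer program by exhaustive matching search.

    Enumerates all matchings of the allowed-cell graph (each chosen pair
    contributes 2*(s_ij - rho) since P is symmetric). Intended as a testing
    oracle; refuses L beyond ``max_length``.
    """
    L = S.shape[0]
    if L > max_length:
        raise ValueError(f"brute force limited to L <= {max_length}, got {L}")
    iu, ju = np.triu_indices(L, k=1)
    on = mask.astype(bool)[iu, ju]
    edges = [
        (int(i), int(j), 2.0 * (float(S[i, j]) - rho))
        for i, j in zip(iu[on], ju[on])
    ]

    best_val = 0.0
    best_pairs: List[Tuple[int, int]] = []

    def recurse(k: int, used: int, val: float, chosen: List[Tuple[int, int]]) -> None:
        nonlocal best_val, best_pairs
        if val > best_val:
            best_val, best_pairs = val, list(chosen)
        for idx in range(k, len(edges)):
            i, j, w = edges[idx]
            bit_i, bit_j = 1 << i, 1 << j
            if used & (bit_i | bit_j):
                continue
            chosen.append((i, j))
            recurse(idx + 1, used | bit_i | bit_j, val + w, chosen)
            chosen.pop()

    recurse(0, 0, 0.0, [])
    return best_val, pairs_to_contact_map(best_pairs, L)
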