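"""Exact non-negative least squares for many right-hand sides at once.

``nnls_multi(A, B)`` solves ``min ||A K - B||_F`` subject to ``K >= 0``
column-by-column, sharing the normal equations across all right-hand
sides and grouping columns with identical passive sets so each active-set
step costs one batched linear solve (the fast combinatorial NNLS scheme
of Van Benthem & Keenan). Inside MCR-ALS both block updates are problems
of exactly this shape — one left matrix, hundreds of right-hand sides —
so this is the inner loop of the whole resolution step.

A per-column fallback to ``scipy.optimize.nnls`` guards against the rare
degenerate cycling case.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

__all__ = ["nnls_multi"]


def _solve_passive(AtA: np.ndarray, AtB: np.ndarray, passive: np.ndarray) -> np.ndarray:
    """Least-squares solutions restricted to per-column passive sets.

    Columns sharing a passive-set pattern are solved together with one
    (pseudo-)inverse of the corresponding submatrix of the normal matrix.
    """
    k, r = AtB.shape
    K = np.zeros((k, r))
    codes = (passive.astype(np.uint64).T * (1 << np.arange(k, dtype=np.uint64))).sum(
        axis=1
    )
    for code in np.unique(codes):
        cols = np.nonzero(codes == code)[0]
        pset = np.nonzero(passive[:, cols[0]])[0]
        if pset.size == 0:
            continue
        sub_A = AtA[np.ix_(pset, pset)]
        sub_B = AtB[np.ix_(pset, cols)]
        try:
            sol = np.linalg.solve(sub_A, sub_B)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub_A, sub_B, rcond=None)[0]
        K[np.ix_(pset, cols)] = sol
    return K


def nnls_multi(A: np.ndarray, B: np.ndarray, tol: float | None = None) -> np.ndarray:
    """Solve ``min ||A K - B||_F`` with ``K >= 0`` for every column of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    squeeze = B.ndim == 1
    if squeeze:
        B = B[:, None]
    if B.shape[0] != A.shape[0]:
        raise ValueError("B must have the same number of rows as A")
    m, k = A.shape
    r = B.shape[1]
    AtA = A.T @ A
    AtB = A.T @ B
    if tol is None:
        tol = 10 * np.finfo(float).eps * max(np.linalg.norm(AtA, 1), 1.0) * k

    # start from the unconstrained solution; clip to get initial passive sets
    try:
        K = np.linalg.solve(AtA, AtB)
    except np.linalg.LinAlgError:
        K = np.linalg.lstsq(AtA, AtB, rcond=None)[0]
    passive = K > tol
    K[~passive] = 0.0
    D = K.copy()

    fcols = np.nonzero(~passive.all(axis=0))[0]
    max_outer = 5 * k + 10
    outer = 0
    while fcols.size:
        outer += 1
        if outer > max_outer:
            break  # fall back below
        K[:, fcols] = _solve_passive(AtA, AtB[:, fcols], passive[:, fcols])
        inner = 0
        hcols = fcols[(K[:, fcols] < -tol).any(axis=0)]
        while hcols.size and inner <= 10 * k:
            inner += 1
            # step toward feasibility along D -> K, zeroing the blocking var
            Kh, Dh = K[:, hcols], D[:, hcols]
            neg = passive[:, hcols] & (Kh < -tol)
            alpha = np.full(Kh.shape, np.inf)
            denom = Dh - Kh
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(neg, Dh / denom, np.inf)
            alpha = np.where(neg, ratio, alpha)
            a_min = alpha.min(axis=0)
            a_min = np.where(np.isfinite(a_min), a_min, 1.0)  # degenerate column guard
            blk = alpha.argmin(axis=0)
            D[:, hcols] = Dh - a_min * (Dh - Kh)
            D[blk, hcols] = 0.0
            passive[blk, hcols] = False
            K[:, hcols] = _solve_passive(AtA, AtB[:, hcols], passive[:, hcols])
            hcols = hcols[(K[:, hcols] < -tol).any(axis=0)]
        if hcols.size:
            break  # cycling: fall back below
        K[:, fcols] = np.clip(K[:, fcols], 0.0, None)
        W = AtB[:, fcols] - AtA @ K[:, fcols]
        # a column is optimal when no active variable has positive gradient
        active_grad = np.where(~passive[:, fcols], W, -np.inf)
        optimal = (active_grad <= tol).all(axis=0)
        new_f = fcols[~optimal]
        if new_f.size:
            grow = active_grad[:, ~optimal].argmax(axis=0)
            passive[grow, new_f] = True
            D[:, new_f] = K[:, new_f]
        fcols = new_f

    bad = np.nonzero((K < -tol).any(axis=0))[0] if fcols.size else np.empty(0, int)
    fallback = set(bad.tolist()) | set(fcols.tolist())
    for j in fallback:
        K[:, j] = _scipy_nnls(A, B[:, j])[0]
    K = np.clip(K, 0.0, None)
    return K[:, 0] if squeeze else K
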