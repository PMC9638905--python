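"""Regularized bilinear regression baseline (affinity regression).

Solves ``D W P^T ~ Y`` for the interaction matrix ``W`` (TFs x alterations),
where ``Y`` (genes x tumors) is expression, ``D`` (genes x TFs) the binary
TF-attribute matrix and ``P`` (tumors x alterations) the binary somatic
profile matrix.  The vectorised system ``(P (x) D) vec(W) ~ vec(Y)`` is a
ridge regression whose normal equations factor over the Kronecker product::

    (P^T P (x) D^T D + lambda I) vec(W) = vec(D^T Y P)

With eigendecompositions ``D^T D = U diag(s) U^T`` and
``P^T P = V diag(t) V^T`` the solution is computed entry-wise in the
eigenbasis, so the Kronecker product is never materialised.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .interpret import spearman_per_tumor


@dataclass
class BilinearSystem:
    Y: np.ndarray  # genes x tumors
    D: np.ndarray  # genes x TFs
    P: np.ndarray  # tumors x alterations
    ridge: float = 1.0

    def __post_init__(self) -> None:
        n, m = self.Y.shape
        if self.D.shape[0] != n:
            raise ValueError("D must have one row per gene of Y")
        if self.P.shape[0] != m:
            raise ValueError("P must have one row per tumor (column of Y)")
        if self.ridge <= 0:
            raise ValueError("ridge penalty must be positive (lambda > 0)")


def fit(system: BilinearSystem) -> np.ndarray:
    """Ridge solution W (TFs x alterations) of the factored normal equations."""
    D, P, Y, lam = system.D, system.P, system.Y, system.ridge
    s, U = np.linalg.eigh(D.T @ D)
    t, V = np.linalg.eigh(P.T @ P)
    rhs = U.T @ (D.T @ Y @ P) @ V          # Q x S in the joint eigenbasis
    denom = s[:, None] * t[None, :] + lam  # eigenvalues of the Kronecker Gram
    return U @ (rhs / denom) @ V.T


def fit_explicit(system: BilinearSystem) -> np.ndarray:
    """Direct ridge solve on the materialised Kronecker design (small systems
    only; quadratic in Q*S memory).  Used as a cross-check for :func:`fit`."""
    D, P, Y, lam = system.D, system.P, system.Y, system.ridge
    X = np.kron(P, D)
    q, sdim = D.shape[1], P.shape[1]
    gram = X.T @ X + lam * np.eye(q * sdim)
    w = np.linalg.solve(gram, X.T @ Y.reshape(-1, order="F"))
    return w.reshape(q, sdim, order="F")


def predict(W: np.ndarray, D: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Predicted expression Yhat = D W P^T (genes x tumors)."""
    return D @ W @ P.T


def tune_ridge(
    Y: np.ndarray,
    D: np.ndarray,
    P: np.ndarray,
    lambda_grid: Sequence[float],
    k: int = 5,
    seed: int = 0,
) -> Tuple[float, pd.DataFrame]:
    """Pick lambda by k-fold CV over tumors, scoring mean per-tumor Spearman."""
    m = Y.shape[1]
    if k > m:
        raise ValueError("more folds than tumors")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)
    rows = []
    for lam in lambda_grid:
        scores = []
        for fold in folds:
            mask = np.ones(m, dtype=bool)
            mask[fold] = False
            system = BilinearSystem(Y=Y[:, mask], D=D, P=P[mask], ridge=lam)
            W = fit(system)
            yhat = predict(W, D, P[fold])
            _, rho = spearman_per_tumor(Y[:, fold].T, yhat.T)
            scores.append(rho)
        rows.append({"ridge": lam, "mean_spearman": float(np.mean(scores))})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["mean_spearman"].idxmax(), "ridge"])
    return best, table


def evaluate_baseline(
    Y: np.ndarray,
    D: np.ndarray,
    P: np.ndarray,
    cancer_types: Sequence[str],
    test_mask: np.ndarray,
    lambda_grid: Sequence[float] = (1e-2, 1e-1, 1.0, 10.0, 100.0),
    cv_k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cancer-type evaluation: fit one bilinear model per type on its
    training tumors (lambda tuned by CV) and report mean per-tumor Spearman on
    that type's test tumors.  ``test_mask`` flags held-out tumors (columns of
    Y)."""
    cts = np.asarray(cancer_types)
    rows = []
    for ct in sorted(set(cts.tolist())):
        tr = (cts == ct) & ~test_mask
        te = (cts == ct) & test_mask
        if tr.sum() < cv_k or te.sum() == 0:
            continue
        lam, _ = tune_ridge(Y[:, tr], D, P[tr], lambda_grid, k=cv_k, seed=seed)
        W = fit(BilinearSystem(Y=Y[:, tr], D=D, P=P[tr], ridge=lam))
        yhat = predict(W, D, P[te])
        rhos, mean_rho = spearman_per_tumor(Y[:, te].T, yhat.T)
        rows.append(
            {"cancer_type": ct, "n_test": int(te.sum()), "ridge": lam,
             "mean_spearman": mean_rho}
        )
    return pd.DataFrame(rows)
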