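"""Edge-weight imputation for incomplete incidence matrices.

Four strategies with increasing structural awareness:

* ``mean`` / ``median`` — a missing cell (i, j) gets the average of the row-i
  statistic and the column-j statistic over observed cells (rows or columns
  with no observations fall back to the global statistic).
* ``als`` — regularised alternating least squares matrix completion: rank-r
  factors U, V minimising the squared error on *observed* cells plus a ridge
  penalty; missing cells are filled with u_i . v_j.
* ``ca`` — iterative correspondence analysis: missing cells are initialised
  with the mean rule, then repeatedly re-estimated from a k-dimensional CA
  reconstruction (row/column masses + truncated SVD of standardised
  residuals) of the completed matrix, clipped at zero to preserve the
  contingency-table semantics.

Every method leaves observed cells bitwise unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .incidence import IncidenceMatrix

METHODS = ("mean", "median", "ca", "als")


@dataclass
class CompletedMatrix:
    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    fit_info: dict = field(default_factory=dict)

    def to_incidence(self, M: IncidenceMatrix) -> IncidenceMatrix:
        """Fully observed incidence matrix carrying the completed values."""
        return IncidenceMatrix(
            A=self.values.copy(),
            mask=np.ones_like(self.values, dtype=bool),
            row_names=list(M.row_names),
            col_names=list(M.col_names),
            weighted=True,
        )


def _check(M: IncidenceMatrix) -> None:
    if not M.mask.any():
        raise ValueError("matrix has no observed cells")


def impute_simple(M: IncidenceMatrix, statistic: str = "mean") -> CompletedMatrix:
    """Row/column-symmetric mean or median imputation."""
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    _check(M)
    A = np.where(M.mask, M.A, np.nan)
    fn = np.nanmean if statistic == "mean" else np.nanmedian
    obs = A[M.mask]
    global_stat = float(fn(obs))
    with warnings.catch_warnings():
        # all-NaN rows/columns raise RuntimeWarning; handled by the fallback
        warnings.simplefilter("ignore", RuntimeWarning)
        row_stat = fn(A, axis=1)
        col_stat = fn(A, axis=0)
    row_stat = np.where(np.isfinite(row_stat), row_stat, global_stat)
    col_stat = np.where(np.isfinite(col_stat), col_stat, global_stat)
    filled = 0.5 * (row_stat[:, None] + col_stat[None, :])
    values = np.where(M.mask, M.A, filled)
    return CompletedMatrix(
        values=values, method=statistic, params={"statistic": statistic}
    )


def impute_als(
    M: IncidenceMatrix,
    rank: int = 2,
    ridge: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> CompletedMatrix:
    """Rank-``rank`` ALS completion on observed cells with ridge ``ridge``.

    Each half-step solves the exact ridge problem for one factor, so the
    penalised loss is non-increasing across iterations; iteration stops when
    the observed-cell RMSE improves by less than ``tol``.
    """
    _check(M)
    m, n = M.shape
    if rank > min(m, n):
        raise ValueError("rank must not exceed min(m, n)")
    if int(M.mask.sum()) < rank * max(m, n):
        warnings.warn(
            "few observed cells for the requested rank; fit may be unstable",
            stacklevel=2,
        )
    A = M.values_filled(0.0)
    W = M.mask
    # warm start from the SVD of the mean-completed matrix: alternating
    # minimisation on observed cells has poor local minima under random
    # initialisation, and the warm start makes the fit reproducible
    X0 = impute_simple(M, "mean").values
    u0, s0, vt0 = np.linalg.svd(X0, full_matrices=False)
    U = u0[:, :rank] * np.sqrt(s0[:rank])
    V = vt0[:rank].T * np.sqrt(s0[:rank])
    rng = np.random.default_rng(seed)
    jitter = 1e-3 * (np.abs(A[W]).mean() or 1.0)
    U = U + rng.normal(scale=jitter, size=U.shape)
    V = V + rng.normal(scale=jitter, size=V.shape)
    eye = ridge * np.eye(rank)

    def _loss() -> tuple[float, float]:
        R = (A - U @ V.T)[W]
        sq = float((R**2).sum())
        pen = sq + ridge * (float((U**2).sum()) + float((V**2).sum()))
        return pen, float(np.sqrt(sq / W.sum()))

    losses = []
    prev_rmse = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(m):
            idx = W[i]
            if not idx.any():
                U[i] = 0.0
                continue
            Vi = V[idx]
            U[i] = np.linalg.solve(Vi.T @ Vi + eye, Vi.T @ A[i, idx])
        for j in range(n):
            idx = W[:, j]
            if not idx.any():
                V[j] = 0.0
                continue
            Uj = U[idx]
            V[j] = np.linalg.solve(Uj.T @ Uj + eye, Uj.T @ A[idx, j])
        pen, rmse = _loss()
        losses.append(pen)
        if prev_rmse - rmse < tol:
            prev_rmse = rmse
            break
        prev_rmse = rmse
    values = np.where(W, M.A, U @ V.T)
    return CompletedMatrix(
        values=values,
        method="als",
        params={"rank": rank, "ridge": ridge, "max_iter": max_iter, "tol": tol,
                "seed": seed},
        fit_info={
            "iterations": n_iter,
            "final_rmse_observed": prev_rmse,
            "loss_history": losses,
        },
    )


def impute_ca(
    M: IncidenceMatrix,
    n_dims: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CompletedMatrix:
    """Iterative correspondence-analysis imputation (non-negative input).

    CA treats the matrix as a contingency-like table, so observed weights
    must be non-negative (use ALS for signed data).  Each sweep decomposes
    the completed correspondence matrix Z = D_r^(-1/2) P D_c^(-1/2) and
    reconstructs missing cells from its leading ``n_dims`` dimensions.  The
    first dimension is the trivial (independence) one, so ``n_dims=1``
    reproduces the independence expectation r_i c_j N and ``n_dims=k`` adds
    the k-1 strongest association dimensions.  Reconstructed missing values
    are clipped at zero to preserve the contingency-table semantics.
    """
    _check(M)
    obs = M.A[M.mask]
    if np.any(obs < 0):
        raise ValueError("CA needs non-negative observed weights; use ALS instead")
    if not np.any(obs > 0):
        raise ValueError("all-zero matrix cannot be decomposed by CA")
    X = impute_simple(M, "mean").values
    X = np.clip(X, 0.0, None)
    miss = ~M.mask
    eps = np.finfo(float).tiny
    delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        total = X.sum()
        P = X / total
        r = np.maximum(P.sum(axis=1), eps)
        c = np.maximum(P.sum(axis=0), eps)
        sqrtE = np.sqrt(np.outer(r, c))
        Z = P / sqrtE
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        k = min(n_dims, s.size)
        Zk = (u[:, :k] * s[:k]) @ vt[:k]
        recon = sqrtE * Zk * total
        new_missing = np.clip(recon[miss], 0.0, None)
        delta = float(np.max(np.abs(new_missing - X[miss]))) if miss.any() else 0.0
        X[miss] = new_missing
        if delta < tol:
            break
    values = np.where(M.mask, M.A, X)
    return CompletedMatrix(
        values=values,
        method="ca",
        params={"n_dims": n_dims, "max_iter": max_iter, "tol": tol},
        fit_info={"iterations": n_iter, "final_delta": delta},
    )


def impute(M: IncidenceMatrix, method: str, **kwargs) -> CompletedMatrix:
    """Dispatch by method name ('mean', 'median', 'ca', 'als')."""
    if method in ("mean", "median"):
        return impute_simple(M, statistic=method)
    if method == "als":
        return impute_als(M, **kwargs)
    if method == "ca":
        return impute_ca(M, **kwargs)
    raise ValueError(f"unknown imputation method {method!r}")
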