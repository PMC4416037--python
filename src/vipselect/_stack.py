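"""Batched sparse PLS-DA fits for cross-validation loops.

Leave-one-out cross-validation refits the same small model on n nearly
identical data subsets; doing that in a Python loop over
:func:`vipselect.spls.fit_spls_da` dominates the runtime of the nested
procedure.  This module fits a whole stack of independent problems
(one slice per fold) with broadcast numpy operations.  Semantics are
identical to the single-model fit -- the test suite asserts slice-by-slice
agreement -- including per-slice early stop on rank deficiency.
"""

from __future__ import annotations

import numpy as np


def loo_index_matrix(n: int) -> np.ndarray:
    """Row indices of the n leave-one-out training sets, shape (n, n-1)."""
    base = np.arange(n)
    idx = np.empty((n, n - 1), dtype=int)
    for i in range(n):
        idx[i, :i] = base[:i]
        idx[i, i:] = base[i + 1:]
    return idx


def fit_spls_stack(
    X: np.ndarray,
    Y: np.ndarray,
    ncomp: int,
    nkeep: int,
    *,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> dict:
    """Fit ``b`` independent sparse PLS-DA models.

    Parameters
    ----------
    X : (b, n, p) stacked centered-or-not feature matrices (centering is done
        internally per slice, as in the single fit).
    Y : (b, n, K) stacked dummy responses.

    Returns
    -------
    dict with stacked arrays: ``W (b,p,H)``, ``C (b,K,H)``, ``ssy (b,H)``,
    ``B (b,p,K)``, ``x_mean (b,p)``, ``y_mean (b,K)``, ``achieved (b,)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    b, n, p = X.shape
    K = Y.shape[2]
    H = int(ncomp)

    x_mean = X.mean(axis=1)
    y_mean = Y.mean(axis=1)
    Xh = X - x_mean[:, None, :]
    Yh = Y - y_mean[:, None, :]
    scale0 = np.sqrt((Xh**2).sum(axis=(1, 2)))
    tt_floor = (1e-10 * np.maximum(scale0, 1.0)) ** 2
    m_floor = (1e-14 * np.maximum(scale0, 1.0)) ** 2

    W = np.zeros((b, p, H))
    P = np.zeros((b, p, H))
    C = np.zeros((b, K, H))
    ssy = np.zeros((b, H))
    achieved = np.zeros(b, dtype=int)
    active = np.ones(b, dtype=bool)

    for h in range(H):
        M = Xh.transpose(0, 2, 1) @ Yh  # (b, p, K)
        act = active & ((M**2).sum(axis=(1, 2)) > m_floor)
        if not act.any():
            break
        _vals, vecs = np.linalg.eigh(M.transpose(0, 2, 1) @ M)
        v = vecs[:, :, -1]  # (b, K)
        u = np.zeros((b, p))
        u_prev = None
        for _it in range(max_iter):
            u = np.einsum("bpk,bk->bp", M, v)
            if nkeep < p:
                order = np.argsort(-np.abs(u), axis=1, kind="stable")
                drop = order[:, nkeep:]
                np.put_along_axis(u, drop, 0.0, axis=1)
            nu = np.linalg.norm(u, axis=1)
            act &= nu > 0
            safe = np.where(nu > 0, nu, 1.0)
            u = u / safe[:, None]
            v = np.einsum("bpk,bp->bk", M, u)
            nv = np.linalg.norm(v, axis=1)
            act &= nv > 0
            v = v / np.where(nv > 0, nv, 1.0)[:, None]
            if u_prev is not None:
                sign = np.where((u * u_prev).sum(axis=1) >= 0, 1.0, -1.0)
                delta = np.abs(u - sign[:, None] * u_prev).max(axis=1)
                if not act.any() or np.all(delta[act] < tol):
                    break
            u_prev = u
        t = np.einsum("bnp,bp->bn", Xh, u)
        tt = (t**2).sum(axis=1)
        act &= tt > tt_floor
        if not act.any():
            break
        safe_tt = np.where(act, tt, 1.0)
        p_h = np.einsum("bnp,bn->bp", Xh, t) / safe_tt[:, None]
        c_h = np.einsum("bnk,bn->bk", Yh, t) / safe_tt[:, None]
        u = np.where(act[:, None], u, 0.0)
        t = np.where(act[:, None], t, 0.0)
        p_h = np.where(act[:, None], p_h, 0.0)
        c_h = np.where(act[:, None], c_h, 0.0)
        Xh = Xh - t[:, :, None] * p_h[:, None, :]
        Yh = Yh - t[:, :, None] * c_h[:, None, :]
        W[:, :, h] = u
        P[:, :, h] = p_h
        C[:, :, h] = c_h
        ssy[:, h] = np.where(act, tt * (c_h**2).sum(axis=1), 0.0)
        achieved += act.astype(int)
        active = act

    # Assemble regression coefficients per slice over the achieved components.
    B = np.zeros((b, p, K))
    uniform = np.all(achieved == H) and H > 0
    if uniform:
        PtW = P.transpose(0, 2, 1) @ W  # (b, H, H)
        B = W @ np.linalg.solve(PtW, C.transpose(0, 2, 1))
    else:
        for i in range(b):
            Hi = achieved[i]
            if Hi == 0:
                continue  # B stays 0 -> predictions fall back to the Y mean
            Wi = W[i, :, :Hi]
            Pi = P[i, :, :Hi]
            Ci = C[i, :, :Hi]
            B[i] = Wi @ np.linalg.solve(Pi.T @ Wi, Ci.T)

    return {
        "W": W,
        "P": P,
        "C": C,
        "ssy": ssy,
        "B": B,
        "x_mean": x_mean,
        "y_mean": y_mean,
        "achieved": achieved,
    }


def loo_sq_errors(X: np.ndarray, Y: np.ndarray, ncomp: int, nkeep: int) -> np.ndarray:
    """Leave-one-out squared prediction errors, shape (n, K).

    One model per left-out row, fitted as a batch; entry (i, k) is the squared
    error of the model trained without row i predicting row i's dummy entry k.
    """
    n = X.shape[0]
    idx = loo_index_matrix(n)
    fit = fit_spls_stack(X[idx], Y[idx], ncomp, nkeep)
    xc = X - fit["x_mean"]  # row i centered with fold i's training mean
    yhat = np.einsum("bp,bpk->bk", xc, fit["B"]) + fit["y_mean"]
    return (yhat - Y) ** 2


def loo_msep(X: np.ndarray, Y: np.ndarray, ncomp: int, nkeep: int) -> float:
    """Pooled LOOCV mean squared error of prediction on the dummy scale."""
    return float(loo_sq_errors(X, Y, ncomp, nkeep).mean())
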