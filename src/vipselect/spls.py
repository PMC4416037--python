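"""Sparse PLS discriminant analysis with VIP coefficients.

The estimator is sparse PLS in regression mode against a one-hot class
response: components are extracted one at a time as the dominant covariance
direction between the current X residual and Y, with the X loading-weight
vector constrained so that at most ``nkeep`` entries are nonzero.  Sparsity is
imposed by hard selection of the ``nkeep`` largest-magnitude entries followed
by renormalization, which realizes the adaptive soft-threshold at the level
that keeps exactly ``nkeep`` variables.  After each component X is deflated by
its rank-one reconstruction and Y by the component's response fit (regression
mode); with ``nkeep = p`` the procedure reduces exactly to dense two-block
PLS (PLS2).

Variable importance in projection (VIP) summarizes each feature's weighted
contribution across components,

    VIP_j = sqrt( p * sum_h SSY_h w_jh^2 / sum_h SSY_h ),

where ``w_h`` are the unit-norm loading weights and ``SSY_h`` the response sum
of squares captured by component ``h``.  Because the weight columns have unit
norm, the mean of squared VIPs over all p features is identically 1; features
never entering a kept set have VIP 0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .preprocess import DummyMatrix


class SplsError(ValueError):
    """Raised on invalid fit requests or shape mismatches."""


@dataclasses.dataclass
class SplsModel:
    """A fitted sparse PLS-DA model.

    Attributes
    ----------
    W : (p, H) loading weights, columns unit-norm with <= nkeep nonzeros.
    T : (n, H) X scores (mutually orthogonal).
    P : (p, H) X loadings.
    C : (K, H) response weights.
    B : (p, K) regression coefficients on centered data.
    ssy : (H,) response sum of squares captured per component.
    kept_sets : per-component arrays of retained feature indices.
    n_components : achieved number of components (may be < requested when the
        residual became rank deficient and the fit stopped early).
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    C: np.ndarray
    B: np.ndarray
    ssy: np.ndarray
    kept_sets: list
    class_order: list
    x_mean: np.ndarray
    y_mean: np.ndarray
    y_total_ss: float
    nkeep: int
    n_components: int
    ncomp_requested: int
    early_stopped: bool

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_classes(self) -> int:
        return self.C.shape[0]

    def to_json(self, path=None) -> str:
        payload = {
            "class_order": list(self.class_order),
            "nkeep": int(self.nkeep),
            "n_components": int(self.n_components),
            "ncomp_requested": int(self.ncomp_requested),
            "early_stopped": bool(self.early_stopped),
            "y_total_ss": float(self.y_total_ss),
            "kept_sets": [list(map(int, k)) for k in self.kept_sets],
        }
        for name in ("W", "T", "P", "C", "B", "ssy", "x_mean", "y_mean"):
            payload[name] = np.asarray(getattr(self, name)).tolist()
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SplsModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            W=np.asarray(d["W"], dtype=float),
            T=np.asarray(d["T"], dtype=float),
            P=np.asarray(d["P"], dtype=float),
            C=np.asarray(d["C"], dtype=float),
            B=np.asarray(d["B"], dtype=float),
            ssy=np.asarray(d["ssy"], dtype=float),
            kept_sets=[np.asarray(k, dtype=int) for k in d["kept_sets"]],
            class_order=list(d["class_order"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=np.asarray(d["y_mean"], dtype=float),
            y_total_ss=float(d["y_total_ss"]),
            nkeep=int(d["nkeep"]),
            n_components=int(d["n_components"]),
            ncomp_requested=int(d["ncomp_requested"]),
            early_stopped=bool(d["early_stopped"]),
        )


@dataclasses.dataclass
class VipScores:
    vip: np.ndarray
    n_components_used: int


def _hard_threshold(u: np.ndarray, nkeep: int) -> np.ndarray:
    """Zero all but the nkeep largest-|u| entries; ties keep the lower index."""
    p = u.size
    if nkeep >= p:
        return u.copy()
    order = np.argsort(-np.abs(u), kind="stable")
    out = np.zeros_like(u)
    keep = order[:nkeep]
    out[keep] = u[keep]
    return out


def fit_spls_da(
    X,
    Y,
    ncomp: int,
    nkeep: int,
    *,
    class_order=None,
    strict: bool = False,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> SplsModel:
    """Fit a sparse PLS-DA model.

    Parameters
    ----------
    X : (n, p) feature matrix (typically autoscaled upstream; the fit centers
        columns internally and records the means for prediction).
    Y : DummyMatrix or (n, K) one-hot response.
    ncomp : number of latent components requested.
    nkeep : maximum nonzero loading weights per component.
    strict : if True, refuse ``ncomp > min(n-1, p)`` outright; otherwise the
        fit stops early when the X residual becomes numerically rank deficient
        and records the achieved component count.
    """
    if isinstance(Y, DummyMatrix):
        class_order = list(Y.class_order)
        Y = Y.values
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise SplsError("X and Y must be 2-D with matching row counts")
    n, p = X.shape
    K = Y.shape[1]
    if class_order is None:
        class_order = [f"class_{k}" for k in range(K)]
    if ncomp < 1:
        raise SplsError("ncomp must be >= 1")
    if nkeep < 1:
        raise SplsError("nkeep must be >= 1")
    if n < 3:
        raise SplsError("need at least 3 samples")
    if strict and ncomp > min(n - 1, p):
        raise SplsError(
            f"ncomp={ncomp} exceeds min(n-1, p)={min(n - 1, p)} (strict mode)"
        )

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xh = X - x_mean
    Yh = Y - y_mean
    y_total_ss = float((Yh**2).sum())
    x_scale0 = float(np.sqrt((Xh**2).sum()))
    tt_floor = (1e-10 * max(x_scale0, 1.0)) ** 2

    W, T, P, C, ssy, kept = [], [], [], [], [], []
    for _h in range(ncomp):
        M = Xh.T @ Yh  # (p, K) cross-covariance of residuals
        if (M**2).sum() <= (1e-14 * max(x_scale0, 1.0)) ** 2:
            break
        # init: dominant right singular vector of M via the K x K Gram matrix
        _vals, vecs = np.linalg.eigh(M.T @ M)
        v = vecs[:, -1]
        u_prev = None
        for _it in range(max_iter):
            u = _hard_threshold(M @ v, nkeep)
            nu = np.linalg.norm(u)
            if nu == 0:
                break
            u = u / nu
            v = M.T @ u
            nv = np.linalg.norm(v)
            if nv == 0:
                break
            v = v / nv
            if u_prev is not None:
                sign = 1.0 if float(u @ u_prev) >= 0 else -1.0
                if np.max(np.abs(u - sign * u_prev)) < tol:
                    break
            u_prev = u
        if u_prev is None or np.linalg.norm(u) == 0:
            break
        t = Xh @ u
        tt = float(t @ t)
        if tt < tt_floor:
            break
        p_h = Xh.T @ t / tt
        c_h = Yh.T @ t / tt
        Xh = Xh - np.outer(t, p_h)
        Yh = Yh - np.outer(t, c_h)  # regression-mode deflation
        W.append(u)
        T.append(t)
        P.append(p_h)
        C.append(c_h)
        ssy.append(tt * float(c_h @ c_h))
        kept.append(np.flatnonzero(u))

    H = len(W)
    if H == 0:
        raise SplsError("no component could be extracted (degenerate data)")
    Wm = np.column_stack(W)
    Tm = np.column_stack(T)
    Pm = np.column_stack(P)
    Cm = np.column_stack(C)
    ssy_v = np.asarray(ssy)
    B = Wm @ np.linalg.solve(Pm.T @ Wm, Cm.T)
    return SplsModel(
        W=Wm,
        T=Tm,
        P=Pm,
        C=Cm,
        B=B,
        ssy=ssy_v,
        kept_sets=kept,
        class_order=list(class_order),
        x_mean=x_mean,
        y_mean=y_mean,
        y_total_ss=y_total_ss,
        nkeep=int(nkeep),
        n_components=H,
        ncomp_requested=int(ncomp),
        early_stopped=H < ncomp,
    )


def predict(model: SplsModel, X_new):
    """Predict dummy responses and class labels for new samples.

    Applies the training centering, forms ``Yhat = Xc B + y_mean`` and assigns
    each sample to the class with the largest predicted dummy entry
    (maximum-distance rule; exact ties resolve to the lowest class index).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise SplsError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    Yhat = (X_new - model.x_mean) @ model.B + model.y_mean
    labels = [model.class_order[int(k)] for k in np.argmax(Yhat, axis=1)]
    return Yhat, labels


def vip(model: SplsModel, n_components: int | None = None) -> VipScores:
    """Wold's VIP over the first ``n_components`` fitted components."""
    H = model.n_components if n_components is None else min(
        int(n_components), model.n_components
    )
    if H < 1:
        raise SplsError("VIP needs at least one fitted component")
    w2 = model.W[:, :H] ** 2
    s = model.ssy[:H]
    v = np.sqrt(model.n_features * (w2 @ s) / s.sum())
    return VipScores(vip=v, n_components_used=H)


def explained_y_variance(model: SplsModel):
    """Per-component and cumulative fractions of response sum of squares.

    Because scores are mutually orthogonal, the response SS decomposes over
    components; the cumulative sequence is non-decreasing and bounded by 1.
    """
    per = model.ssy / model.y_total_ss
    return per, np.cumsum(per)
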