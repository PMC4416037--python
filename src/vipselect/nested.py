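"""Nested double leave-one-out cross-validation for (nkeep, ncomp) selection.

The procedure tunes the two sparse PLS-DA hyperparameters -- the number of
variables kept per component (``nkeep``) and the number of latent components
(``ncomp``) -- on a grid, in three steps:

1. **Outer VIP filter.**  For each outer fold (one sample held out) and each
   grid cell, fit sparse PLS-DA on the outer training set and record the VIP
   coefficients; features with nonzero VIP define the cell's candidate set.
2. **Inner component tuning.**  Within each outer training set, a second
   leave-one-out loop evaluates the mean squared error of prediction (MSEP, on
   the dummy-response scale) for every cell, restricted to that fold/cell's
   candidate features; the per-``nkeep`` MSEP-minimizing ``ncomp`` is recorded.
3. **Outer test error.**  For every cell, the model refitted on each outer
   training set (restricted to its candidate features) predicts the held-out
   sample; pooling over folds yields an ``nkeep x ncomp`` MSEP matrix.

The MSEP matrix is converted to ascending ranks and smoothed with the 3x3
cross-shaped kernel ((0,1,0),(1,2,1),(0,1,0)), normalized at each position by
the in-bounds kernel weight, so that the chosen cell sits in a region that is
robustly good rather than an isolated minimum.  Features are finally scored by
their mean VIP across outer folds at the chosen cell; those at or above the
relevance threshold (default 1) form the relevance table, with an occurrence
count of how many folds individually put them at or above the threshold.

The whole procedure is deterministic: leave-one-out folds are exhaustive and
nothing is randomized.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata

from ._stack import fit_spls_stack, loo_index_matrix, loo_sq_errors
from .preprocess import DummyMatrix, FeatureTable, dummy_code
from .spls import SplsError, fit_spls_da, predict


class NestedCvError(ValueError):
    """Raised on invalid grids or degenerate cross-validation inputs."""


@dataclasses.dataclass
class Grid:
    """The (nkeep, ncomp) tuning grid; defaults span 1..100 x 1..10."""

    nkeep_values: tuple = tuple(range(1, 101))
    ncomp_values: tuple = tuple(range(1, 11))

    def __post_init__(self):
        self.nkeep_values = tuple(int(v) for v in self.nkeep_values)
        self.ncomp_values = tuple(int(v) for v in self.ncomp_values)
        for vals, name in (
            (self.nkeep_values, "nkeep_values"),
            (self.ncomp_values, "ncomp_values"),
        ):
            if len(vals) == 0:
                raise NestedCvError(f"{name} must be nonempty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise NestedCvError(f"{name} must be strictly increasing")
            if vals[0] < 1:
                raise NestedCvError(f"{name} must be >= 1")

    @classmethod
    def from_ranges(cls, nkeep: str, ncomp: str) -> "Grid":
        """Parse 'lo:hi' range strings, e.g. ``Grid.from_ranges('1:30', '1:4')``."""

        def rng(s):
            lo, hi = (int(x) for x in str(s).split(":"))
            return tuple(range(lo, hi + 1))

        return cls(rng(nkeep), rng(ncomp))

    @property
    def shape(self):
        return (len(self.nkeep_values), len(self.ncomp_values))


@dataclasses.dataclass
class CvGridResult:
    """State accumulated across the three nested-CV steps."""

    grid: Grid
    sample_ids: list                 # outer fold f holds out sample_ids[f]
    class_order: list
    feature_names: list
    vips: np.ndarray                 # (folds, nkeep, ncomp, p)
    achieved: np.ndarray             # (folds, nkeep, ncomp) components reached
    inner_msep: np.ndarray | None = None        # (folds, nkeep, ncomp)
    inner_optimal_ncomp: np.ndarray | None = None  # (folds, nkeep), values
    outer_msep: np.ndarray | None = None        # (nkeep, ncomp)
    contradiction_count: np.ndarray | None = None  # (nkeep, ncomp)

    @property
    def n_folds(self) -> int:
        return self.vips.shape[0]

    def masks(self):
        """Boolean nonzero-VIP candidate masks, shape (folds, nkeep, ncomp, p)."""
        return self.vips > 0


@dataclasses.dataclass
class SelectionResult:
    rank_matrix: np.ndarray
    smoothed_scores: np.ndarray
    optimal_nkeep: int
    optimal_ncomp: int
    relevance_table: pd.DataFrame
    vip_threshold: float
    tie_count: int

    def summary(self) -> dict:
        return {
            "optimal_nkeep": int(self.optimal_nkeep),
            "optimal_ncomp": int(self.optimal_ncomp),
            "n_relevant": int(len(self.relevance_table)),
            "vip_threshold": float(self.vip_threshold),
            "smoothed_score_min": float(np.min(self.smoothed_scores)),
            "tie_count": int(self.tie_count),
        }


# ---------------------------------------------------------------------------
# Elementary pieces
# ---------------------------------------------------------------------------

def msep(Y_pred, Y_true) -> float:
    """Mean squared error of prediction over all entries of the dummy block."""
    if isinstance(Y_true, DummyMatrix):
        Y_true = Y_true.values
    Y_pred = np.asarray(Y_pred, dtype=float)
    Y_true = np.asarray(Y_true, dtype=float)
    if Y_pred.shape != Y_true.shape:
        raise NestedCvError(
            f"shape mismatch: predicted {Y_pred.shape} vs true {Y_true.shape}"
        )
    return float(np.mean((Y_pred - Y_true) ** 2))


def _require_scaled(table: FeatureTable):
    if table.transform_state != "log_centered_scaled":
        raise NestedCvError(
            "nested selection expects an autoscaled table "
            f"(transform_state='log_centered_scaled', got {table.transform_state!r})"
        )


# ---------------------------------------------------------------------------
# Step 1: outer VIP filter
# ---------------------------------------------------------------------------

def outer_vip_filter(table: FeatureTable, grid: Grid) -> CvGridResult:
    """Fit every outer-fold training set over the grid and record VIPs.

    For a shared ``nkeep`` the sparse components are extracted sequentially,
    so the fit at the deepest requested ``ncomp`` contains every shallower
    model; each ``nkeep`` is therefore fitted once per fold and the per-cell
    VIPs are read off its leading components.  Cells deeper than the achieved
    component count reuse the deepest achievable model (recorded in
    ``achieved``).
    """
    _require_scaled(table)
    n, p = table.values.shape
    if n < 4:
        raise NestedCvError("need at least 4 samples for nested LOOCV")
    Y = dummy_code(table.class_labels)
    X = table.values
    idx = loo_index_matrix(n)
    Xs = X[idx]
    Ys = Y.values[idx]
    nk, nc = grid.shape
    max_ncomp = max(grid.ncomp_values)
    vips = np.zeros((n, nk, nc, p))
    achieved = np.zeros((n, nk, nc), dtype=int)
    comp_idx = np.arange(max_ncomp)
    for ik, k in enumerate(grid.nkeep_values):
        fit = fit_spls_stack(Xs, Ys, max_ncomp, k)
        W2 = fit["W"] ** 2  # (folds, p, H)
        ssy = fit["ssy"]    # (folds, H)
        for ic, c in enumerate(grid.ncomp_values):
            h_eff = np.minimum(c, fit["achieved"])  # per fold
            mask = comp_idx[None, :] < h_eff[:, None]  # (folds, H)
            s = ssy * mask
            denom = s.sum(axis=1)
            safe = np.where(denom > 0, denom, 1.0)
            v = np.sqrt(p * np.einsum("bph,bh->bp", W2, s) / safe[:, None])
            v = np.where(denom[:, None] > 0, v, 0.0)
            vips[:, ik, ic, :] = v
            achieved[:, ik, ic] = h_eff
    return CvGridResult(
        grid=grid,
        sample_ids=list(table.sample_ids),
        class_order=list(Y.class_order),
        feature_names=list(table.feature_names),
        vips=vips,
        achieved=achieved,
    )


# ---------------------------------------------------------------------------
# Step 2: inner ncomp tuning
# ---------------------------------------------------------------------------

def inner_tune_ncomp(table: FeatureTable, cv: CvGridResult) -> CvGridResult:
    """Inner LOOCV within each outer training set, per grid cell.

    Each cell's candidate features (nonzero outer-fold VIP) define the input
    matrix; the inner loop leaves out one training sample at a time and pools
    the squared dummy-scale errors.  Cells with an empty candidate set get
    MSEP ``+inf``.  Per (fold, nkeep) the MSEP-minimizing ``ncomp`` is stored
    (ties resolve to the smaller ``ncomp``).
    """
    _require_scaled(table)
    n = table.n_samples
    Y = dummy_code(table.class_labels)
    X = table.values
    idx = loo_index_matrix(n)
    nk, nc = cv.grid.shape
    masks = cv.masks()
    inner = np.full((n, nk, nc), np.inf)
    for f in range(n):
        Xtr = X[idx[f]]
        Ytr = Y.values[idx[f]]
        for ik, k in enumerate(cv.grid.nkeep_values):
            for ic, c in enumerate(cv.grid.ncomp_values):
                feats = masks[f, ik, ic]
                if not feats.any():
                    continue
                err = loo_sq_errors(Xtr[:, feats], Ytr, c, k)
                inner[f, ik, ic] = err.mean()
    opt = np.asarray(cv.grid.ncomp_values)[np.argmin(inner, axis=2)]
    cv.inner_msep = inner
    cv.inner_optimal_ncomp = opt
    return cv


# ---------------------------------------------------------------------------
# Step 3: outer-test MSEP matrix
# ---------------------------------------------------------------------------

def outer_test_msep(table: FeatureTable, cv: CvGridResult) -> np.ndarray:
    """Pooled held-out MSEP per grid cell, refitting on candidate features.

    For each cell and each outer fold the model is refitted on the outer
    training set restricted to that fold/cell's candidate set and predicts the
    held-out sample; errors pool over all folds and response columns.  Cells
    whose ``ncomp`` disagrees with the inner-optimal component count are still
    evaluated (the full matrix is needed for rank smoothing); the disagreement
    is tallied in ``contradiction_count`` as a diagnostic.
    """
    _require_scaled(table)
    n = table.n_samples
    Y = dummy_code(table.class_labels)
    X = table.values
    idx = loo_index_matrix(n)
    nk, nc = cv.grid.shape
    masks = cv.masks()
    sqerr = np.zeros((nk, nc, n))
    bad = np.zeros((nk, nc), dtype=bool)
    for f in range(n):
        Xtr = X[idx[f]]
        Ytr = Y.values[idx[f]]
        for ik, k in enumerate(cv.grid.nkeep_values):
            for ic, c in enumerate(cv.grid.ncomp_values):
                feats = masks[f, ik, ic]
                if not feats.any():
                    bad[ik, ic] = True
                    continue
                try:
                    model = fit_spls_da(
                        Xtr[:, feats], Ytr, c, k, class_order=cv.class_order
                    )
                except SplsError:
                    bad[ik, ic] = True
                    continue
                yhat, _ = predict(model, X[f, feats])
                sqerr[ik, ic, f] = ((yhat[0] - Y.values[f]) ** 2).mean()
    outer = sqerr.mean(axis=2)
    outer[bad] = np.inf
    if cv.inner_optimal_ncomp is not None:
        cvals = np.asarray(cv.grid.ncomp_values)
        # folds whose inner-optimal ncomp disagrees with the cell's ncomp
        disagree = cv.inner_optimal_ncomp[:, :, None] != cvals[None, None, :]
        cv.contradiction_count = disagree.sum(axis=0)
    cv.outer_msep = outer
    return outer


# ---------------------------------------------------------------------------
# Rank smoothing and selection
# ---------------------------------------------------------------------------

_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, 2.0, 1.0], [0.0, 1.0, 0.0]])


def rank_and_smooth(outer_msep: np.ndarray):
    """Rank the MSEP matrix ascending and smooth with the 3x3 cross kernel.

    Finite cells receive average ranks 1..N (ties averaged); non-finite
    (flagged) cells are assigned rank N+1 but are excluded both from the
    ranking and from their neighbors' kernel normalization, and their own
    smoothed score is ``+inf`` so they can never be selected.  Border cells
    normalize over the in-bounds kernel weights only, so a constant matrix is
    a fixed point of the smoother.
    """
    m = np.asarray(outer_msep, dtype=float)
    finite = np.isfinite(m)
    n_fin = int(finite.sum())
    if n_fin == 0:
        raise NestedCvError("all grid cells are flagged; nothing to rank")
    ranks = np.full(m.shape, float(n_fin + 1))
    ranks[finite] = rankdata(m[finite], method="average")
    num = ndimage.correlate(
        np.where(finite, ranks, 0.0), _KERNEL, mode="constant", cval=0.0
    )
    den = ndimage.correlate(
        finite.astype(float), _KERNEL, mode="constant", cval=0.0
    )
    smoothed = np.full(m.shape, np.inf)
    ok = finite & (den > 0)
    smoothed[ok] = num[ok] / den[ok]
    return ranks, smoothed


def select_optimal(smoothed_scores: np.ndarray, grid: Grid):
    """Grid cell with the lowest smoothed rank score.

    Exact ties resolve to the smaller ``ncomp``, then the smaller ``nkeep``
    (parsimony); the number of tied cells is returned for logging.
    """
    s = np.asarray(smoothed_scores, dtype=float)
    if not np.isfinite(s).any():
        raise NestedCvError("no finite smoothed score to select from")
    best = np.min(s)
    tied = np.argwhere(s == best)  # rows are (ik, ic)
    order = np.lexsort((tied[:, 0], tied[:, 1]))  # ncomp first, then nkeep
    ik, ic = tied[order[0]]
    return grid.nkeep_values[ik], grid.ncomp_values[ic], len(tied)


def aggregate_relevance(
    cv: CvGridResult,
    optimal: tuple,
    threshold: float = 1.0,
    op: str = ">=",
    feature_meta=None,
) -> pd.DataFrame:
    """Relevance table at the selected grid cell.

    Per feature: mean VIP across outer folds and the occurrence count (number
    of folds whose own VIP meets the threshold).  Rows whose mean VIP meets
    the threshold are kept, sorted by descending mean VIP.  ``op`` selects the
    comparison (``">="`` by default, ``">"`` available).
    """
    if op not in (">=", ">"):
        raise NestedCvError("op must be '>=' or '>'")
    ik = cv.grid.nkeep_values.index(optimal[0])
    ic = cv.grid.ncomp_values.index(optimal[1])
    v = cv.vips[:, ik, ic, :]  # (folds, p)
    mean_vip = v.mean(axis=0)
    meets = (v >= threshold) if op == ">=" else (v > threshold)
    occurrence = meets.sum(axis=0)
    keep = (mean_vip >= threshold) if op == ">=" else (mean_vip > threshold)
    rows = np.flatnonzero(keep)
    techniques = (
        feature_meta["technique"].reindex(cv.feature_names).fillna("unknown")
        if feature_meta is not None
        else pd.Series("unknown", index=cv.feature_names)
    )
    df = pd.DataFrame(
        {
            "feature": [cv.feature_names[j] for j in rows],
            "technique": [techniques.iloc[j] for j in rows],
            "mean_VIP": mean_vip[rows],
            "occurrence": occurrence[rows],
        }
    )
    df = df.sort_values(
        ["mean_VIP", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def nested_select(
    table: FeatureTable,
    grid: Grid | None = None,
    vip_threshold: float = 1.0,
    threshold_op: str = ">=",
):
    """Run the full three-step nested LOOCV and select the optimal model.

    Returns ``(CvGridResult, SelectionResult)``.  Deterministic: repeated
    calls on the same table are bit-identical.
    """
    grid = grid or Grid()
    cv = outer_vip_filter(table, grid)
    inner_tune_ncomp(table, cv)
    outer_test_msep(table, cv)
    ranks, smoothed = rank_and_smooth(cv.outer_msep)
    nkeep, ncomp, ties = select_optimal(smoothed, grid)
    relevance = aggregate_relevance(
        cv,
        (nkeep, ncomp),
        threshold=vip_threshold,
        op=threshold_op,
        feature_meta=table.feature_meta,
    )
    sel = SelectionResult(
        rank_matrix=ranks,
        smoothed_scores=smoothed,
        optimal_nkeep=nkeep,
        optimal_ncomp=ncomp,
        relevance_table=relevance,
        vip_threshold=vip_threshold,
        tie_count=ties,
    )
    return cv, sel
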