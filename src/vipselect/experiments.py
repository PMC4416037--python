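"""Reusable simulation experiments built on the synthetic generator.

These drive the calibration and recovery checks: a planted-signal recovery
run (does the pipeline's relevance table contain the features that truly
differ between classes?) and a null type-I-error calibration of the
univariate layer.
"""

from __future__ import annotations

import numpy as np

from .nested import Grid, nested_select
from .preprocess import log_center_scale
from .synthetic import SyntheticSpec, generate, planted_shifts
from .univariate import kruskal_wallis


def planted_recovery_run(
    seed: int,
    n_features: int = 200,
    n_informative: int = 10,
    shift: float = 2.5,
    grid: Grid | None = None,
    samples_per_class: tuple = (5, 5, 5, 5, 5),
) -> dict:
    """One planted-signal replicate: generate, select, score recovery.

    Uses a balanced five-class design of five samples each.  Returns the
    selected (nkeep, ncomp), the pooled outer MSEP at the selected cell, the
    relevance-table size and the fraction of planted features it recovered.
    """
    grid = grid or Grid(tuple(range(1, 31)), tuple(range(1, 5)))
    spec = SyntheticSpec(
        n_features=n_features,
        informative=planted_shifts(n_informative, shift),
        samples_per_class=samples_per_class,
        seed=seed,
    )
    table, truth = generate(spec)
    scaled = log_center_scale(table)
    cv, sel = nested_select(scaled, grid)
    ik = grid.nkeep_values.index(sel.optimal_nkeep)
    ic = grid.ncomp_values.index(sel.optimal_ncomp)
    found = set(sel.relevance_table["feature"]) & set(truth["informative_names"])
    return {
        "seed": seed,
        "optimal_nkeep": sel.optimal_nkeep,
        "optimal_ncomp": sel.optimal_ncomp,
        "outer_msep": float(cv.outer_msep[ik, ic]),
        "n_relevant": int(len(sel.relevance_table)),
        "recall": len(found) / n_informative,
        "n_informative": n_informative,
    }


def null_kw_type1_rate(
    seed: int, n_features: int = 2000, alpha: float = 0.05
) -> float:
    """Fraction of null features the Kruskal-Wallis test rejects at ``alpha``.

    Data are drawn with no planted shifts, so every rejection is a false
    positive; a calibrated test rejects about ``alpha`` of the features.
    """
    spec = SyntheticSpec(n_features=n_features, informative={}, seed=seed)
    table, _ = generate(spec)
    scaled = log_center_scale(table)
    rej = 0
    for j in range(n_features):
        _h, p = kruskal_wallis(scaled.values[:, j], scaled.class_labels)
        rej += p <= alpha
    return rej / n_features


def loo_baseline_sq_errors(Y: np.ndarray) -> np.ndarray:
    """Squared errors of the intercept-only (class-proportion) predictor.

    For each left-out sample the prediction is the mean dummy row of the
    remaining samples; the natural no-information reference for the MSEP.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    tot = Y.sum(axis=0)
    pred = (tot[None, :] - Y) / (n - 1)
    return (pred - Y) ** 2
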