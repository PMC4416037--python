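"""Feature-table I/O, abundance transformation, dummy coding and PCA sample QC.

A *feature table* holds relative abundances of metabolite features
(chromatography--mass-spectrometry signals, identified or unknown) measured
across biological samples: samples in rows, features in columns, plus one
categorical class label per sample (e.g. a temperament type).  Tables arrive
either raw (positive abundances, to be log-transformed and autoscaled here)
or already transformed upstream.

Sample-level quality control follows common metabolomics practice: a PCA of
the scaled table, with samples flagged as outliers when their score on one of
the leading components is extreme relative to the cohort (robust z-score on
median/MAD).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

TRANSFORM_STATES = ("raw", "log", "log_centered_scaled")
TECHNIQUES = ("GC-MS", "LC-MS", "unknown")

# Consistent with the Gaussian: 1/Phi^-1(3/4), turns a MAD into a sigma-like scale.
_MAD_TO_SD = 1.4826022185056018


class FeatureTableError(ValueError):
    """Raised on malformed feature tables or invalid transformation requests."""


@dataclasses.dataclass
class FeatureTable:
    """Sample x feature abundance matrix with labels and feature metadata.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    class_labels : list of str
        One categorical class label per sample.
    values : ndarray of shape (n_samples, n_features)
        Abundance matrix. Must be finite (missing values are rejected rather
        than imputed).
    feature_meta : DataFrame indexed by feature name
        Per-feature metadata; must contain a ``technique`` column with values
        in ``{"GC-MS", "LC-MS", "unknown"}``.
    transform_state : str
        One of ``raw``, ``log``, ``log_centered_scaled``.
    """

    sample_ids: list
    class_labels: list
    values: np.ndarray
    feature_meta: pd.DataFrame
    transform_state: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_labels = [str(c) for c in self.class_labels]
        if self.values.ndim != 2:
            raise FeatureTableError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise FeatureTableError(
                "sample_ids, class_labels and values row count must agree"
            )
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise FeatureTableError(f"duplicated sample ID: {dup!r}")
        names = list(self.feature_meta.index)
        if len(names) != p:
            raise FeatureTableError("feature_meta rows must match value columns")
        dup = _first_duplicate(names)
        if dup is not None:
            raise FeatureTableError(f"duplicated feature name: {dup!r}")
        if "technique" not in self.feature_meta.columns:
            self.feature_meta = self.feature_meta.assign(technique="unknown")
        bad = set(self.feature_meta["technique"]) - set(TECHNIQUES)
        if bad:
            raise FeatureTableError(f"unknown technique tags: {sorted(bad)}")
        if self.transform_state not in TRANSFORM_STATES:
            raise FeatureTableError(
                f"transform_state must be one of {TRANSFORM_STATES}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FeatureTableError(
                "values contain missing or non-finite cells; "
                "vipselect rejects missing data rather than imputing"
            )

    # -- convenience ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list:
        return list(self.feature_meta.index)

    @property
    def classes(self) -> list:
        """Distinct class labels in first-appearance order."""
        seen: dict = {}
        for c in self.class_labels:
            seen.setdefault(c, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def check_scaled(self, tol: float = 1e-8) -> None:
        """Verify the per-feature mean-0 / sample-SD-1 invariant.

        Raises :class:`FeatureTableError` when any column violates it beyond
        ``tol``. Pre-transformed files rounded to a few decimals satisfy the
        invariant only loosely, hence the configurable tolerance.
        """
        mu = self.values.mean(axis=0)
        sd = self.values.std(axis=0, ddof=1)
        bad = np.flatnonzero(
            (np.abs(mu) > tol) | (np.abs(sd - 1.0) > tol)
        )
        if bad.size:
            names = [self.feature_names[j] for j in bad[:5]]
            raise FeatureTableError(
                f"{bad.size} feature columns violate the mean-0/SD-1 invariant "
                f"at tolerance {tol:g} (first offenders: {names})"
            )

    def subset_samples(self, keep: Sequence[int]) -> "FeatureTable":
        keep = list(keep)
        return FeatureTable(
            [self.sample_ids[i] for i in keep],
            [self.class_labels[i] for i in keep],
            self.values[keep],
            self.feature_meta.copy(),
            self.transform_state,
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            list(self.sample_ids),
            list(self.class_labels),
            self.values[:, idx],
            self.feature_meta.loc[list(names)].copy(),
            self.transform_state,
        )


@dataclasses.dataclass
class DummyMatrix:
    """One-hot class-membership response block (the Y of the discriminant fit)."""

    values: np.ndarray  # (n_samples, n_classes), rows sum to 1
    class_order: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.class_order):
            raise FeatureTableError("dummy matrix shape must be n x n_classes")
        if not np.allclose(self.values.sum(axis=1), 1.0):
            raise FeatureTableError("each dummy row must sum to 1")
        if np.any(self.values.sum(axis=0) < 1):
            raise FeatureTableError("every class column needs at least one sample")


@dataclasses.dataclass
class QcReport:
    """PCA-based sample QC: leading scores, per-sample outlier flags, rule."""

    pc_scores: np.ndarray  # (n_samples, n_pcs)
    outlier_flags: np.ndarray  # bool per sample
    rule_params: dict
    sample_ids: list

    def to_json(self, path=None) -> str:
        payload = {
            "rule_params": self.rule_params,
            "samples": [
                {
                    "sample_id": sid,
                    "pc_scores": [float(v) for v in row],
                    "outlier": bool(flag),
                }
                for sid, row, flag in zip(
                    self.sample_ids, self.pc_scores, self.outlier_flags
                )
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    path,
    label_column: str | None = "type",
    delimiter: str = "\t",
    label_map: str | Path | None = None,
    transform_state: str = "raw",
    technique_map: dict | None = None,
) -> FeatureTable:
    """Read a delimited feature table (samples in rows, features in columns).

    Layout: header row of feature names, first column sample IDs, and either a
    ``label_column`` among the columns or a separate two-column
    ``label_map`` file (sample ID, class label). ``transform_state`` declares
    how the stored values were produced (files shipped already log-transformed
    and autoscaled should be read with ``transform_state="log_centered_scaled"``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dup = _first_duplicate(list(df.index))
    if dup is not None:
        raise FeatureTableError(f"duplicated sample ID in {path.name}: {dup!r}")

    if label_column is not None and label_column in df.columns:
        labels = df[label_column].astype(str).tolist()
        df = df.drop(columns=[label_column])
    elif label_map is not None:
        mapping = _read_label_map(label_map, delimiter)
        missing = [s for s in df.index if s not in mapping]
        if missing:
            raise FeatureTableError(
                f"label map lacks entries for samples: {missing[:5]}"
            )
        labels = [mapping[s] for s in df.index]
    else:
        raise FeatureTableError(
            f"label column {label_column!r} absent and no label map given"
        )

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            raise FeatureTableError(
                f"non-numeric cell in feature column {col!r}: {exc}"
            ) from None

    technique_map = technique_map or {}
    meta = pd.DataFrame(
        {"technique": [technique_map.get(c, "unknown") for c in df.columns]},
        index=list(df.columns),
    )
    return FeatureTable(list(df.index), labels, values, meta, transform_state)


def _read_label_map(path, delimiter):
    lm = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if lm.shape[1] < 2:
        raise FeatureTableError("label map needs two columns: sample ID, label")
    return dict(zip(lm.iloc[:, 0].astype(str), lm.iloc[:, 1].astype(str)))


def write_feature_table(
    table: FeatureTable, path, delimiter: str = "\t", label_column: str = "type"
) -> None:
    """Write a table in the same dialect ``read_feature_table`` consumes.

    Values are printed with 12 significant digits so a read/write round trip
    preserves them to that precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id" + delimiter + label_column)
        for name in table.feature_names:
            fh.write(delimiter + str(name))
        fh.write("\n")
        for sid, lab, row in zip(
            table.sample_ids, table.class_labels, table.values
        ):
            fh.write(str(sid) + delimiter + str(lab))
            for v in row:
                fh.write(delimiter + format(v, ".12g"))
            fh.write("\n")


# ---------------------------------------------------------------------------
# Transformation chain
# ---------------------------------------------------------------------------

def constant_features(table: FeatureTable) -> list:
    """Names of features whose column is constant (zero sample variance)."""
    sd = table.values.std(axis=0, ddof=1)
    return [table.feature_names[j] for j in np.flatnonzero(sd == 0)]


def drop_features(table: FeatureTable, names: Sequence[str]) -> FeatureTable:
    """Return a table without the named features (documented pre-filter for
    constant columns ahead of :func:`log_center_scale`)."""
    keep = [n for n in table.feature_names if n not in set(names)]
    return table.subset_features(keep)


def log_center_scale(table: FeatureTable, pseudo_count: float = 0.0) -> FeatureTable:
    """Natural log, per-feature mean-centering, unit-variance scaling.

    The standard autoscaling chain for abundance data: ``log(x + pseudo_count)``
    followed by column centering and division by the sample standard deviation
    (denominator n-1). Applying it twice is a hard error so a table can never
    be silently double-transformed.
    """
    if table.transform_state != "raw":
        raise FeatureTableError(
            f"log_center_scale expects a raw table, got {table.transform_state!r}"
        )
    if pseudo_count < 0:
        raise FeatureTableError("pseudo_count must be non-negative")
    shifted = table.values + pseudo_count
    if np.any(shifted <= 0):
        raise FeatureTableError(
            "non-positive abundances after pseudo-count; cannot log-transform"
        )
    logged = np.log(shifted)
    sd = logged.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [table.feature_names[j] for j in zero]
        raise FeatureTableError(
            "zero-variance features after log transform: "
            f"{names[:10]}{'...' if len(names) > 10 else ''}; "
            "drop them first (see constant_features/drop_features)"
        )
    scaled = (logged - logged.mean(axis=0)) / sd
    return FeatureTable(
        list(table.sample_ids),
        list(table.class_labels),
        scaled,
        table.feature_meta.copy(),
        "log_centered_scaled",
    )


def dummy_code(class_labels: Sequence[str]) -> DummyMatrix:
    """One-hot encode class labels, columns in first-appearance order."""
    labels = [str(c) for c in class_labels]
    order: dict = {}
    for c in labels:
        order.setdefault(c, len(order))
    if len(order) < 2:
        raise FeatureTableError(
            "at least two distinct classes are required for discrimination"
        )
    Y = np.zeros((len(labels), len(order)))
    for i, c in enumerate(labels):
        Y[i, order[c]] = 1.0
    return DummyMatrix(Y, list(order))


# ---------------------------------------------------------------------------
# PCA sample QC
# ---------------------------------------------------------------------------

def pca_outlier_qc(
    table: FeatureTable, n_pcs: int = 2, robust_z_cut: float = 5.0
) -> QcReport:
    """Flag outlier samples on the leading principal components.

    A PCA is run on the (scaled) sample x feature matrix; a sample is flagged
    when the robust z-score of its score -- (score - median) / (1.4826 * MAD)
    -- on any of the first ``n_pcs`` components exceeds ``robust_z_cut`` in
    absolute value.  The rule codifies the visual "extreme outlier on the score
    plot" practice deterministically; the default cut of 5 flags a sample whose
    score sits several cohort-widths outside the rest.
    """
    n, p = table.values.shape
    if n_pcs < 1:
        raise FeatureTableError("n_pcs must be >= 1")
    if n_pcs > min(n - 1, p):
        raise FeatureTableError(
            f"n_pcs={n_pcs} exceeds min(n_samples-1, n_features)={min(n - 1, p)}"
        )
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(table.values)
    flags = np.zeros(n, dtype=bool)
    for k in range(n_pcs):
        s = scores[:, k]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        scale = _MAD_TO_SD * mad
        if scale == 0:
            # Degenerate spread (most scores identical): fall back to the SD.
            scale = s.std(ddof=1)
            if scale == 0:
                continue
        flags |= np.abs(s - med) / scale > robust_z_cut
    return QcReport(
        pc_scores=scores,
        outlier_flags=flags,
        rule_params={
            "n_pcs": int(n_pcs),
            "robust_z_cut": float(robust_z_cut),
            "scale": "median/MAD (MAD x 1.4826)",
        },
        sample_ids=list(table.sample_ids),
    )
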