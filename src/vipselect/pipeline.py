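"""End-to-end orchestration: QC -> scaling -> nested selection -> confirmation.

``run_pipeline`` reproduces the full analysis flow on one feature table:
PCA-based sample QC with optional exclusion of flagged outliers, the
log/center/scale transformation (skipped, but verified, for tables declared
pre-transformed), the nested double-LOOCV grid selection, relevance
aggregation, univariate confirmation of the relevant features, and two-way
clustering.  Every stage writes a plain-text artifact under the configured
output prefix and every decision flag (ties, inner/outer contradictions,
excluded samples) lands in the machine-readable run summary.

Re-running an identical configuration byte-reproduces every output: nothing
in the procedure is randomized.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .nested import Grid, nested_select
from .preprocess import (
    FeatureTable,
    log_center_scale,
    pca_outlier_qc,
    read_feature_table,
)
from .spls import explained_y_variance, fit_spls_da
from .preprocess import dummy_code
from .univariate import feature_stats, plot_heatmap, two_way_cluster

log = logging.getLogger("vipselect")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name."""


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs; mirrors the CLI flags 1:1."""

    input_path: str
    out_prefix: str
    label_column: str = "type"
    label_map: str | None = None
    delimiter: str = "\t"
    pretransformed: bool = False
    pseudo_count: float = 0.0
    scale_check_tol: float = 1e-3
    qc_n_pcs: int = 2
    qc_robust_z_cut: float = 5.0
    exclude_outliers: bool = True
    nkeep: str = "1:100"
    ncomp: str = "1:10"
    vip_threshold: float = 1.0
    threshold_op: str = ">="
    alpha: float = 0.05
    heatmap: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and rethrow
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig, table: FeatureTable | None = None) -> dict:
    """Execute all stages; returns the run summary (also written as JSON).

    ``table`` may be passed directly (e.g. a synthetic table) instead of
    reading ``config.input_path``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    summary: dict = {"vipselect_version": __version__, "config": dataclasses.asdict(config), "flags": []}

    if table is None:
        table = _stage("read")(read_feature_table)(
            config.input_path,
            label_column=config.label_column,
            delimiter=config.delimiter,
            label_map=config.label_map,
            transform_state=(
                "log_centered_scaled" if config.pretransformed else "raw"
            ),
        )
    summary["n_samples_in"] = table.n_samples
    summary["n_features"] = table.n_features
    summary["classes"] = table.classes

    # ---- QC -----------------------------------------------------------
    qc_input = table
    if not config.pretransformed:
        # QC operates on the scaled table (see methods note); scale a copy.
        qc_input = _stage("qc-scale")(log_center_scale)(table, config.pseudo_count)
    qc = _stage("qc")(pca_outlier_qc)(
        qc_input, n_pcs=config.qc_n_pcs, robust_z_cut=config.qc_robust_z_cut
    )
    qc.to_json(f"{prefix}_qc.json")
    excluded = [
        sid for sid, f in zip(qc.sample_ids, qc.outlier_flags) if f
    ]
    summary["qc_excluded_samples"] = excluded
    if excluded:
        summary["flags"].append(f"QC excluded samples: {excluded}")
    if config.exclude_outliers and excluded:
        keep = [i for i, f in enumerate(qc.outlier_flags) if not f]
        table = table.subset_samples(keep)
        log.info("excluded %d outlier sample(s): %s", len(excluded), excluded)
    summary["n_samples_used"] = table.n_samples

    # ---- transformation ----------------------------------------------
    if config.pretransformed:
        _stage("scale-check")(table.check_scaled)(config.scale_check_tol)
        scaled = table
    else:
        scaled = _stage("scale")(log_center_scale)(table, config.pseudo_count)

    # ---- nested selection --------------------------------------------
    grid = Grid.from_ranges(config.nkeep, config.ncomp)
    cv, sel = _stage("nested-selection")(nested_select)(
        scaled, grid, config.vip_threshold, config.threshold_op
    )
    _write_grid_tsv(f"{prefix}_msep.tsv", cv.outer_msep, grid)
    _write_grid_tsv(f"{prefix}_smoothed.tsv", sel.smoothed_scores, grid)
    sel.relevance_table.to_csv(f"{prefix}_relevance.tsv", sep="\t", index=False)
    summary["selected"] = sel.summary()
    ik = grid.nkeep_values.index(sel.optimal_nkeep)
    ic = grid.ncomp_values.index(sel.optimal_ncomp)
    summary["outer_msep_at_selected"] = float(cv.outer_msep[ik, ic])
    summary["contradiction_count_at_selected"] = int(
        cv.contradiction_count[ik, ic]
    )
    if sel.tie_count > 1:
        summary["flags"].append(
            f"{sel.tie_count} grid cells tied at the minimum smoothed score"
        )

    # ---- final classification model ----------------------------------
    Y = dummy_code(scaled.class_labels)
    final = _stage("final-fit")(fit_spls_da)(
        scaled.values, Y, sel.optimal_ncomp, sel.optimal_nkeep
    )
    _per, cum = explained_y_variance(final)
    summary["explained_y_variance"] = float(cum[-1])
    final.to_json(f"{prefix}_model.json")

    # ---- univariate confirmation -------------------------------------
    relevant = list(sel.relevance_table["feature"])
    if relevant:
        stats_df = _stage("univariate")(feature_stats)(
            scaled, relevant, alpha=config.alpha
        )
        stats_df.to_csv(f"{prefix}_stats.tsv", sep="\t", index=False)
        summary["kw_significant"] = int(
            (stats_df["KW_p"] <= config.alpha).sum()
        )
        wmw_cols = [c for c in stats_df.columns if c.startswith("WMW_p[")]
        summary["wmw_any_significant"] = int(
            (stats_df[wmw_cols] <= config.alpha).any(axis=1).sum()
        )
        cluster = _stage("clustering")(two_way_cluster)(scaled, relevant)
        summary["cluster_flags"] = cluster.flags
        if config.heatmap:
            _stage("heatmap")(plot_heatmap)(
                scaled, cluster, f"{prefix}_heatmap.png", relevant
            )
    else:
        summary["kw_significant"] = 0
        summary["wmw_any_significant"] = 0
        summary["flags"].append("relevance table empty; univariate stage skipped")

    Path(f"{prefix}_run.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _write_grid_tsv(path, matrix, grid: Grid):
    with open(path, "w") as fh:
        fh.write("nkeep\\ncomp")
        for c in grid.ncomp_values:
            fh.write(f"\t{c}")
        fh.write("\n")
        for ik, k in enumerate(grid.nkeep_values):
            fh.write(str(k))
            for ic in range(len(grid.ncomp_values)):
                v = matrix[ik, ic]
                fh.write("\t" + (format(v, ".10g") if np.isfinite(v) else "inf"))
            fh.write("\n")
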