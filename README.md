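# vipselect

Sparse PLS-DA feature selection for untargeted metabolite profiling tables.

## The problem

Untargeted GC-MS / LC-MS profiling yields hundreds to thousands of metabolite
features measured on a small number of biological samples — for example ~24
animals spread over five temperament-type classes.  The question is which few
features actually discriminate the classes.  With *p* ≫ *n*, ordinary
discriminant analysis overfits, so `vipselect` implements the sparse partial
least squares discriminant analysis (sPLS-DA) workflow used in exploratory
metabolomics:

1. **Preprocessing** — log transform, per-feature mean centering and unit
   variance scaling; one-hot (dummy block) coding of the class response *Y*;
   PCA-based sample QC with a deterministic robust-z outlier rule.
2. **sPLS-DA** — PLS regression of *Y* on *X* extracting components
   *t<sub>h</sub> = X w<sub>h</sub>* one at a time, where each loading-weight
   vector *w<sub>h</sub>* keeps only the `nkeep` largest-magnitude entries
   (hard selection + renormalization); X and Y are deflated in regression
   mode.  Per-feature relevance is summarized by Wold's VIP,
   *VIP<sub>j</sub> = √(p · Σ<sub>h</sub> SSY<sub>h</sub> w<sub>jh</sub>² / Σ<sub>h</sub> SSY<sub>h</sub>)*,
   which satisfies mean(VIP²) = 1.
3. **Nested double leave-one-out cross-validation** over the grid
   `nkeep` × `ncomp` (defaults 1..100 × 1..10): an outer LOOCV filters
   features by nonzero VIP, an inner LOOCV (within each outer training set)
   tunes the component count by the mean squared error of prediction (MSEP)
   on the dummy scale, and the outer held-out samples give a pooled MSEP per
   grid cell.  The MSEP matrix is ranked ascending and smoothed with the 3×3
   cross kernel ((0,1,0),(1,2,1),(0,1,0)) (normalized over in-bounds
   neighbors); the cell with the lowest smoothed rank score wins.
4. **Relevance table** — features whose mean VIP across the outer folds at
   the selected cell is ≥ 1, with an occurrence count of folds individually
   reaching the threshold.
5. **Confirmation** — per-feature Kruskal-Wallis and pairwise two-sided
   Wilcoxon-Mann-Whitney tests (exact enumeration at the small group sizes
   typical here), plus two-way hierarchical clustering for the heatmap.

The procedure is fully deterministic: LOOCV folds are exhaustive and nothing
is randomized.

A synthetic-data generator (`vipselect.synthetic`) emulates the assumed data
structure — log-normal abundances, five classes of ~5 samples, a planted set
of class-discriminative features with configurable effect sizes and optional
feature equicorrelation — so every stage is testable without the original
study data.

## Worked example

```bash
vipselect simulate --seed 7 --n-features 200 --n-informative 10 \
    --out table.tsv --truth truth.json
vipselect pipeline --input table.tsv --out run --nkeep 1:30 --ncomp 1:4
```

The pipeline prints the selection summary (output of an actual run):

```
{"optimal_nkeep": 8, "optimal_ncomp": 4, "n_relevant": 28,
 "vip_threshold": 1.0, "smoothed_score_min": 6.8, "tie_count": 1}
```

meaning the smoothed-rank criterion chose 8 variables per component and 4
components, and 28 features had mean VIP ≥ 1 across the outer folds — the
candidate discriminators.  `run_relevance.tsv` lists them with technique tag,
mean VIP and occurrence count; `run_msep.tsv` / `run_smoothed.tsv` hold the
grid matrices; `run_stats.tsv` the univariate confirmation; `run_qc.json`
the PCA outlier report; `run_run.json` the full machine-readable summary.

The same analysis runs on an already-transformed published table
(`--pretransformed` verifies the scaling invariant instead of re-scaling):

```bash
vipselect pipeline --input cortex.tsv --out cortex --pretransformed
```

Library use mirrors the CLI: `generate`, `log_center_scale`,
`nested_select`, `feature_stats`, `run_pipeline`.

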