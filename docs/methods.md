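# Methods

## Model and procedure

`vipselect` addresses multi-class discrimination of a small cohort (n ≈ 25)
described by a wide metabolite-feature matrix (p in the hundreds to
thousands).  The classifier is sparse PLS in regression mode against the
dummy-coded class matrix Y (one column per class, rows one-hot).  Components
are extracted sequentially: at step h the cross-covariance matrix
M = X<sub>h</sub>ᵀY<sub>h</sub> of the current residuals is formed, the
dominant pair (u, v) is found by power iteration started from the exact
dominant right singular vector of M (computed from the K×K Gram matrix), and
at every iteration the X-weight u is hard-thresholded to its `nkeep`
largest-magnitude entries and renormalized.  Hard selection realizes the
adaptive soft threshold at exactly the level that keeps `nkeep` variables,
which matches the "number of kept variables" semantics of the tuning grid.
Magnitude ties at the selection boundary keep the lower feature index
(stable sort), making the fit deterministic.  Scores t = X<sub>h</sub>u,
loadings p = X<sub>h</sub>ᵀt/tᵀt and response weights c = Y<sub>h</sub>ᵀt/tᵀt
follow; both blocks are deflated by the rank-one component (regression
mode).  Y-weights are dense; a single `nkeep` is shared by all components.
With `nkeep = p` the algorithm reduces exactly to dense PLS2 — the test
suite verifies agreement with an independent textbook NIPALS implementation
and with scikit-learn's `PLSRegression` to 1e-8.

Prediction uses the assembled coefficients B = W(PᵀW)⁻¹Cᵀ on training-
centered data; class assignment is the argmax over predicted dummy columns
(maximum-distance rule), with exact ties resolving to the lowest class
index.  This is the simplest rule consistent with using the dummy-scale MSEP
as the tuning criterion.

VIP is Wold's statistic over the fitted components with SSY<sub>h</sub> =
(tᵀt)(cᵀc); because weight columns are unit-norm, mean(VIP²) = 1 exactly,
and features outside every kept set have VIP 0.

## Nested double leave-one-out cross-validation

Step 1 holds out each sample once; on each outer training set the sparse fit
is computed for every `nkeep` at the deepest requested `ncomp` (sequential
extraction means the shallower models are prefixes, so each `nkeep` needs
one fit per fold), and per-cell VIPs and nonzero-VIP candidate masks are
recorded.  Step 2 runs a second exhaustive LOOCV inside each outer training
set, restricted per cell to that fold's candidate mask, and records the
pooled inner MSEP and the per-`nkeep` MSEP-minimizing `ncomp` (ties to the
smaller value).  Step 3 refits on each outer training set (again restricted
to the fold/cell mask — each fold uses its own mask rather than a cross-fold
union, the more literal reading of a per-fold filter) and predicts the held-
out sample, pooling squared errors into the `nkeep` × `ncomp` MSEP matrix.
The full matrix is computed even where a cell's `ncomp` disagrees with the
inner-optimal one, because the smoothing step needs the complete surface;
disagreements are tallied per cell as a diagnostic rather than collapsing
the matrix.

MSEPs are ranked ascending with average ranks for ties; the rank matrix is
convolved with the cross kernel ((0,1,0),(1,2,1),(0,1,0)), each position
normalized by the sum of in-bounds kernel weights so borders are unbiased
and a constant matrix is a fixed point.  Cells that could not be evaluated
(empty candidate set, unfittable model) carry rank N+1, are excluded from
their neighbors' normalization, and get an infinite smoothed score so they
can never win.  The minimum smoothed score selects the model; exact ties
prefer the smaller `ncomp`, then the smaller `nkeep` (parsimony), and the
tie count is logged.

Relevance: mean VIP across outer folds at the selected cell, kept at ≥ 1 by
default.  The occurrence column counts folds whose own VIP reaches the
threshold — counting threshold crossings rather than nonzero VIPs is what
produces informative sub-maximal occurrence values once `nkeep` is large
enough that selected features are nonzero in nearly every fold.  The
comparison operator is configurable (≥ vs >); ≥ is the default as the
procedural definition.

Inner training sets have n−2 samples while the default grid requests up to
10 components, so deep cells can be rank deficient: fits stop early at
numerical rank deficiency, record the achieved depth, and the cell reuses
the deepest achievable model with the event flagged.

## Univariate layer

Kruskal-Wallis uses the tie-corrected H referred to chi-square with k−1
degrees of freedom (the convention behind the reported p-values); an exact
enumeration mode over all distinct group assignments is available for
total n ≤ 12 and is validated against full-permutation oracles.  Pairwise
Wilcoxon-Mann-Whitney tests are two-sided; for combined n ≤ 12 the p-value
is computed by exact enumeration of all C(n, n₁) assignments using midranks,
which handles ties correctly (the U distribution is symmetric about
n₁n₂/2 under exchangeability, so the two-sided p counts |U − n₁n₂/2| at
least as extreme).  Larger pairs use the normal approximation with tie and
continuity correction; each pair's mode is reported.  P-values are nominal
by design; a Benjamini-Hochberg column is emitted for information only and
never used for selection.  Two-way clustering uses Euclidean distance with
Ward linkage (the common default for autoscaled abundance heatmaps; the
choice is configurable).

## Sample QC

QC PCA operates on the scaled table (for pre-scaled published tables the
covariance/correlation distinction vanishes; for raw synthetic data scaling
first keeps the rule comparable across features).  A sample is flagged when
the robust z-score (median/MAD, MAD × 1.4826) of its score on any of the
first `n_pcs = 2` components exceeds 5.  This codifies the "extreme outlier
on the score plot" judgement deterministically: a sample several
cohort-widths outside the rest (e.g. a score of ~64 against a cohort range
of ±14) is flagged, while homogeneous Gaussian cohorts of this size are
flagged in well under 5% of cases (verified by simulation).  A zero MAD
falls back to the standard deviation.

## Synthetic generator

Log-abundances are Gaussian: mean `base_log_mean = 5.0` (arbitrary
abundance units on the log scale; only differences matter after
autoscaling), SD `base_log_sd = 1.0`, optional equicorrelation rho via a
shared per-sample factor, exponentiated to positive raw abundances so the
log-transform step of the pipeline is meaningful.  Informative features add
class-specific mean shifts in SD units; the stock pattern shifts feature i
in class i mod K only, emulating metabolites elevated in a single
temperament type.  The default design is five classes sized (5, 5, 5, 5, 4)
— mirroring a post-QC cohort with one reduced class and exercising
unbalanced folds — while the recovery experiments use the balanced 5 × 5
design.  The generator does not model chromatography artifacts, missingness,
batch effects or technique-specific intensity differences, so passing
recovery tests demonstrate statistical behavior under the assumed model,
not robustness to real acquisition noise.

## Problem sizes and numerical choices

The shipped experiments run at 200 features, 24–25 samples and a reduced
grid of `nkeep` 1..30 × `ncomp` 1..4 — large enough to exhibit the p ≫ n
regime and the selection behavior, small enough that a replicate of the
full nested procedure completes in tens of seconds; the full 100 × 10
default grid on a published-scale table is supported and simply takes
proportionally longer.  Cross-validation refits are executed as batched
stacks of fold-wise problems (one numpy slice per fold) that the test suite
pins slice-by-slice to the reference single fit.  Convergence of the sparse
power iteration is declared at a sign-aligned weight change below 1e-12
(cap 500 iterations); rank deficiency at tᵀt below (1e-10 · ‖X‖)².  The
estimator centers X and Y internally and stores the means, so CV refits on
row subsets of a scaled table are handled exactly.

## Known limitations

Exact reproduction of third-party VIP/MSEP values depends on matching the
conventions of the original sPLS-DA implementation (deflation mode,
threshold style, tie handling); agreement is expected to printed precision
for structure and to small tolerances for error statistics.  The exact
univariate modes are exponential in n and guarded accordingly.  Occurrence
counts are defined at the selected cell only; no stability selection across
cells is attempted.
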