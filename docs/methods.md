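# Methods

This note documents the models implemented in `longidecomp`, the assumptions
behind them, the defaults that matter, and what the synthetic benchmarks do
and do not demonstrate.

## Generative model for synthetic cohorts

The generator (`longidecomp.synth`) emulates a prospective repeated-measures
design: `n_subjects` subjects observed at an ordered subset of
{T0, T1, T2, T3, PP3, PP6, PP9}.  Observed counts arise from a cell-type
mixture:

- **Signature.** A genes × cell-types matrix S on the linear scale with
  log-normal background expression (log-mean log 5, log-sd 1.2) and
  `markers_per_type` designated marker genes per type, set to `marker_fold`
  times the gene's maximum across the other types.  Default
  `marker_fold = 50`: immune signature matrices (LM22-style) show strong
  marker specificity, and markers must be specific enough that a doubling of
  a cell type's proportion is visible as roughly a doubling of its markers'
  bulk expression.
- **Composition trajectories.** Each subject draws a baseline composition
  from Dirichlet(α); per timepoint, the baseline's additive-log-ratio (ALR)
  coordinates (reference = last type) are shifted by configured amounts and
  mapped back to the simplex.  This keeps rows exactly on the simplex and
  preserves subjects' rank ordering.  The default α =
  (6, 14, 10, 8, 7, 6, 5, 4) over eight types puts the shifted
  neutrophil-like type near 10% at baseline with realistic between-subject
  spread; the default shift schedule (+0.6, +0.85, +1.0 at T1–T3, 0 at PP3)
  roughly doubles that type during pregnancy and reverts it postpartum,
  mirroring the expansion-and-reversion pattern reported for neutrophils in
  pregnancy.
- **Counts.** With p the sample's composition and share_g the gene's
  fraction of the raw mixture Σ_c p_c S_gc,

      μ_{g,i,t} = N_{i,t} · exp(b_{g,i}) · exp(ρ_{g,t}) · share_{g,i,t}

  where N is the target library size (log-normal, mean 2 × 10⁶, CV 0.2 —
  desk-scale libraries keeping full runs fast while leaving counts deep
  enough for NB asymptotics), b_{g,i} ~ N(0, τ²) is a gene-by-subject random
  effect inducing within-subject correlation (τ = 0.3, a free knob: the
  within-subject correlation of such cohorts is not pinned down by published
  summaries; 0.3 gives intra-class correlations typical of repeated-measures
  expression data), and ρ_{g,t} is the planted regulation effect
  (ρ_{g,T0} = 0).  Counts are negative binomial with variance μ + φ_g μ²,
  φ_g log-uniform on [0.01, 0.5].  Regulated genes (5% by default, signs
  random) ramp to |ρ| = ln 4 over the trimesters (0.5/0.8/1.0 of full size at
  T1/T2/T3) and revert to 0 postpartum.  Ages are N(28.9, 1.0) truncated
  above 18 and parity is drawn 7:6:1 over {0, 1, 2}, matching the cohort
  the design emulates.

**Truth labels.** A gene is *composition* iff it is a marker of a type whose
trajectory is materially non-constant and carries no ρ; *regulation* iff
ρ ≠ 0 and it is not such a marker; *mixed* iff both; *null* otherwise.
"Materially non-constant" uses a proportion fold-change threshold (median
|log(p_t/p_T0)| > log 1.5 at some timepoint): shifting one type moves every
other type slightly through simplex renormalization, and those passive moves
(typically < 15%) cannot surface as two-fold marker expression changes, so
they are not counted as planted composition effects.  The labels are pure
functions of signature, trajectories and plan, and are recomputed and
checked in the tests.

**What the generator does not emulate:** sequencing artifacts (GC/length
bias, batch), cell-type-specific regulation (regulation is a global
multiplicative effect per gene-timepoint, which is what bulk data can
identify), isoforms, and any sequence content.  Passing recovery benchmarks
therefore shows the statistical machinery is correct under the mixture
model, not that real cohorts satisfy that model.

## Preprocessing

Biotype filtering removes the default set {rRNA, pseudogene, misc_RNA,
Mt_tRNA, scaRNA, snRNA, snoRNA, TEC}.  The low-expression rule keeps genes
with raw CPM > 10/L in ≥ 8 samples (L = minimum library size in millions);
raw (pre-normalization) CPM is used deliberately, since filtering precedes
normalization.  TMM factors follow the published definition: reference =
sample whose 75th-percentile CPM is closest to the mean; per sample,
log-ratios M and average abundances A over genes positive in both samples;
double trimming (30% of M, 5% of A, per tail, by rank); factor =
2^(Σ wM/Σ w) with inverse delta-method variance weights; factors rescaled to
geometric mean 1.  Zeros are excluded from M/A rather than
continuity-corrected.  Fewer than 10 surviving genes triggers a logged
fallback to factor 1.  Log-CPM uses a prior count (0.5) scaled by effective
library size so the transform does not reintroduce depth effects.

## Deconvolution and composition covariates

Proportions are estimated per sample by NNLS over the genes shared between
bulk and signature.  Columns of S and the bulk vector are z-scored before
solving (stabilizes the fit across expression scales); the coefficients are
mapped back to the linear scale by dividing by each column's sd and then
renormalized to the simplex, which makes noiseless mixtures of signature
columns recoverable exactly and the estimate invariant to the bulk scale.
A zero solution falls back to uniform proportions with a warning.

Composition PCs come from an SVD of the column-centered proportions.  A PC
becomes a covariate when, regressing each gene's log-CPM on that PC alone,
more than 5% of genes reach BH FDR < 0.05 — one concrete operationalization
of "associated with genome-wide expression"; both numbers are config knobs.

## The longitudinal GEE screen

Counts for one gene are modeled marginally: log link, linear predictor =
intercept + timepoint indicators (baseline reference) + centered age
(+ parity, + selected PCs), offset ln(N_k f_k).  The variance function is
μ + αμ² with the method-of-moments dispersion
α̂ = max(0, Σ((y−μ̂)² − μ̂)/Σμ̂²) estimated once from an initial independence
fit and then held fixed — at 14 clusters, jointly iterating α with β is
unstable, and the moment form also absorbs the marginal variance inflation
from the subject random effect.  The estimating equation
Σ D'V⁻¹(y − μ) = 0 is solved by Fisher scoring to ‖Δβ‖∞ < 1e-8 (cap 100
iterations); the exchangeable working correlation, when requested, is the
usual standardized-residual cross-product moment estimator clamped to
(−1/(max cluster − 1), 0.99).  Inference uses the sandwich covariance
B⁻¹MB⁻¹.

**Joint test reference distribution.** The screen's statistic is the joint
Wald W over the timepoint coefficients.  With K clusters, M is estimated
from only K score vectors, and referring W to χ²_df is badly anticonservative
for joint tests at K ≈ 14 (measured null rejection 0.22–0.28 at nominal
0.05 — exactly what the Hotelling T² distribution of W predicts).  The
default therefore refers W·(K−df)/(df·(K−1)) to F(df, K−df), the standard
small-cluster practice; this brings the null rejection rate to 0.06–0.08 at
the cohort's size.  The plain χ² reference remains available
(`reference="chisq"`), and the sandwich estimator itself is unmodified.
Genes that fail to converge are flagged and excluded from the BH correction.

## Mechanism classification and reversion

A gene is called pregnancy-associated when q < 0.05 and the maximum
|log2FC| over T1–T3 is ≥ 1 (boundary counts as a pass; fold changes are the
GEE timepoint coefficients divided by ln 2, keeping adjusted and unadjusted
variants commensurable).  The max-over-trimesters gate is one of two
defensible readings of a per-trimester rule; per-timepoint flags are
retained so the other is recomputable.  Set algebra over the paired screens
yields the class partition.  PP3-versus-T3 contrasts come from releveling
the timepoint factor to T3, not from differencing fold changes — identical
point estimates, exact tests.

A caveat worth stating: a gene under genuine regulation has a real marginal
time effect and is therefore significant in *both* screens, landing in
"mixed".  The "regulation" label (adjusted-only) captures genes whose
association is *masked* until composition variation is adjusted away.  On
synthetic cohorts with strong planted effects, masking is rare, so the
4-way truth-versus-predicted balanced accuracy saturates around 0.55–0.6
(truth-regulation genes are recovered, but as "mixed"); detection of
regulated genes by the adjusted screen — the scientifically operative
quantity — runs at ~0.83 sensitivity under the default conditions.

## Co-expression modules

Biweight midcorrelation: points weighted by (1−u²)²·1[|u|<1] around the
median with u = (x−med)/(9·mad); each tail is rescaled so at most
`max_p_outliers` (default 0.1) of points per side are fully down-weighted —
an implementation of side-specific outlier capping that is approximate with
respect to the WGCNA original.  Zero-MAD genes fall back to Pearson (logged).
Signed-hybrid adjacency cor^β (β = 5) zeroes negative correlations; TOM
follows the standard shared-neighbor formula.  Modules come from
average-linkage clustering of 1−TOM with a *static* cut (default height
0.995, minimum size 30) — a deliberate simplification of dynamic tree
cutting that keeps the stage dependency-free and testable; the cut height is
exposed in config.  Eigengenes are the first right-singular vector of the
standardized module submatrix (sign fixed positive against members); module
pairs with eigengene dissimilarity 1−r < 0.25 are merged iteratively,
closest pair first.  Labels use the conventional color ordering by
decreasing size, "grey" = unassigned.  The default module universe is all
analyzed genes (config may restrict to adjusted-screen significant genes).

## Enrichment

One-sided hypergeometric over-representation only (k = 0 gives p = 1
exactly; otherwise the upper tail is an exact pmf summation), fold =
(k/n)/(K/N), BH across sets, deterministic (p, name) ordering.  The default
universe is the filtered gene space used by the screens; the choice of
universe is configurable because it materially changes p-values.

## Numerical choices and degenerate inputs

Linear predictors are clipped to ±30 before exponentiation; NB draws use
size 1/φ.  Singular estimating-equation or covariance matrices set the
convergence flag and propagate missing p-values.  Empty gene lists, constant
bulk profiles, constant proportion matrices, all-grey module assignments and
sub-minimum reversion gene sets all degrade to warnings plus well-defined
empty/NaN outputs rather than errors.  All randomness flows through
numpy `default_rng` seeds recorded in the run manifest; identical seeds give
bit-identical output tables.

## Benchmark problem sizes

The default cohort is 14 subjects × 5 timepoints × 2,000 genes × 8 cell
types — a desk-scale analog of a 14-subject, 22-cell-type study that keeps a
full pipeline run around 15 seconds and the complete test suite under two
minutes.  Null calibration uses a 500-gene global-null cohort; mechanism
recovery averages 5 cohorts with a +1.0 ALR shift on the neutrophil-like
type and ln 4 regulation effects; module recovery uses two planted 60-gene
blocks over 40 samples.

## Known limitations

- The NB-GEE uses the basic sandwich; no bias-corrected (Mancl–DeRouen
  style) small-sample covariance adjustments are provided, only the F
  reference for the joint test.
- NNLS deconvolution assumes the signature spans the mixture; unmodeled cell
  types bias proportions toward the nearest modeled ones.
- PC adjustment can absorb genuine regulation signal when many regulated
  genes co-vary with composition estimates (deconvolution is performed on
  the same bulk data), slightly attenuating adjusted-screen effects.
- Static tree cutting yields coarser modules than dynamic cutting on
  real-data dendrograms.
- Age enters linearly; timepoints are categorical with no spline smoothing.
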