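# longidecomp

Decompose longitudinal whole-blood gene expression changes into shifts in
**cell-type composition** versus **transcriptional regulation**.

## The problem

Repeated-measures bulk RNA-seq of whole blood — for example a prospective
pregnancy cohort sampled at a pre-pregnancy baseline (T0), each trimester
(T1–T3) and postpartum (PP3) — shows sweeping expression changes over time.
Bulk expression, however, is a mixture over cell types: a gene's measured
level can move because the cells expressing it become more or less abundant,
or because the gene is genuinely up- or down-regulated within cells.
`longidecomp` implements the full analysis that separates the two
mechanisms, for statisticians and computational biologists working with
small longitudinal cohorts (tens of subjects, a handful of timepoints):

1. **Preprocessing** — biotype and low-expression filtering
   (keep genes with CPM > 10/L in ≥ 8 samples, L = minimum library size in
   millions), then trimmed-mean-of-M-values (TMM) normalization factors.
2. **Deconvolution** — per-sample cell-type proportions by nonnegative
   least squares against a user-supplied signature matrix; proportions
   summarized by PCA, with expression-associated PCs selected as model
   covariates.
3. **Longitudinal screen** — per gene, a generalized estimating equation
   (GEE) with log link, negative-binomial variance v(μ) = μ + αμ²,
   independence or exchangeable working correlation, offset
   ln(library size × TMM factor), and robust sandwich covariance
   B⁻¹MB⁻¹.  A joint Wald test over the timepoint coefficients (Hotelling
   F reference at small cluster counts) is BH-corrected across genes.
4. **Mechanism classification** — a gene is pregnancy-associated when
   FDR < 0.05 and some trimester shows |log2FC| ≥ 1 versus baseline.
   Comparing calls from the unadjusted and composition-adjusted screens
   partitions genes into *composition* (unadjusted only), *regulation*
   (adjusted only), *mixed* (both) and *none*; the releveled screen
   (T3 baseline) measures how changes revert postpartum.
5. **Co-expression and enrichment** — biweight midcorrelation
   (maxPOutliers = 0.1), signed-hybrid adjacency (power β = 5), topological
   overlap, average-linkage module detection and eigengene merging
   (cut 0.25), plus generic hypergeometric over-representation of gene
   lists in GMT collections.

Because raw cohorts of this design are rarely shareable, the package ships a
first-class synthetic-cohort generator (`longidecomp.synth`) with known
composition trajectories and planted per-gene regulation effects, so every
stage can be validated against ground truth.

## Worked example

```python
from longidecomp import deconv, effects, gee, preprocess
from longidecomp.config import PipelineConfig
from longidecomp.pipeline import simulate_cohort

cfg = PipelineConfig(seed=1)            # 14 subjects, T0..PP3, 2000 genes
signature, comps, plan, counts, meta, truth = simulate_cohort(cfg)
filtered = preprocess.filter_low_expression(counts)
factors  = preprocess.tmm_factors(filtered)
cpm      = preprocess.cpm_normalized(filtered, factors)
log_cpm  = preprocess.cpm_normalized(filtered, factors, log=True)

est  = deconv.estimate_proportions(cpm, signature.values)
pcs  = deconv.proportion_pcs(est)
keep = deconv.select_pcs(pcs, log_cpm)

screen_u = gee.run_screen(filtered, factors, meta)
screen_a = gee.run_screen(filtered, factors, meta, pcs=pcs.scores.iloc[:, list(keep)])
mech = effects.classify_mechanism(
    effects.call_pregnancy_associated(screen_u),
    effects.call_pregnancy_associated(screen_a),
)
print(mech["class"].value_counts())
```

Output (seed 1):

```
class
none           1865
mixed            92
composition      34
regulation        9
```

Most pregnancy-associated calls disappear once the composition PCs enter the
model — they were driven by the expanding neutrophil-like population — while
the genes carrying planted regulation effects stay significant.  Re-fitting
with a T3 baseline gives the postpartum reversion correlation:

```
reversion: Pearson r = -0.991 over 116 PP3-significant genes
```

i.e. T3→PP3 changes almost exactly undo the T0→T3 changes.  The scripts in
`examples/` walk through each capability (`simulate_cohort.py`,
`deconvolve_proportions.py`, `screen_and_classify.py`,
`coexpression_modules.py`, `gene_set_enrichment.py`) and print annotated
numbers like the above.

The end-to-end driver writes every table plus a reproducibility manifest:

```bash
longidecomp run --seed 42 --outdir out/        # or: longidecomp simulate/screen/...
```

## Layout

```
src/longidecomp/   synth, preprocess, deconv, gee, effects, enrich,
                   coexpr, io, config, pipeline, evaluate, cli
tests/             unit, property and acceptance suites
examples/          narrative scripts, one per capability
docs/methods.md    model, assumptions, parameter choices, limitations
```
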