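"""Run the paired longitudinal screens and classify each gene's mechanism.

Every gene is tested for association with the timepoint factor by a
negative-binomial-variance GEE with robust (sandwich) inference, once without
and once with the composition PCs as covariates.  Comparing the two call sets
separates genes driven by shifting cell proportions from genes under
transcriptional regulation; a releveled screen (T3 baseline) quantifies how
pregnancy changes revert postpartum.
"""

from longidecomp import deconv, effects, gee, preprocess
from longidecomp.config import PipelineConfig
from longidecomp.pipeline import simulate_cohort

cfg = PipelineConfig(seed=1)
signature, compositions, plan, counts, metadata, truth = simulate_cohort(cfg)
filtered = preprocess.filter_low_expression(counts)
factors = preprocess.tmm_factors(filtered)
cpm = preprocess.cpm_normalized(filtered, factors)
log_cpm = preprocess.cpm_normalized(filtered, factors, log=True)

est = deconv.estimate_proportions(cpm, signature.values)
pcs = deconv.proportion_pcs(est)
selected = deconv.select_pcs(pcs, log_cpm)
pc_scores = pcs.scores.iloc[:, list(selected)]

screen_u = gee.run_screen(filtered, factors, metadata)
screen_a = gee.run_screen(filtered, factors, metadata, pcs=pc_scores)
calls_u = effects.call_pregnancy_associated(screen_u)
calls_a = effects.call_pregnancy_associated(screen_a)
print(f"pregnancy-associated (FDR<0.05, FC>=2): "
      f"{int(calls_u['flagged'].sum())} unadjusted, "
      f"{int(calls_a['flagged'].sum())} adjusted")

mech = effects.classify_mechanism(calls_u, calls_a)
print("\nmechanism classes (unadjusted vs adjusted call algebra):")
print(mech["class"].value_counts().to_string())
print("-> most calls disappear after composition adjustment, i.e. they were")
print("   driven by the expanding neutrophil-like population")

print("\ngenes first flagged per trimester (unadjusted):")
print(effects.venn_counts(calls_u).to_string(index=False))

screen_t3 = gee.run_screen(filtered, factors, metadata, baseline="T3")
r, n = effects.reversion_correlation(screen_u, screen_t3)
print(f"\nreversion: Pearson r = {r:.3f} over {n} PP3-significant genes")
print("-> strong anti-correlation: postpartum changes undo pregnancy changes")
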