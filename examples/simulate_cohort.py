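"""Generate a longitudinal whole-blood cohort with known ground truth.

Fourteen subjects are sampled at a pre-pregnancy baseline (T0), each
trimester (T1-T3) and three months postpartum (PP3).  A neutrophil-like cell
type expands during pregnancy and reverts postpartum; 5% of genes carry a
planted transcriptional-regulation effect.  The truth ledger records which
mechanism drives each gene, enabling recovery benchmarks downstream.
"""

from longidecomp.config import PipelineConfig
from longidecomp.pipeline import simulate_cohort

cfg = PipelineConfig(seed=1)
signature, compositions, plan, counts, metadata, truth = simulate_cohort(cfg)

print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"subjects: {metadata['subject_id'].nunique()}, "
      f"timepoints: {sorted(metadata['timepoint'].unique())}")

p = compositions.proportions
for tp in cfg.cohort.timepoints:
    med = p.xs(tp, level="timepoint")["neutrophils"].median()
    print(f"median neutrophil proportion at {tp}: {med:.3f}")
print("-> the shifted type roughly doubles during pregnancy and reverts at PP3")

print("\nplanted mechanism classes (truth ledger):")
print(truth.table["class"].value_counts().to_string())
print("-> 'composition' genes are markers of the expanding type; 'regulation'")
print("   genes carry a multiplicative fold-4 effect that vanishes postpartum")
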