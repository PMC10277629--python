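"""Detect weighted co-expression modules on a planted two-block structure.

Two blocks of 60 genes share a latent profile (within-block correlation 0.8).
The chain is biweight midcorrelation -> signed-hybrid adjacency (power 5) ->
topological overlap -> average-linkage clustering -> eigengene merging.
"""

import numpy as np
import pandas as pd

from longidecomp import coexpr

rng = np.random.default_rng(5)
rows, truth = [], []
for block in range(2):
    common = rng.normal(size=40)
    for _ in range(60):
        rows.append(np.sqrt(0.8) * common + np.sqrt(0.2) * rng.normal(size=40))
        truth.append(block)
expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(120)])

cor = coexpr.bicor_matrix(expr)
adjacency = coexpr.adjacency_signed_hybrid(cor, beta=5)
tom = coexpr.tom_similarity(adjacency)
labels = coexpr.detect_modules(tom, min_module_size=30)
assignment = coexpr.merge_modules(expr, labels, merge_cut=0.25)

print("module sizes:")
print(assignment.labels.value_counts().to_string())
purity = (
    pd.crosstab(assignment.labels, np.asarray(truth)).max(axis=1).sum() / len(truth)
)
print(f"assignment purity vs planted blocks: {purity:.3f}")
print("-> the two planted blocks are recovered as two clean modules")

enrichment = coexpr.module_set_enrichment(
    assignment, {"T1": [f"g{i}" for i in range(60)]}
)
best = enrichment.sort_values("p").iloc[0]
print(f"\nmodule most enriched for the stage-T1 list: {best['module']} "
      f"(p={best['p']:.2e}, fold={best['fold']:.1f})")
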