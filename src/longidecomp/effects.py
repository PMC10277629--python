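"""Fold-change calls, onset assignment, mechanism classification, reversion.

A gene is "pregnancy-associated" when its longitudinal screen is significant
(BH q below the FDR threshold) *and* at least one trimester shows an absolute
fold change of ``fc`` or more versus the pre-pregnancy baseline.  Comparing
the calls from the unadjusted screen with those from the screen adjusted for
cell-composition PCs splits genes by mechanism:

    composition  significant only unadjusted   (driven by shifting proportions)
    mixed        significant in both           (proportions + regulation)
    regulation   significant only adjusted     (transcriptional regulation)
    none         significant in neither
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

TRIMESTERS = ("T1", "T2", "T3")
MECHANISM_CLASSES = ("none", "composition", "mixed", "regulation")


def call_pregnancy_associated(
    screen: pd.DataFrame,
    fdr: float = 0.05,
    fc: float = 2.0,
    timepoints: Sequence[str] = TRIMESTERS,
) -> pd.DataFrame:
    """Flag genes with q < fdr and max |log2FC| >= log2(fc) over ``timepoints``.

    The boundary counts as a pass (>=).  Per-timepoint flags mark which
    timepoints individually clear the fold-change threshold for flagged
    genes.
    """
    thr = np.log2(fc)
    fc_cols = [f"log2FC_{tp}" for tp in timepoints]
    missing = [c for c in fc_cols if c not in screen.columns]
    if missing:
        raise ValueError(f"screen lacks fold-change columns: {missing}")
    lfc = screen[fc_cols].to_numpy(float)
    sig = (screen["q"].to_numpy(float) < fdr) & (np.nanmax(np.abs(lfc), axis=1) >= thr)
    sig &= screen["converged"].to_numpy(bool) if "converged" in screen.columns else True
    out = pd.DataFrame({"flagged": sig}, index=screen.index)
    for j, tp in enumerate(timepoints):
        out[f"flag_{tp}"] = sig & (np.abs(lfc[:, j]) >= thr)
    return out


def onset_timepoint(calls: pd.DataFrame, timepoints: Sequence[str] = TRIMESTERS) -> pd.Series:
    """Earliest flagged timepoint per gene, or '' when never flagged."""
    onset = pd.Series("", index=calls.index, dtype=object, name="onset")
    for tp in reversed(list(timepoints)):
        onset[calls[f"flag_{tp}"].to_numpy(bool)] = tp
    return onset


def classify_mechanism(
    unadjusted_calls: pd.DataFrame, adjusted_calls: pd.DataFrame
) -> pd.DataFrame:
    """Partition genes into none/composition/mixed/regulation by set algebra."""
    if not unadjusted_calls.index.equals(adjusted_calls.index):
        diff = unadjusted_calls.index.symmetric_difference(adjusted_calls.index)
        raise ValueError(f"call sets cover different genes, e.g. {list(diff[:5])}")
    u = unadjusted_calls["flagged"].to_numpy(bool)
    a = adjusted_calls["flagged"].to_numpy(bool)
    cls = np.where(u & a, "mixed", np.where(u, "composition", np.where(a, "regulation", "none")))
    out = pd.DataFrame({"class": cls}, index=unadjusted_calls.index)
    out["onset_unadjusted"] = onset_timepoint(unadjusted_calls)
    out["onset_adjusted"] = onset_timepoint(adjusted_calls)
    for col in unadjusted_calls.columns:
        if col.startswith("flag_"):
            out[f"unadjusted_{col}"] = unadjusted_calls[col]
            out[f"adjusted_{col}"] = adjusted_calls[col]
    return out


def venn_counts(calls: pd.DataFrame, timepoints: Sequence[str] = TRIMESTERS) -> pd.DataFrame:
    """Counts of flagged genes for every combination of timepoint membership."""
    flags = calls[[f"flag_{tp}" for tp in timepoints]].to_numpy(bool)
    rows = []
    for mask in range(1, 2 ** len(timepoints)):
        member = np.array([(mask >> j) & 1 for j in range(len(timepoints))], bool)
        exact = np.all(flags == member, axis=1) & calls["flagged"].to_numpy(bool)
        rows.append(
            {
                "timepoints": "+".join(tp for tp, m in zip(timepoints, member) if m),
                "n_genes": int(exact.sum()),
            }
        )
    return pd.DataFrame(rows)


def reversion_correlation(
    screen_vs_t0: pd.DataFrame,
    screen_vs_t3: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    fdr: float = 0.05,
    fc: float = 2.0,
) -> tuple[float, int]:
    """Correlation between T0->T3 and T3->PP3 expression changes.

    ``screen_vs_t3`` is the screen re-fit with the timepoint factor releveled
    to a T3 baseline (so its log2FC_PP3 is the T3->PP3 change).  When
    ``gene_subset`` is None it defaults to genes significantly changing at
    PP3 versus T3.  Returns (Pearson r, subset size); fewer than 3 genes
    yields (nan, n) with a warning.
    """
    if gene_subset is None:
        calls = call_pregnancy_associated(screen_vs_t3, fdr=fdr, fc=fc, timepoints=("PP3",))
        gene_subset = calls.index[calls["flagged"]]
    genes = pd.Index(gene_subset)
    n = len(genes)
    if n < 3:
        warnings.warn(f"reversion subset has only {n} genes; correlation undefined", stacklevel=2)
        return np.nan, n
    x = screen_vs_t0.loc[genes, "log2FC_T3"].to_numpy(float)
    y = screen_vs_t3.loc[genes, "log2FC_PP3"].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 finite fold-change pairs", stacklevel=2)
        return np.nan, int(ok.sum())
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return r, int(ok.sum())
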