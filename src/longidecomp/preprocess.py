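"""Gene filtering and TMM library-size normalization.

Order of operations mirrors standard bulk RNA-seq practice: drop unwanted
gene biotypes, drop low-expression genes using raw (pre-normalization) CPM,
then compute trimmed-mean-of-M-values (TMM) scaling factors against a
reference sample.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_TYPES = frozenset(
    {"rRNA", "pseudogene", "misc_RNA", "Mt_tRNA", "scaRNA", "snRNA", "snoRNA", "TEC"}
)


@dataclasses.dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM factors (geometric mean 1) and library sizes."""

    factors: pd.Series
    lib_sizes: pd.Series
    reference: str

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(float)
        if (f <= 0).any():
            raise ValueError("TMM factors must be positive")
        if abs(np.exp(np.mean(np.log(f))) - 1.0) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def filter_gene_types(
    counts: pd.DataFrame,
    gene_types: pd.Series | None,
    excluded_types: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TYPES,
) -> pd.DataFrame:
    """Remove genes whose biotype is in ``excluded_types``; order preserved."""
    if not excluded_types:
        return counts
    if gene_types is None:
        raise ValueError("gene_type column is required to filter by gene type")
    gene_types = gene_types.reindex(counts.index)
    keep = ~gene_types.isin(set(excluded_types))
    return counts.loc[keep]


def filter_low_expression(
    counts: pd.DataFrame, cpm_numerator: float = 10.0, min_samples: int = 8
) -> pd.DataFrame:
    """Keep genes with raw CPM > cpm_numerator / L in >= min_samples samples.

    L is the minimum library size in millions, so the threshold adapts to the
    shallowest library: the rule approximates "seen in enough samples at a
    depth-independent level".
    """
    if counts.shape[1] < min_samples:
        raise ValueError(f"need at least min_samples={min_samples} samples")
    lib = counts.sum(axis=0).to_numpy(float)
    L = lib.min() / 1e6
    cpm = counts.to_numpy(float) * 1e6 / lib
    keep = (cpm > cpm_numerator / L).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return counts.loc[keep]


def _tmm_one(
    y_k: np.ndarray, y_r: np.ndarray, n_k: float, n_r: float, trim_m: float, trim_a: float
) -> float:
    """TMM factor of one sample against the reference (log2 factor -> 2^...).

    Zeros are excluded (logs undefined); after double trimming on M and A the
    factor is the precision-weighted mean of M values.
    """
    pos = (y_k > 0) & (y_r > 0)
    y_k, y_r = y_k[pos], y_r[pos]
    if y_k.size == 0:
        return 1.0
    pk, pr = y_k / n_k, y_r / n_r
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    # precision weights: inverse of the delta-method variance of M
    w = 1.0 / ((n_k - y_k) / (n_k * y_k) + (n_r - y_r) / (n_r * y_r))

    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 10:
        logger.warning("fewer than 10 genes survive TMM trimming; falling back to factor 1")
        return 1.0
    return float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed mean of M-values scaling factors, geometric mean rescaled to 1.

    The reference is the sample whose 75th-percentile CPM is closest to the
    mean 75th-percentile across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    y = counts.to_numpy(float)
    lib = y.sum(axis=0)
    q75 = np.quantile(y / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts.columns[ref_idx]

    raw = np.array(
        [
            _tmm_one(y[:, k], y[:, ref_idx], lib[k], lib[ref_idx], trim_m, trim_a)
            if k != ref_idx
            else 1.0
            for k in range(y.shape[1])
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=counts.columns, name="lib_size"),
        reference=str(ref),
    )


def cpm_normalized(
    counts: pd.DataFrame,
    factors: NormFactors | None = None,
    log: bool = False,
    prior: float = 0.5,
) -> pd.DataFrame:
    """CPM on TMM-effective library sizes; optionally log2 with a scaled prior.

    The prior count is scaled by each sample's effective library size relative
    to the mean, so the log transform does not reintroduce depth effects.
    """
    if factors is None:
        eff = counts.sum(axis=0).astype(float)
    else:
        if not factors.factors.index.equals(counts.columns):
            raise ValueError("normalization factors do not match the count matrix samples")
        eff = factors.effective_lib_sizes.astype(float)
    if not log:
        return counts * 1e6 / eff
    prior_k = prior * eff / eff.mean()
    return np.log2((counts + prior_k) * 1e6 / (eff + 2 * prior_k))
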