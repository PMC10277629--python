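"""Hypergeometric over-representation of gene lists in named gene sets.

Generic one-sided enrichment against GMT-style collections (transcription
factor regulons, co-expression modules, cell-type marker sets).  The universe
defaults to the filtered gene space used by the longitudinal screens.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .gee import bh_fdr

logger = logging.getLogger(__name__)


def hypergeom_test(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Upper-tail hypergeometric p and fold enrichment.

    p = P(X >= k) for X ~ Hypergeom(N population, K successes, n draws),
    computed by summing the exact pmf; fold = (k/n) / (K/N), NaN when k = 0.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        p = 1.0  # P(X >= 0) exactly
    else:
        hi = min(n, K)
        p = min(float(np.sum(stats.hypergeom.pmf(np.arange(k, hi + 1), N, K, n))), 1.0)
    fold = (k / n) / (K / N) if k > 0 and n > 0 and K > 0 else np.nan
    return p, fold


def enrich_collection(
    gene_list: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric test of one gene list against every set in a collection.

    Genes outside the universe are dropped (count logged); duplicates are
    removed before sizes are computed.  Rows are ordered by (p, set name) and
    BH-corrected across sets.
    """
    universe = set(universe)
    raw = list(gene_list)
    genes = set(raw) & universe
    dropped = len(set(raw)) - len(genes)
    if dropped:
        logger.info("dropped %d list genes outside the universe", dropped)
    N = len(universe)
    n = len(genes)
    if n == 0:
        warnings.warn("gene list empty after intersecting with the universe", stacklevel=2)
        return pd.DataFrame(columns=["set", "k", "K", "n", "N", "p", "fold", "q"]).set_index("set")
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        if not members:
            continue
        k = len(genes & members)
        p, fold = hypergeom_test(k, n, len(members), N)
        rows.append({"set": name, "k": k, "K": len(members), "n": n, "N": N, "p": p, "fold": fold})
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["set", "k", "K", "n", "N", "p", "fold", "q"]).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "set"], kind="stable").set_index("set")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {parts[0]!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate set name in GMT: {name!r}")
            seen = dict.fromkeys(g for g in parts[2:] if g)
            sets[name] = list(seen)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
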