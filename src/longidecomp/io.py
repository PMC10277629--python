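"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (genes in rows, header = sample ids) or MatrixMarket
with sidecar gene/sample index files; metadata, signatures, factors and
result tables are TSV.  Round trips are exact for integer counts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()].unique()
        raise DataError(f"duplicate {what} id(s): {list(map(str, dup[:5]))}")


def read_counts(path, format: str | None = None) -> pd.DataFrame:
    """Read a count matrix from TSV or MatrixMarket (+ .genes/.samples files)."""
    path = Path(path)
    if format is None:
        format = "MTX" if path.suffix.lower() == ".mtx" else "TSV"
    if format.upper() == "TSV":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.columns.empty:
            raise DataError(f"malformed header in {path}: no sample columns")
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError(f"non-numeric counts in {path}")
        if not np.allclose(values, np.round(values)) or (values < 0).any():
            raise DataError(f"counts in {path} must be nonnegative integers")
        df = df.astype(np.int64)
        df.index.name = "gene"
        df.columns.name = "sample_id"
        return df
    if format.upper() == "MTX":
        genes_path = path.with_suffix(".genes.txt")
        samples_path = path.with_suffix(".samples.txt")
        for p in (genes_path, samples_path):
            if not p.exists():
                raise DataError(f"MTX index file missing: {p}")
        mat = spio.mmread(path)
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        mat = np.asarray(mat.todense()) if sparse.issparse(mat) else np.asarray(mat)
        if mat.shape != (len(genes), len(samples)):
            raise DataError(
                f"MTX dimensions {mat.shape} do not match index lengths "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        if (mat < 0).any() or not np.allclose(mat, np.round(mat)):
            raise DataError(f"counts in {path} must be nonnegative integers")
        df = pd.DataFrame(mat.astype(np.int64), index=pd.Index(genes, name="gene"),
                          columns=pd.Index(samples, name="sample_id"))
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        return df
    raise DataError(f"unknown count matrix format: {format}")


def write_counts(counts: pd.DataFrame, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "MTX" if path.suffix.lower() == ".mtx" else "TSV"
    if format.upper() == "TSV":
        counts.to_csv(path, sep="\t")
    elif format.upper() == "MTX":
        spio.mmwrite(str(path), sparse.csr_matrix(counts.to_numpy()))
        path.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
        path.with_suffix(".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        raise DataError(f"unknown count matrix format: {format}")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "subject_id", "timepoint"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"metadata lacks required columns: {sorted(missing)}")
    meta = meta.set_index("sample_id")
    _check_unique(meta.index, "sample")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


def read_signature(path) -> pd.DataFrame:
    sig = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(sig.index, "gene")
    if (sig.to_numpy(float) < 0).any():
        raise DataError("signature matrix must be nonnegative (linear scale)")
    return sig


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
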