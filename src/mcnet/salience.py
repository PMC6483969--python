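"""Expression preprocessing and tail-quantile dichotomization.

Each gene's expression values are split into "normal" and "salient" states:
a value is salient when it falls into the gene-specific lower q or upper
(1-q) empirical quantile tail, both tails considered simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import check_proportion

__all__ = [
    "ExpressionMatrix",
    "SalienceMatrix",
    "preprocess_counts",
    "dichotomize",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_counts_mtx",
    "write_salience_tsv",
    "read_salience_tsv",
]

MIN_SAMPLES_FOR_SALIENCE = 10


@dataclass
class ExpressionMatrix:
    """genes x samples real matrix (log scale after preprocessing)."""

    values: pd.DataFrame
    dataset: str = "default"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("expression matrix contains infinite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SalienceMatrix:
    """genes x samples binary matrix; 1 marks salient expression."""

    states: pd.DataFrame
    q: float
    dataset: str = "default"

    def __post_init__(self) -> None:
        arr = self.states.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("salience states must be binary")

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)

    def salient_genes(self, sample: str) -> frozenset[str]:
        col = self.states[sample]
        return frozenset(col.index[col == 1])


def preprocess_counts(raw: pd.DataFrame, max_zero_fraction: float = 0.5,
                      dataset: str = "default") -> ExpressionMatrix:
    """Drop genes with too many zero counts, then log2(x + 1) transform.

    A gene is dropped iff its zero fraction strictly exceeds
    ``max_zero_fraction`` (a gene with exactly that fraction is retained).
    """
    check_proportion(max_zero_fraction, "max_zero_fraction")
    arr = raw.to_numpy(dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("raw counts must be nonnegative")
    zero_frac = (raw == 0).mean(axis=1)
    kept = raw.loc[zero_frac <= max_zero_fraction]
    return ExpressionMatrix(np.log2(kept + 1.0), dataset=dataset)


def dichotomize(expr: ExpressionMatrix, q: float = 0.02,
                min_samples: int = MIN_SAMPLES_FOR_SALIENCE) -> SalienceMatrix:
    """Mark per-gene lower-q / upper-(1-q) quantile tails as salient.

    Empirical quantiles use linear interpolation; comparisons are inclusive
    (value <= lower threshold or >= upper threshold is salient), so ties at
    the threshold count as salient.  Constant genes and genes with fewer than
    ``min_samples`` non-missing values are never salient.
    """
    if not (0 < q < 0.5):
        raise ValueError(f"q must lie in (0, 0.5); got {q!r}")

    vals = expr.values.to_numpy(dtype=float)
    states = np.zeros(vals.shape, dtype=np.int8)
    n_thin = 0
    for i in range(vals.shape[0]):
        row = vals[i]
        mask = np.isfinite(row)
        if mask.sum() < min_samples:
            n_thin += 1
            continue
        obs = row[mask]
        if obs.max() == obs.min():
            continue  # constant gene: no co-regulation signal
        lo = np.quantile(obs, q)
        hi = np.quantile(obs, 1.0 - q)
        states[i, mask] = ((obs <= lo) | (obs >= hi)).astype(np.int8)
    if n_thin:
        warnings.warn(f"{n_thin} gene(s) with < {min_samples} non-missing values "
                      "excluded from salience (all-zero rows)", stacklevel=2)
    return SalienceMatrix(
        pd.DataFrame(states, index=expr.values.index, columns=expr.values.columns),
        q=q, dataset=expr.dataset)


# ---------------------------------------------------------------------------
# I/O

def read_expression_tsv(path: str | Path, dataset: str = "default") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), dataset=dataset)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def read_counts_mtx(mtx_path: str | Path, genes_path: str | Path,
                    samples_path: str | Path) -> pd.DataFrame:
    """Read a sparse MatrixMarket count matrix with gene/sample sidecar lists."""
    from scipy.io import mmread

    mat = mmread(mtx_path).toarray()
    genes = [l.strip() for l in open(genes_path, encoding="utf-8") if l.strip()]
    samples = [l.strip() for l in open(samples_path, encoding="utf-8") if l.strip()]
    return pd.DataFrame(mat, index=genes, columns=samples)


def write_salience_tsv(sal: SalienceMatrix, path: str | Path) -> None:
    sal.states.to_csv(path, sep="\t", index_label="gene")


def read_salience_tsv(path: str | Path, q: float, dataset: str = "default") -> SalienceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return SalienceMatrix(df.astype(np.int8), q=q, dataset=dataset)
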