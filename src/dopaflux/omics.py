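"""Median-of-ratios normalization of UMI count matrices and gene weights.

Size factors follow the DESeq-style estimator: for each sample, the median
over genes of the ratio of the gene's count to its geometric mean across
samples, restricted to genes with all-positive counts.  Gene weights are
log2 of the mean normalized expression with an activity threshold (default
−3, i.e. mean normalized expression ≥ 2⁻³ = 0.125).  The scale on which the
threshold applies is a configuration point; log2 of mean normalized
expression is the package default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = -3.0


class NormalizationError(ValueError):
    pass


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors per sample and the normalized matrix (genes × samples).

    Genes with a total count of zero are removed before factor computation
    and from the output.  Genes containing any zero count are excluded from
    factor estimation but retained in the normalized matrix.
    """
    if (counts.values < 0).any():
        raise NormalizationError("counts must be nonnegative")
    if counts.index.duplicated().any():
        raise NormalizationError("duplicate gene ids")
    kept = counts.loc[counts.sum(axis=1) > 0]
    positive = kept.loc[(kept > 0).all(axis=1)]
    if positive.empty:
        raise NormalizationError(
            "no gene with all-positive counts; size factors are undefined"
        )
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    size_factors.name = "size_factor"
    normalized = kept.div(size_factors, axis=1)
    return size_factors, normalized


def gene_weights(
    normalized: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Gene weight table: weight = log2(mean normalized expression).

    Genes with zero mean get weight −inf and are inactive; a gene is active
    iff its weight is at or above the threshold.
    """
    mean = normalized.mean(axis=1)
    with np.errstate(divide="ignore"):
        weight = np.log2(mean.to_numpy())
    table = pd.DataFrame(
        {"weight": weight, "active": weight >= threshold}, index=normalized.index
    )
    table.index.name = "gene"
    table.attrs["threshold"] = threshold
    return table


def read_counts(path: str | Path, mtx_genes: str | Path | None = None,
                mtx_samples: str | Path | None = None) -> pd.DataFrame:
    """Read a gene × sample count table (TSV/CSV, or MTX with id files)."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(str(path)).toarray()
        genes = Path(mtx_genes).read_text().split() if mtx_genes else [
            f"g{i}" for i in range(mat.shape[0])
        ]
        samples = Path(mtx_samples).read_text().split() if mtx_samples else [
            f"s{j}" for j in range(mat.shape[1])
        ]
        return pd.DataFrame(mat, index=genes, columns=samples)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def write_weights(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
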