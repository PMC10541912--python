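"""Expression-matrix preprocessing: TPM normalization, mitochondrial
filtering, variable-gene selection, and gene-phenotype correlation.

Matrices are pandas DataFrames with genes as rows and samples as columns.
Downstream modeling operates on log2(TPM + 1); the +1 offset handles zero
counts and is applied by :func:`log_transform`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MITO_LABELS = {"MT", "CHRM", "M"}


def log_transform(expression: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), the modeling transform used throughout the pipeline."""
    return np.log2(expression + 1.0)


def tpm_normalize(counts: pd.DataFrame, gene_lengths: pd.Series,
                  chromosome_labels: pd.Series | None = None,
                  drop_mito: bool = True) -> pd.DataFrame:
    """Convert raw counts to TPM, dropping mitochondrial genes first.

    Mitochondrial transcripts can occupy a large, sample-variable share of
    the library, which would distort the per-million denominator, so genes
    on the mitochondrial chromosome (labels ``MT``/``chrM``/``M``, case
    insensitive) are removed before normalization.

    TPM_g = (count_g / length_kb_g) / sum_g(count/length_kb) * 1e6, so each
    sample column sums to 1e6.
    """
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"gene lengths missing for {missing}...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")

    if drop_mito and chromosome_labels is not None:
        chrom = chromosome_labels.reindex(counts.index).astype(str)
        is_mito = chrom.str.upper().str.removeprefix("CHR").isin({"M", "MT"})
        counts = counts.loc[~is_mito.values]
        lengths = lengths.loc[counts.index]

    rate = counts.div(lengths / 1e3, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0].tolist()
        raise ValueError(f"all-zero sample(s) after filtering: {bad}")
    return rate.div(denom, axis=1) * 1e6


def select_variable_genes(expression: pd.DataFrame, k: int) -> pd.Index:
    """Top-k genes by variance of log2(TPM+1) across samples.

    Ties are broken by gene name so the selection is deterministic.
    """
    if k > expression.shape[0]:
        raise ValueError(f"k={k} exceeds number of genes {expression.shape[0]}")
    logx = log_transform(expression)
    var = logx.var(axis=1, ddof=1)
    # mergesort is stable; pre-sorting by gene name makes the tie-break lexicographic
    order = var.sort_index().sort_values(ascending=False, kind="mergesort")
    return order.index[:k]


def gene_phenotype_correlation(expression: pd.DataFrame,
                               phenotype: pd.Series,
                               already_log: bool = False) -> pd.Series:
    """Per-gene Pearson correlation of log2(TPM+1) with a phenotype vector.

    Returns a Series sorted descending by correlation (ties broken by gene
    name), the ranked list consumed by pre-ranked enrichment.  Genes with
    zero variance across samples get r = 0.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    missing = [s for s in expression.columns if s not in phenotype.index]
    if missing:
        raise KeyError(f"phenotype missing for samples {missing}")
    y = phenotype.reindex(expression.columns).to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype vector is constant")

    X = expression.to_numpy(float) if already_log else log_transform(expression).to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    ranked = pd.Series(r, index=expression.index, name="r")
    # deterministic: sort by (-r, gene name)
    ranked = ranked.sort_index().sort_values(ascending=False, kind="mergesort")
    return ranked


def write_rnk(ranked: pd.Series, path) -> None:
    """Two-column ranked-list (RNK) writer for interoperability."""
    ranked.to_csv(path, sep="\t", header=False)


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes-as-rows TSV with a header of sample names."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t")
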