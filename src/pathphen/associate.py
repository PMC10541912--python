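"""Three-method pathway-phenotype association and rank integration.

Each pathway is scored against a continuous phenotype vector three ways:

1. pre-ranked GSEA on the gene-phenotype correlation vector (ranked by
   enrichment p, ties broken by |NES|);
2. correlation of per-sample ssGSEA enrichment levels with the phenotype
   (ranked by |r|);
3. cross-validated PLS1 trained on the pathway's gene expression (ranked
   by the pooled out-of-fold Pearson r between predicted and observed
   phenotype).

Each method's ranking is converted to a percentile in [0, 100] (average
ranks for ties), and the pathway's summary statistic is the minimum
percentile across the three methods — a pathway is interesting if *any*
view of the data ranks it near the top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import gene_phenotype_correlation, log_transform
from .genesets import GeneSetCollection
from .gsea import DEFAULT_ALPHA, preranked_gsea_collection, ssgsea_collection
from .phenotypes import pearson_association
from .plsr import DEFAULT_COMPONENTS, cv_plsr_score

METHOD_COLUMNS = ("gsea_pct", "ssgsea_pct", "plsr_pct")


def ssgsea_phenotype_association(ssgsea_matrix: pd.DataFrame,
                                 phenotype: pd.Series) -> pd.DataFrame:
    """Per-pathway Pearson correlation of enrichment levels with phenotype.

    Constant enrichment rows are excluded with a warning.  Returns a
    DataFrame indexed by pathway with columns r, p and abs_r (the ranking
    key).
    """
    y = phenotype.reindex(ssgsea_matrix.columns)
    if y.isna().any():
        raise KeyError("phenotype missing for some samples")
    rows = {}
    dropped = []
    for pathway, scores in ssgsea_matrix.iterrows():
        x = scores.to_numpy(float)
        if np.ptp(x) == 0:
            dropped.append(pathway)
            continue
        r, p = pearson_association(x, y.to_numpy(float))
        rows[pathway] = {"r": r, "p": p, "abs_r": abs(r)}
    if dropped:
        warnings.warn(f"excluded constant ssGSEA rows: {dropped[:5]}")
    return pd.DataFrame.from_dict(rows, orient="index")


def _tied_percentiles(primary: np.ndarray, secondary: np.ndarray | None = None) -> np.ndarray:
    """Percentile ranks in [0, 100], smaller key = better, average ties.

    Ties are averaged on the (primary, secondary) pair; with n == 1 the
    single entry gets percentile 0.
    """
    n = primary.size
    if n == 1:
        return np.zeros(1)
    if secondary is None:
        ranks = rankdata(primary, method="average")
    else:
        order = np.lexsort((secondary, primary))
        ordinal = np.empty(n)
        ordinal[order] = np.arange(1, n + 1)
        # average ordinal ranks over groups tied on both keys
        key = np.stack([primary, secondary])
        ranks = ordinal.copy()
        _, inverse = np.unique(key.T, axis=0, return_inverse=True)
        for grp in np.unique(inverse):
            sel = inverse == grp
            ranks[sel] = ordinal[sel].mean()
    return 100.0 * (ranks - 1) / (n - 1)


@dataclass
class AssociationResult:
    """All per-method tables plus the integrated percentile table."""

    table: pd.DataFrame          # pathway x (gsea_pct, ssgsea_pct, plsr_pct, min_pct)
    gsea: pd.DataFrame
    ssgsea_assoc: pd.DataFrame
    plsr: pd.DataFrame
    ranked_genes: pd.Series


def integrate_percentile_ranks(gsea_results: pd.DataFrame,
                               ssgsea_assoc: pd.DataFrame,
                               plsr_scores: pd.DataFrame) -> pd.DataFrame:
    """Combine the three method rankings into minimum percentile ranks.

    Inputs are indexed by pathway: GSEA needs columns p and nes, the
    ssGSEA association needs abs_r (or r), and the PLSR table needs cv_r.
    The pathway universe is the outer join; a pathway missing from a
    method gets percentile 100 for that method (flagged in the
    ``missing_methods`` column).  Rows are sorted by min_pct ascending,
    ties broken by pathway name.
    """
    universe = sorted(set(gsea_results.index) | set(ssgsea_assoc.index)
                      | set(plsr_scores.index))
    if not universe:
        raise ValueError("empty pathway universe")
    out = pd.DataFrame(index=pd.Index(universe, name="pathway"))

    def fill(method_index, percentiles, col):
        series = pd.Series(percentiles, index=method_index)
        out[col] = series.reindex(out.index).fillna(100.0)
        return series

    g = gsea_results
    fill(g.index, _tied_percentiles(g["p"].to_numpy(float),
                                    -g["nes"].abs().to_numpy(float)), "gsea_pct")
    s = ssgsea_assoc
    s_key = s["abs_r"] if "abs_r" in s else s["r"].abs()
    fill(s.index, _tied_percentiles(-s_key.to_numpy(float)), "ssgsea_pct")
    p = plsr_scores
    fill(p.index, _tied_percentiles(-p["cv_r"].to_numpy(float)), "plsr_pct")

    out["min_pct"] = out[list(METHOD_COLUMNS)].min(axis=1)
    missing = []
    for name in out.index:
        lacks = [m for m, tab in (("gsea", g), ("ssgsea", s), ("plsr", p))
                 if name not in tab.index]
        missing.append(",".join(lacks))
    out["missing_methods"] = missing
    return out.sort_index().sort_values("min_pct", kind="mergesort")


def associate_pathways(expression: pd.DataFrame, phenotype: pd.Series,
                       collection: GeneSetCollection, n_perm: int = 1000,
                       seed: int = 1, weight: float = 1.0,
                       alpha: float = DEFAULT_ALPHA,
                       components=DEFAULT_COMPONENTS,
                       n_splits: int = 5, n_repeats: int = 5,
                       already_log: bool = False) -> AssociationResult:
    """Full three-method association of a gene-set collection with a phenotype.

    ``expression`` is a genes x samples TPM-like matrix (set
    ``already_log=True`` if it is pre-transformed); modeling uses
    log2(x + 1).  The same ``seed`` drives the GSEA permutation null and
    the CV fold layout, so results are reproducible end to end.
    """
    logx = expression if already_log else log_transform(expression)
    ranked = gene_phenotype_correlation(logx, phenotype, already_log=True)
    collection = collection.filtered(logx.index, min_size=1)

    gsea_df = preranked_gsea_collection(ranked, collection, weight=weight,
                                        n_perm=n_perm, seed=seed)
    ssg = ssgsea_collection(logx, collection, alpha=alpha)
    ssg_assoc = ssgsea_phenotype_association(ssg, phenotype)

    y = phenotype.reindex(logx.columns).to_numpy(float)
    plsr_rows = {}
    for pathway in collection:
        X = logx.loc[list(collection[pathway])].to_numpy(float).T  # samples x genes
        cv = cv_plsr_score(X, y, components=components, n_splits=n_splits,
                           n_repeats=n_repeats, seed=seed)
        plsr_rows[pathway] = {"cv_r": cv.r, "best_components": cv.best_components}
    plsr_df = pd.DataFrame.from_dict(plsr_rows, orient="index")

    table = integrate_percentile_ranks(gsea_df, ssg_assoc, plsr_df)
    return AssociationResult(table=table, gsea=gsea_df, ssgsea_assoc=ssg_assoc,
                             plsr=plsr_df, ranked_genes=ranked)
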