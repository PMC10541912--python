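"""Pre-ranked gene set enrichment and single-sample enrichment scores.

Pre-ranked GSEA walks a gene list ranked by a signed metric (here the
gene-phenotype Pearson correlation): member genes push a running sum up by
their normalized |metric|^weight, non-members push it down by 1/(N - |S|),
and the enrichment score (ES) is the signed maximum deviation from zero.
Because the phenotype is already collapsed into one ranked metric, the
null is built by resampling random gene sets of matching size; the
permutation p-value is the one-sided tail frequency on the ES's sign side
with +1 smoothing, and NES divides the ES by the mean |null ES| of
matching sign.

ssGSEA scores one sample at a time: genes are ranked by expression
(descending, ties broken by gene name), in-set steps are rank^alpha
weights normalized to sum 1, out-of-set steps are uniform, and the score
is the summed difference of the two empirical CDFs over list positions.
Only ranks enter the statistic, so any strictly increasing transform of a
sample's expression leaves its scores unchanged.

Both statistics are computed with closed-form O(|S|) kernels over hit
positions, equivalent to the full running-sum definitions (the test suite
checks this against brute-force recomputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

DEFAULT_WEIGHT = 1.0
DEFAULT_ALPHA = 0.25


@dataclass
class EnrichmentResult:
    pathway: str
    es: float
    nes: float
    p: float
    size: int
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def _es_from_hits(abs_pow: np.ndarray, hit_pos: np.ndarray, n: int) -> float:
    """Signed max deviation of the running sum, from sorted hit positions.

    ``abs_pow`` is |metric|^weight over the ranked list; ``hit_pos`` are
    0-based positions of set members in ranked order.  Equivalent to the
    full N-step running sum: between hits the sum decays linearly, so its
    extrema occur immediately after a hit (positive candidates) or just
    before a hit (negative candidates).
    """
    s = hit_pos.size
    if s == n:
        return 1.0  # no miss steps; the running sum peaks at exactly 1
    hw = abs_pow[hit_pos]
    denom = hw.sum()
    if denom == 0:
        raise ValueError("all in-set metric values are zero; ES undefined")
    hw = hw / denom
    cum = np.cumsum(hw)
    miss = 1.0 / (n - s)
    i = np.arange(1, s + 1)
    after = cum - (hit_pos + 1 - i) * miss       # just after each hit
    before = (cum - hw) - (hit_pos - i + 1) * miss  # just before each hit
    hi = after.max()
    lo = min(before.min(), 0.0)
    # exact |peak| = |trough| ties break toward the positive side; the
    # tolerance keeps the break deterministic under float summation noise
    return float(hi) if hi >= -lo - 1e-12 else float(lo)


def _null_es(abs_pow: np.ndarray, size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES values of ``n_perm`` random gene sets of a given size."""
    n = abs_pow.size
    if size == n:
        return np.ones(n_perm)
    # distinct positions per permutation via random-key argpartition
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, size - 1, axis=1)[:, :size]
    pos.sort(axis=1)
    hw = abs_pow[pos]
    denom = hw.sum(axis=1, keepdims=True)
    ok = denom[:, 0] > 0
    denom[~ok] = 1.0
    hw = hw / denom
    cum = np.cumsum(hw, axis=1)
    miss = 1.0 / (n - size)
    i = np.arange(1, size + 1)
    after = cum - (pos + 1 - i) * miss
    before = (cum - hw) - (pos - i + 1) * miss
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    es = np.where(hi >= -lo - 1e-12, hi, lo)
    es[~ok] = 0.0
    return es


def _p_and_nes(es: float, null: np.ndarray) -> tuple[float, float]:
    # ties count as "at least as extreme"; the tolerance keeps null values
    # that equal the ES in real arithmetic (but drift by float rounding)
    # inside the tail, which matters on small, discrete universes
    tol = 1e-9 * max(1.0, abs(es))
    n_perm = null.size
    if es > 0:
        side = null[null > 0]
        k = int(np.sum(null >= es - tol))
    elif es < 0:
        side = null[null < 0]
        k = int(np.sum(null <= es + tol))
    else:
        return 1.0, 0.0
    p = (1 + k) / (n_perm + 1)
    mean_abs = float(np.abs(side).mean()) if side.size else np.nan
    nes = es / mean_abs if side.size else np.nan
    return float(p), float(nes)


def _ranked_arrays(ranked: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    genes = ranked.index.to_numpy(str)
    metric = ranked.to_numpy(float)
    if np.all(metric == 0):
        raise ValueError("degenerate ranked list: all metric values are zero")
    return genes, metric


def preranked_gsea(ranked: pd.Series, gene_set, name: str = "set",
                   weight: float = DEFAULT_WEIGHT, n_perm: int = 10000,
                   seed: int = 1) -> EnrichmentResult:
    """Enrichment of one gene set in a ranked list (metric sorted descending)."""
    genes, metric = _ranked_arrays(ranked)
    genes_upper = np.char.upper(genes)
    members = {str(g).upper() for g in gene_set}
    missing = members - set(genes_upper)
    if missing:
        raise KeyError(f"set members absent from the ranked universe: {sorted(missing)[:3]}")
    abs_pow = np.abs(metric) ** weight
    hit_pos = np.nonzero(np.isin(genes_upper, list(members)))[0]
    es = _es_from_hits(abs_pow, hit_pos, genes.size)
    null = _null_es(abs_pow, hit_pos.size, n_perm, np.random.default_rng(seed))
    p, nes = _p_and_nes(es, null)
    return EnrichmentResult(pathway=name, es=es, nes=nes, p=p,
                            size=hit_pos.size, n_perm=n_perm, seed=seed)


def preranked_gsea_collection(ranked: pd.Series, collection: GeneSetCollection,
                              weight: float = DEFAULT_WEIGHT, n_perm: int = 1000,
                              seed: int = 1) -> pd.DataFrame:
    """Pre-ranked GSEA over a whole collection.

    The resampling null depends only on the ranked metric and the set
    size, so one null distribution per distinct set size is shared across
    pathways.  Returns a DataFrame indexed by pathway with columns es,
    nes, p, size.
    """
    genes, metric = _ranked_arrays(ranked)
    abs_pow = np.abs(metric) ** weight
    gene_pos = {g.upper(): i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    hits: dict[str, np.ndarray] = {}
    for pname in collection:
        pos = np.array(sorted(gene_pos[g] for g in collection[pname] if g in gene_pos))
        if pos.size == 0:
            raise ValueError(f"gene set {pname!r} has no members in the ranked universe")
        hits[pname] = pos
    nulls = {size: _null_es(abs_pow, size, n_perm, rng)
             for size in sorted({p.size for p in hits.values()})}

    rows = []
    for pname, pos in hits.items():
        es = _es_from_hits(abs_pow, pos, genes.size)
        p, nes = _p_and_nes(es, nulls[pos.size])
        rows.append({"pathway": pname, "es": es, "nes": nes, "p": p, "size": pos.size})
    return pd.DataFrame(rows).set_index("pathway")


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _sample_positions(expr: np.ndarray, gene_names: np.ndarray) -> np.ndarray:
    """Position of each gene in the descending-expression order.

    Ties in expression are broken by gene name (ascending), making the
    ranking deterministic.
    """
    order = np.lexsort((gene_names, -expr))
    pos = np.empty(expr.size, dtype=np.int64)
    pos[order] = np.arange(expr.size)
    return pos


def _ssgsea_from_positions(pos: np.ndarray, alpha: float, n: int, s: int) -> float:
    """Closed-form ssGSEA score from 0-based in-set list positions.

    The summed ECDF difference telescopes: a hit at position p contributes
    its normalized weight for the (n - p) trailing positions; misses
    contribute uniformly.  Equivalent to the position-by-position running
    sum (checked against brute force in the tests).
    """
    ranks = (n - pos).astype(float)  # top of the list gets rank n
    w = ranks ** alpha
    wsum = w.sum()
    tail = n - pos  # number of positions the cumulative step covers
    term_in = float((w * tail).sum() / wsum)
    if s == n:
        return term_in - 0.0
    total_tail = n * (n + 1) / 2.0
    term_out = (total_tail - float(tail.sum())) / (n - s)
    return term_in - term_out


def ssgsea_score(expression, gene_set, alpha: float = DEFAULT_ALPHA):
    """Single-sample enrichment score(s) of one gene set.

    ``expression`` may be a Series (one sample; returns a float) or a
    genes x samples DataFrame (returns a Series per sample).  Invariant
    under any strictly increasing per-sample transform of the expression
    values.
    """
    if isinstance(expression, pd.Series):
        return float(ssgsea_score(expression.to_frame("s"), gene_set, alpha).iloc[0])
    members = {str(g).upper() for g in gene_set}
    gene_names = expression.index.to_numpy(str)
    genes_upper = np.char.upper(gene_names)
    missing = members - set(genes_upper)
    if missing:
        raise KeyError(f"set members absent from expression: {sorted(missing)[:3]}")
    in_idx = np.nonzero(np.isin(genes_upper, list(members)))[0]
    n, s = gene_names.size, in_idx.size
    out = {}
    for col in expression.columns:
        x = expression[col].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant expression in sample {col!r}; ranks are name order")
        pos = _sample_positions(x, gene_names)
        out[col] = _ssgsea_from_positions(pos[in_idx], alpha, n, s)
    return pd.Series(out, name="ssgsea")


def ssgsea_collection(expression: pd.DataFrame, collection: GeneSetCollection,
                      alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """ssGSEA scores for every pathway (rows) and sample (columns)."""
    gene_names = expression.index.to_numpy(str)
    gene_pos = {g.upper(): i for i, g in enumerate(gene_names)}
    n = gene_names.size
    sample_pos = {col: _sample_positions(expression[col].to_numpy(float), gene_names)
                  for col in expression.columns}
    rows = {}
    for pname in collection:
        in_idx = np.array([gene_pos[g] for g in collection[pname] if g in gene_pos])
        if in_idx.size == 0:
            raise ValueError(f"gene set {pname!r} has no members in the expression universe")
        rows[pname] = [
            _ssgsea_from_positions(sample_pos[col][in_idx], alpha, n, in_idx.size)
            for col in expression.columns
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=expression.columns)
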