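"""Binding-site / expression integration.

Connects transcription-factor binding peaks to transcription: strand-aware
promoter-window classification of peak summits around the nearest TSS
(default window -2500..+100 bp), one-vs-rest Z-score differential
expression calling for single-replicate panels, exact hypergeometric
over-representation of promoter-bound gene sets, and the bookkeeping of
how many differentially expressed genes are direct promoter targets.

Coordinate conventions: peak intervals are BED-style 0-based half-open;
TSS positions and summits handled by this module are 1-based genomic
coordinates (the BED reader converts at the boundary).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import log_transform

PROMOTER_UPSTREAM = 2500
PROMOTER_DOWNSTREAM = 100


def read_bed_peaks(path) -> pd.DataFrame:
    """Read peaks from BED or narrowPeak.

    Returns a frame with chrom, start, end (0-based half-open), a 1-based
    ``summit`` position (narrowPeak column 10 offset when present and
    nonnegative, otherwise the interval midpoint) and ``q_value`` when a
    narrowPeak qValue column exists.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError("BED needs at least chrom, start, end")
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": df[1].astype(int),
        "end": df[2].astype(int),
    })
    if (out.start >= out.end).any():
        raise ValueError("BED intervals must satisfy start < end")
    if ncol >= 4:
        out["name"] = df[3].astype(str)
    if ncol >= 10 and (df[9] >= 0).all():
        out["summit"] = out.start + df[9].astype(int) + 1  # offset -> 1-based
    else:
        out["summit"] = (out.start + out.end) // 2 + 1
    if ncol >= 9:
        out["q_value"] = 10.0 ** (-df[8].astype(float))  # narrowPeak -log10(q)
    return out


def read_tss_table(path, collapse: str = "most-upstream") -> pd.DataFrame:
    """Read a TSS table (gene, chrom, tss_position [1-based], strand).

    Multiple TSS per gene collapse to the most upstream per strand by
    default (smallest position on +, largest on -); ``collapse=None``
    keeps all records.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss_position", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"TSS table needs columns {sorted(required)}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if collapse == "most-upstream":
        df = collapse_tss(df)
    return df.reset_index(drop=True)


def collapse_tss(tss: pd.DataFrame) -> pd.DataFrame:
    """One TSS per gene: the most upstream in transcription direction."""
    def pick(grp: pd.DataFrame) -> pd.Series:
        if (grp["strand"] == "+").all():
            return grp.loc[grp["tss_position"].idxmin()]
        return grp.loc[grp["tss_position"].idxmax()]

    return (tss.groupby("gene", sort=True, group_keys=False)
            .apply(pick, include_groups=True).reset_index(drop=True))


def promoter_window(tss_position: int, strand: str,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """Closed genomic interval of the promoter window around one TSS."""
    if strand == "+":
        return tss_position - upstream, tss_position + downstream
    if strand == "-":
        return tss_position - downstream, tss_position + upstream
    raise ValueError(f"bad strand {strand!r}")


def classify_promoter_peaks(peaks: pd.DataFrame, tss_table: pd.DataFrame,
                            upstream: int = PROMOTER_UPSTREAM,
                            downstream: int = PROMOTER_DOWNSTREAM) -> pd.DataFrame:
    """Flag peaks whose summit falls in the promoter window of the nearest TSS.

    For each peak the nearest TSS on its chromosome (by |summit - TSS|,
    distance ties broken by gene name) is found; the peak is a promoter
    peak iff its summit lies inside that TSS's strand-aware window
    [-upstream, +downstream] (both ends inclusive).  Peaks on chromosomes
    absent from the TSS table are skipped with a warning.  Returns the
    peak frame with gene, distance, is_promoter columns.
    """
    out = peaks.copy()
    out["gene"] = pd.NA
    out["distance"] = np.nan
    out["is_promoter"] = False

    by_chrom = {c: sub.sort_values(["tss_position", "gene"]).reset_index(drop=True)
                for c, sub in tss_table.groupby("chrom")}
    unknown = set()
    for i, peak in out.iterrows():
        sub = by_chrom.get(peak["chrom"])
        if sub is None:
            unknown.add(peak["chrom"])
            continue
        pos = sub["tss_position"].to_numpy()
        d = np.abs(pos - peak["summit"])
        dmin = d.min()
        cand = sub.loc[d == dmin]
        rec = cand.sort_values("gene").iloc[0]  # tie-break by gene name
        lo, hi = promoter_window(int(rec["tss_position"]), rec["strand"],
                                 upstream, downstream)
        out.at[i, "gene"] = rec["gene"]
        out.at[i, "distance"] = float(dmin)
        out.at[i, "is_promoter"] = bool(lo <= peak["summit"] <= hi)
    if unknown:
        warnings.warn(f"peaks on chromosomes without TSS records skipped: {sorted(unknown)}")
    return out


def promoter_target_genes(classified_peaks: pd.DataFrame) -> set[str]:
    """Genes with at least one promoter peak."""
    sel = classified_peaks.loc[classified_peaks["is_promoter"], "gene"]
    return set(sel.dropna().astype(str))


def call_deg_one_vs_rest(expression: pd.DataFrame, focus_sample: str,
                         q_threshold: float = 0.05,
                         already_log: bool = False) -> pd.DataFrame:
    """One-vs-rest differential expression by Z-scored log fold change.

    Per gene, delta = log2(TPM+1) in the focus sample minus the mean over
    the remaining samples.  Deltas are Z-standardized across genes (the
    only null distribution available for a single-replicate comparison),
    converted to two-sided normal p-values and BH-adjusted; a gene is a
    DEG iff q < ``q_threshold``.  Direction follows the sign of delta.
    """
    if focus_sample not in expression.columns:
        raise KeyError(f"unknown sample {focus_sample!r}")
    rest = [c for c in expression.columns if c != focus_sample]
    if len(rest) < 3:
        raise ValueError("need at least 3 non-focus samples")
    logx = expression if already_log else log_transform(expression)
    focus = logx[focus_sample]
    rest_mean = logx[rest].mean(axis=1)
    delta = focus - rest_mean
    sd = float(delta.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance of deltas; Z scores undefined")
    z = (delta - delta.mean()) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "log2_focus": focus,
        "mean_rest": rest_mean,
        "delta": delta,
        "z": z,
        "p": p,
        "q": q,
        "direction": np.where(delta >= 0, "up", "down"),
        "is_deg": q < q_threshold,
    })


def hypergeom_enrichment(target_genes, pathway_set, universe) -> tuple[int, float]:
    """Exact over-representation tail: P(overlap >= k) under hypergeometric.

    N = |universe|, K = |pathway_set|, n = |target_genes| (all intersected
    with the universe).  Returns (observed overlap k, upper-tail p).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    target = set(target_genes) & uni
    pset = set(pathway_set) & uni
    if set(target_genes) - uni or set(pathway_set) - uni:
        warnings.warn("genes outside the universe were ignored")
    k = len(target & pset)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(pset), len(target)))
    return k, p


def deg_target_overlap(deg_results, promoter_targets) -> dict:
    """DEG / promoter-target overlap counts, split by direction.

    ``deg_results`` is either the frame from :func:`call_deg_one_vs_rest`
    (direction-aware) or a plain iterable of DEG names.  Returns n_deg,
    n_deg_and_bound, fraction_bound and per-direction breakdowns.
    """
    targets = set(map(str, promoter_targets))
    if isinstance(deg_results, pd.DataFrame):
        degs = deg_results.loc[deg_results["is_deg"]]
        up = set(degs.index[degs["direction"] == "up"].astype(str))
        down = set(degs.index[degs["direction"] == "down"].astype(str))
    else:
        up = set(map(str, deg_results))
        down = set()
    all_degs = up | down
    bound = all_degs & targets
    return {
        "n_deg": len(all_degs),
        "n_deg_and_bound": len(bound),
        "fraction_bound": len(bound) / len(all_degs) if all_degs else 0.0,
        "n_up": len(up),
        "n_up_bound": len(up & targets),
        "n_down": len(down),
        "n_down_bound": len(down & targets),
    }
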