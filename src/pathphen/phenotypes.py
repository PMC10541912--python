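"""Replicate assay measurements -> normalized phenotype scores.

Six cellular phenotypes (growth-factor-independent survival, apoptosis
resistance, migration, invasion, anoikis resistance, mammosphere polarity)
are each normalized as log2 fold changes over a matched reference line
(a wild-type-overexpressing control), tested against zero with a two-sided
single-sample t-test, and summarized per cell line as the mean of the
available normalized phenotypes ("overall aggressiveness").

Dose-response assays are summarized by the area between the log2
fold-change curves of a test line and the reference (trapezoidal rule on
the linear dose axis); anoikis assays by the reciprocal of the dead/live
death index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PHENOTYPES = (
    "gf_survival", "apoptosis_resistance", "migration",
    "invasion", "anoikis_resistance", "mammosphere_polarity",
)


@dataclass
class PhenotypeScore:
    """One cell line x phenotype normalized score."""

    log2fc: float
    sem: float
    p_value: float
    n: int
    cell_line: str | None = None
    phenotype: str | None = None


def log2fc_normalize(values, reference_values, method: str = "mean-of-ratios",
                     cell_line: str | None = None,
                     phenotype: str | None = None) -> PhenotypeScore:
    """Normalize replicate measurements as log2 fold change over a reference.

    Default is mean-of-ratios: each replicate is log2-transformed against
    the reference mean and the per-replicate log ratios are averaged; their
    SEM and a two-sided one-sample t-test against zero are attached.
    ``method="ratio-of-means"`` instead takes log2(mean(values)/mean(ref)).
    """
    values = np.asarray(values, float)
    reference_values = np.asarray(reference_values, float)
    for name, arr in (("values", values), ("reference_values", reference_values)):
        bad = np.nonzero(arr <= 0)[0]
        if bad.size:
            raise ValueError(f"nonpositive {name} at replicate index {bad[0]}: "
                             f"{arr[bad[0]]!r} (log2 requires positive measurements)")
    ref_mean = reference_values.mean()
    ratios = np.log2(values / ref_mean)
    if method == "mean-of-ratios":
        fc = float(ratios.mean())
    elif method == "ratio-of-means":
        fc = float(np.log2(values.mean() / ref_mean))
    else:
        raise ValueError(f"unknown method {method!r}")
    n = values.size
    sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    p = one_sample_ttest(ratios) if n > 1 else np.nan
    return PhenotypeScore(log2fc=fc, sem=sem, p_value=p, n=n,
                          cell_line=cell_line, phenotype=phenotype)


def one_sample_ttest(log2fc_replicates) -> float:
    """Two-sided p for H0: mean of the log2 fold changes is zero."""
    x = np.asarray(log2fc_replicates, float)
    if x.size < 2:
        raise ValueError("need at least 2 replicates for a t-test")
    if np.ptp(x) == 0:
        warnings.warn("zero variance across replicates; t-test undefined")
        return np.nan
    return float(stats.ttest_1samp(x, popmean=0.0).pvalue)


def shapiro_normality(replicates, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality test; the flag is True when p >= alpha."""
    x = np.asarray(replicates, float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk p-values unreliable above n=5000")
    stat, p = stats.shapiro(x)
    return float(stat), float(p), bool(p >= alpha)


def apoptosis_resistance_score(cell_curves, reference_curves, doses=None,
                               log_dose: bool = False,
                               exclude_doses: tuple[float, ...] = (3.0,)) -> float:
    """Area between the log2 dose-response curves of a line and the reference.

    Inputs are untreated-normalized caspase activities, either Series
    indexed by dose or DataFrames (dose x replicates) whose replicate
    means are used.  Per dose, delta(d) = log2(reference(d) / cell(d)) —
    positive means less caspase activity than the reference, i.e. more
    apoptosis-resistant.  The score is the trapezoidal integral of delta
    over the shared doses on the linear dose axis (``log_dose=True``
    integrates over log10 dose instead).  Doses listed in
    ``exclude_doses`` (default: the 3.0 uM dose, where essentially all
    cells die) are dropped; doses present on only one side are dropped
    with a warning.
    """
    def to_series(curve) -> pd.Series:
        if isinstance(curve, pd.DataFrame):
            return curve.mean(axis=1)
        return pd.Series(curve) if not isinstance(curve, pd.Series) else curve

    cell = to_series(cell_curves)
    ref = to_series(reference_curves)
    if doses is not None:
        cell = cell.reindex([d for d in doses if d in cell.index])
        ref = ref.reindex([d for d in doses if d in ref.index])
    shared = [d for d in cell.index if d in ref.index and d not in exclude_doses]
    dropped = (set(cell.index) | set(ref.index)) - set(shared) - set(exclude_doses)
    if dropped:
        warnings.warn(f"doses present on only one curve were dropped: {sorted(dropped)}")
    if len(shared) < 2:
        raise ValueError("need at least 2 shared doses between cell and reference")
    shared = sorted(shared)
    c = cell.loc[shared].to_numpy(float)
    r = ref.loc[shared].to_numpy(float)
    if (c <= 0).any() or (r <= 0).any():
        raise ValueError("responses must be positive for the log2 ratio")
    delta = np.log2(r / c)
    x = np.log10(np.asarray(shared, float)) if log_dose else np.asarray(shared, float)
    return float(np.trapezoid(delta, x))


def anoikis_scores(dead_count: float, live_count: float) -> tuple[float, float]:
    """Death index (dead/live) and anoikis resistance (its reciprocal)."""
    if live_count <= 0:
        raise ValueError("live_count must be positive")
    if dead_count < 0:
        raise ValueError("dead_count must be nonnegative")
    death_index = dead_count / live_count
    if dead_count == 0:
        warnings.warn("no dead cells; anoikis resistance reported as +inf")
        return 0.0, np.inf
    return float(death_index), float(live_count / dead_count)


def anoikis_log2_live_dead(dead_count: float, live_count: float) -> float:
    """Alternative convention: log2(live/dead) reported directly.

    Equivalent to log2 of the resistance value from :func:`anoikis_scores`;
    both conventions appear in the field and are exposed side by side.
    """
    _, resistance = anoikis_scores(dead_count, live_count)
    return float(np.log2(resistance))


def overall_aggressiveness(phenotype_matrix: pd.DataFrame) -> pd.Series:
    """Per-cell-line mean of available phenotype scores, sorted ascending.

    Missing entries are ignored in the mean; all-missing rows are excluded
    with a warning.  Ties in the mean are broken lexicographically by cell
    line name so the ordering is total.
    """
    agg = phenotype_matrix.mean(axis=1, skipna=True)
    if agg.isna().any():
        warnings.warn(f"excluded all-missing cell lines: {agg.index[agg.isna()].tolist()}")
        agg = agg.dropna()
    return agg.sort_index().sort_values(ascending=True, kind="mergesort")


def pearson_association(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p (t-distributed with n-2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def score_phenotype_table(table: pd.DataFrame, reference: str = "WT_OE",
                          alpha: float = 0.05,
                          method: str = "mean-of-ratios") -> pd.DataFrame:
    """Score a long-format assay table against the reference cell line.

    ``table`` columns: cell_line, phenotype, replicate_id, value.  For
    every (cell line, phenotype) the replicates are log2fc-normalized
    against the reference line's replicate mean for that phenotype.
    Returns a tidy frame with log2fc, sem, p_value, n and a significance
    flag at ``alpha``; pivot on (cell_line, phenotype) for the matrix and
    feed it to :func:`overall_aggressiveness`.
    """
    required = {"cell_line", "phenotype", "replicate_id", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for phen, sub in table.groupby("phenotype", sort=True):
        ref = sub.loc[sub.cell_line == reference, "value"].to_numpy(float)
        if ref.size == 0:
            raise ValueError(f"no reference ({reference!r}) rows for phenotype {phen!r}")
        for cell, grp in sub[sub.cell_line != reference].groupby("cell_line", sort=True):
            score = log2fc_normalize(grp["value"].to_numpy(float), ref,
                                     method=method, cell_line=cell, phenotype=phen)
            rows.append({"cell_line": cell, "phenotype": phen,
                         "log2fc": score.log2fc, "sem": score.sem,
                         "p_value": score.p_value, "n": score.n,
                         "significant": bool(score.p_value < alpha)
                         if np.isfinite(score.p_value) else False})
    return pd.DataFrame(rows)


def phenotype_matrix(scored: pd.DataFrame) -> pd.DataFrame:
    """Pivot the output of :func:`score_phenotype_table` to cell x phenotype."""
    return scored.pivot(index="cell_line", columns="phenotype", values="log2fc")
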