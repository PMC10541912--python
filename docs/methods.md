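# Methods

This note records the statistical procedures `pathphen` implements, the
defaults it ships, the choices made where the design was genuinely open,
and what its synthetic validation does and does not establish.

## Phenotype scoring

Replicate assay values are assumed positive on their native scale.
Normalization is *mean-of-ratios*: each replicate is divided by the
reference line's replicate mean and log2-transformed, and the per-replicate
log ratios are averaged; their SEM and a two-sided one-sample *t*-test
against zero accompany the score. A *ratio-of-means* variant
(`method="ratio-of-means"`) is available; the two agree when replicate
scatter is small and neither is canonical. Normality of replicate sets can
be checked with the Shapiro–Wilk test at α = 0.05 (3 ≤ n ≤ 5000).

The apoptosis summary integrates Δ(d) = log2(reference(d)/cell(d)) over
the dose axis with the trapezoidal rule. Integration is over the **linear**
dose axis by default: the informative doses (0.3–1.0 µM doxorubicin) span
less than one decade, so the choice is low-impact; `log_dose=True` switches
to log10 dose. The 3.0 µM dose is excluded by default because essentially
all cells die there and the readout carries no contrast. The sign
convention makes *less* caspase activity than the reference positive, i.e.
resistance-positive. The score is antisymmetric under curve swap and
linear in a constant log2 shift (a shift *s* over span *D* integrates to
exactly *s·D*).

Anoikis is reported as the death index dead/live and its reciprocal
(resistance); the alternative convention log2(live/dead) seen in some
protocols is exposed as `anoikis_log2_live_dead` — the two differ only by
the log transform of the same ratio. A zero dead count yields a +inf
resistance sentinel with a warning rather than an error.

Overall aggressiveness is the row mean of the available normalized
phenotypes, ignoring missing entries (equivalent to mean imputation for
the ordering, and used *only* there — significance tests never see imputed
values). The ordering is made total by breaking ties lexicographically on
the cell-line name.

## Spheroid morphometrics

Segmentation uses the cell-wide marker channel: global Otsu threshold,
hole filling, largest connected component (first-found on ties), centroid
= mask center of mass. The published pipelines this emulates used
custom CellProfiler settings that are not public; Otsu is the standard
parameter-free stand-in.

Radial profiles use **equal-radius** rings: pixel at distance r from the
centroid goes to bin ⌈20·r/r_max⌉ (centre pixel to bin 1), r_max being the
largest mask-pixel distance. Ring means are divided by the total mask
pixel count, making profiles comparable across spheroid sizes; the raw
ring means are kept alongside. Empty rings (possible when the radius is
small relative to 20 bins; a radius below 20 px triggers a warning at
generation time) are reported as 0 and flagged. Profiles are invariant
under image translation and 90° rotations up to floating-point summation
order.

Hollowness = mean(bins 1–10)/mean(bins 11–20) of the nuclear profile
(0 = fully cleared lumen, ≈1 = filled; classification threshold 0.5).
Polarity = sum(ring means, bins 16–20)/sum(all ring means) of the
basement-membrane-marker profile: ≈1 for a basally confined marker and
5/20 = 0.25 for a diffuse one — note this is a share of *ring means*, not
of pixels, so the diffuse baseline is the bin share, not the outer-area
share. Zero denominators return inf/NaN sentinels with warnings.

The scalar "mammosphere polarity" phenotype fed into the aggressiveness
mean is this package's construction (no standard definition exists):
−log2(polarity/polarity_reference), so that *loss* of basal polarity is
aggressive-positive like the other phenotype scores.

## Pathway–phenotype association

All modeling operates on log2(TPM+1); the +1 offset handles zeros and is
the only part of the transform that is a convention rather than a
necessity. TPM normalization removes mitochondrial genes (labels chrM/MT)
*before* computing the per-million denominator, because mitochondrial
reads can occupy a large, sample-variable library share.

**Ranked list.** Per-gene Pearson correlation of log2(TPM+1) with the
phenotype vector; constant genes get r = 0; descending order with
lexicographic tie-break.

**Pre-ranked GSEA.** Hit steps |r_i|^w / Σ_{j∈S}|r_j|^w with weight
w = 1 (the classic weighted statistic), miss steps 1/(N−|S|); ES = signed
maximum deviation of the running sum. Ties between the positive peak and
negative trough break toward positive, with a 1e-12 tolerance so the break
is deterministic under floating-point summation noise; tail counts for the
permutation p likewise include null values within 1e-9 of the observed ES,
which matters on small discrete universes where substantial null mass sits
exactly at the observed score. The ES is computed by a
closed-form O(|S|) kernel over hit positions — the running sum is linear
between hits, so its extrema sit immediately after or before hits — and
the test suite verifies exact agreement with the full running sum.
Because the phenotype is already collapsed into one ranked metric, the
only available null is resampling random gene sets of matching size; the
null therefore depends only on the metric and the set size and is shared
across same-size pathways in collection runs.
p = (1 + #{null of matching sign beyond ES})/(n_perm + 1) ∈
[1/(n_perm+1), 1]; NES = ES / mean|null ES of matching sign|. Production
defaults: n_perm = 10,000 for single-set analyses, 1,000 for collection
sweeps (ranking ties on p are broken by |NES|, so coarser p resolution
does not disturb the integrated ranking).

**ssGSEA.** Per sample, genes are ranked by expression descending with
lexicographic tie-break; in-set steps are rank^α weights normalized to
sum 1 (α = 0.25), out-of-set steps uniform; the score is the summed
difference of the two ECDFs over list positions, computed by an O(|S|)
telescoped form. Only ranks enter, so the score is bit-exact invariant
under strictly increasing per-sample transforms — which also makes the
TPM-vs-log-TPM question moot for untied data. No cross-sample min–max
rescaling is applied. Pathway association is the Pearson correlation of
the per-sample scores with the phenotype, ranked by |r|; because the
statistic is rank-based, even a noise-free linear planting gives |r|
slightly below 1.

**PLS1.** NIPALS with column centering and unit scaling (zero-variance
columns dropped): w_k ∝ X_kᵀy (unit norm), t_k = X_k w_k, deflation of X
and y; per-component coefficient paths allow one fit to serve all
component counts. With as many components as the predictor rank the fit
equals ordinary least squares (verified to 1e-8 against the
normal-equations oracle). Cross-validation is repeated 5-fold (5
repeats); out-of-fold predictions are **pooled** across all folds and
repeats and scored with a single Pearson r — at n ≈ 13, per-fold
correlations on 2–3 points are unstable, pooling is not. The component
grid 2–5 is clamped per fold to min(train_n − 1, usable features) so that
narrow feature sets are still scored; singleton test folds are merged
into a neighbor. Forward feature selection greedily adds the feature
maximizing the pooled CV r, scanning candidates in lexicographic order
(deterministic ties) and stopping early if no candidate improves the
score.

**Integration.** Per method, pathways are ranked (GSEA: ascending p then
descending |NES|; ssGSEA: descending |r|; PLSR: descending CV r) and
converted to percentiles 100·(rank−1)/(n−1) with average ranks on exact
ties; a pathway absent from a method gets percentile 100 and a flag. The
summary is the minimum percentile across methods: a pathway is
interesting if *any* of the three complementary views places it near the
top. Nominal p (not FDR) drives the GSEA ranking — percentiles are
rank-based, so any monotone adjustment would give the same order.

## Signature clustering

The Calinski–Harabasz index (SSB/(k−1))/(SSW/(n−k)) measures how tightly
a designated group clusters against the rest; it is computed by default
on a 2-component PCA projection of the signature enrichment panel
(`full_space=True` uses the raw space). PCA uses the SVD of the
column-centered matrix with a deterministic sign convention
(largest-magnitude loading positive). Enrichment groups come from Ward
agglomerative clustering (scipy linkage) into k = 3 groups labeled
high/mid/low by mean enrichment; the method is a documented, swappable
choice — the grouping is not sensitive to it when groups are separated.

## Regulatory integration

Peaks are BED-style 0-based half-open; TSS positions and summits are
handled as 1-based genomic coordinates with conversion at the reader
boundary (narrowPeak summit offset → start + offset + 1; midpoint
fallback). Multiple TSS per gene collapse to the most upstream in
transcription direction. A peak is a promoter peak iff its **summit**
falls in the window [TSS−2500, TSS+100] (strand-aware, both ends
inclusive) of its *nearest* TSS, distance ties broken by gene name;
summit-based assignment matches summit-centric annotation workflows, and
an interval-overlap variant is deliberately out of scope.

One-vs-rest differential expression for single-replicate panels: per
gene, δ = log2(TPM+1)_focus − mean(log2(TPM+1)_rest); the per-panel
distribution of δ across genes is the only null available, so z =
(δ − mean δ)/sd δ, two-sided normal p, Benjamini–Hochberg q, DEG iff
q < 0.05. Under an exchangeable null the nominal p < 0.05 rate calibrates
to ≈5% while the BH-adjusted rate is near zero — both are checked.
All-zero δ (focus identical to the rest mean) leaves z undefined and
raises an error. Over-representation of promoter-bound genes in a pathway
uses the exact hypergeometric upper tail on the shared universe.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of a mutant-panel study: 13
samples, a TPM-like positive expression scale with log-normal baselines
(log-mean 3, log-sd 1 — realistic RNA-seq dispersion; the exact law is a
free choice), a continuous phenotype evenly spaced over (−3, 3) emulating
the spread of log2FC phenotype scores, informative pathways whose genes
follow baseline + slope·phenotype + N(0, σ), shifted log2 dose–response
curves with multiplicative replicate noise, binomial dead/live counts,
and geometric spheroid sections (annulus vs disk nuclei; rim vs uniform
marker) with clipped additive Gaussian noise. Informative pathways get
dedicated disjoint genes and fixed names across seeds (so multi-seed
recovery can track them); background pathways draw from the remaining
pool, disjointly when it is large enough and with between-set overlap
otherwise — curated collections overlap heavily, so this is realistic.
At the validation scale (200 pathways × 20 genes in a 2,000-gene
universe) background sets do overlap.

Not emulated: read-level sequencing noise, gene–gene correlation
structure beyond the planted pathways, batch effects, assay-specific
systematic errors, partial-volume and optical effects in imaging, and
ChIP fragment distributions. Passing recovery tests therefore shows the
statistics are implemented correctly and are sensitive at realistic
signal-to-noise — not that real panels of this size always yield such
clean rankings.

## Validation problem sizes

The multi-seed experiments run at: 100 seeds × (13 samples, 2,000 genes,
200 pathways of 20, 2 planted, slope/noise = 1, GSEA n_perm = 500) for
recovery; 100 seeds × 51 features for forward selection; 50 images per
class (noise up to 20% of signal) for morphometrics; 100 seeds × 2,000
genes for the DEG null; 1,000 random instances (universe ≤ 50) for the
ES oracle and 5 universes ≤ 8 at n_perm = 10,000 for the enumeration
check; 500 matrices for ssGSEA invariance; 100 random problems for the
PLS/OLS identity. These sizes give stable rates while keeping a full run
in minutes on one CPU.

## Known limitations

* The GSEA null is gene-set resampling, not phenotype permutation; its p
  answers "is this score extreme among random same-size sets", which is
  the only question available once the metric is fixed.
* ssGSEA scores are not comparable across universes of different size.
* PLS1 CV at n = 13 has high variance fold-to-fold; only the pooled
  statistic is reported, and repeated CV mitigates but does not remove
  the dependence on fold layout (the seed fixes it).
* The one-vs-rest DEG z-test treats genes as exchangeable within a
  panel; correlated gene programs inflate its effective significance.
* Promoter classification considers the nearest TSS only; a summit inside
  another gene's window but nearer to a different TSS is not called.
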