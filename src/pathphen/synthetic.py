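"""Synthetic inputs with planted ground truth.

Emulates the data structure of a ~13-line mutant cell-line panel study:

* an expression panel in which the member genes of a few "informative"
  pathways track a continuous per-sample phenotype linearly, on top of a
  log-normal baseline and Gaussian noise (TPM-like positive scale);
* dose-response caspase-activity curves where a test line is displaced
  from a reference line by a constant log2 shift;
* two-channel spheroid images (hollow or filled lumen; peripheral or
  diffuse basement-membrane marker);
* dead/live cell counts for anoikis assays.

Every generator is deterministic under a fixed seed and records the
planted truth so recovery tests can score the pipeline against it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection, write_gmt
from .morphometrics import SpheroidImage

DEFAULT_DOSES = (0.3, 0.7, 1.0)


@dataclass
class PanelConfig:
    """Study conditions for the synthetic expression panel.

    Defaults mirror the structure used throughout the pipeline's recovery
    experiments: 13 samples, 2,000 genes, 200 pathways of 20 genes of
    which 2 are informative, unit effect slope and unit expression noise,
    and a phenotype spread of (-3, 3) emulating the range of log2
    fold-change phenotype scores across a cell-line panel.
    """

    n_samples: int = 13
    n_genes: int = 2000
    n_pathways: int = 200
    pathway_size: int = 20
    n_informative: int = 2
    effect_slope: float = 1.0
    noise_sd: float = 1.0
    phenotype_range: tuple[float, float] = (-3.0, 3.0)
    baseline_log_mean: float = 3.0   # lognormal baseline, mimics RNA-seq dispersion
    baseline_log_sd: float = 1.0
    allow_overlap: bool = True       # background sets may share genes when the pool is small
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_pathways:
            raise ValueError("n_informative exceeds n_pathways")
        if self.pathway_size < 10:
            raise ValueError("pathway_size must be >= 10")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size exceeds n_genes")
        if self.n_informative * self.pathway_size > self.n_genes:
            raise ValueError("informative pathways need disjoint genes; increase n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated panel."""

    informative_pathways: set[str]
    phenotype_vector: pd.Series
    gene_effects: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "informative_pathways": sorted(self.informative_pathways),
            "phenotype_vector": self.phenotype_vector.to_dict(),
            "gene_effects": self.gene_effects[self.gene_effects != 0].to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def gen_panel(config: PanelConfig) -> tuple[pd.DataFrame, pd.Series, GeneSetCollection, SyntheticTruth]:
    """Generate an expression panel with planted pathway-phenotype structure.

    Informative-pathway genes follow baseline + effect_slope * phenotype +
    N(0, noise_sd); background genes are baseline + noise.  Values are
    clipped at zero (TPM-like scale).  The phenotype vector is evenly
    spaced over ``phenotype_range``.  Informative pathways always receive
    dedicated, mutually disjoint genes; background pathways are drawn from
    the remaining pool, disjointly when the pool is large enough and with
    between-set overlap otherwise (curated collections overlap too).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [f"S{i:02d}" for i in range(1, config.n_samples + 1)]
    genes = np.array([f"G{i:05d}" for i in range(1, config.n_genes + 1)])
    phenotype = pd.Series(
        np.linspace(*config.phenotype_range, config.n_samples), index=samples,
        name="phenotype",
    )

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                             size=config.n_genes)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples)) \
        if config.noise_sd > 0 else np.zeros((config.n_genes, config.n_samples))

    expr = baseline[:, None] + noise

    # plant the informative pathways on a random disjoint gene block;
    # a zero slope plants nothing, so the truth is empty by construction
    n_informative = config.n_informative if config.effect_slope != 0 else 0
    perm = rng.permutation(config.n_genes)
    n_info_genes = n_informative * config.pathway_size
    info_gene_idx = perm[:n_info_genes]
    pool_idx = perm[n_info_genes:]

    effects = np.zeros(config.n_genes)
    effects[info_gene_idx] = config.effect_slope
    expr += effects[:, None] * phenotype.to_numpy()[None, :]
    np.maximum(expr, 0.0, out=expr)

    # informative pathways keep fixed names across seeds so multi-seed
    # recovery experiments can track each planted pathway's rank
    pathway_names = [f"PW{i:04d}" for i in range(1, config.n_pathways + 1)]
    info_names = pathway_names[:n_informative]
    sets: dict[str, list[str]] = {}
    blocks = info_gene_idx.reshape(n_informative, config.pathway_size) \
        if n_informative else np.empty((0, config.pathway_size), int)
    for name, block in zip(info_names, blocks):
        sets[name] = genes[np.sort(block)].tolist()

    background_names = [n for n in pathway_names if n not in sets]
    n_bg = len(background_names)
    if n_bg * config.pathway_size <= pool_idx.size:
        # fully disjoint background sets
        bg_idx = rng.permutation(pool_idx)[: n_bg * config.pathway_size]
        bg_blocks = bg_idx.reshape(n_bg, config.pathway_size)
    else:
        if not config.allow_overlap:
            raise ValueError("gene pool too small for disjoint background sets; "
                             "set allow_overlap=True or increase n_genes")
        bg_blocks = np.stack([
            rng.choice(pool_idx, size=config.pathway_size, replace=False)
            for _ in range(n_bg)
        ])
    for name, block in zip(background_names, bg_blocks):
        sets[name] = genes[np.sort(block)].tolist()

    collection = GeneSetCollection({n: sets[n] for n in pathway_names},
                                   source=f"synthetic(seed={config.seed})")
    expression = pd.DataFrame(expr, index=genes, columns=samples)
    truth = SyntheticTruth(
        informative_pathways=set(info_names),
        phenotype_vector=phenotype,
        gene_effects=pd.Series(effects, index=genes, name="slope"),
    )
    return expression, phenotype, collection, truth


def gen_dose_response(n_doses: int = 3, shift: float = 1.0, seed: int = 0,
                      doses: tuple[float, ...] | None = None,
                      n_replicates: int = 3, noise_sd: float = 0.0,
                      baseline: float = 1.0, dose_gain: float = 1.0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference and test dose-response tables with replicates.

    The reference curve is an increasing untreated-normalized caspase
    response; the test curve is the reference displaced *down* by ``shift``
    in log2 response at every dose, so the downstream area-between-curves
    score of the pair recovers ``shift`` x (dose span).  Replicate noise is
    multiplicative log-normal with log2-scale standard deviation
    ``noise_sd``; replicate means are unbiased in log space.

    Returns two DataFrames indexed by dose with one column per replicate.
    """
    if doses is None:
        doses = tuple(DEFAULT_DOSES[:n_doses]) if n_doses <= len(DEFAULT_DOSES) \
            else tuple(np.linspace(0.3, 3.0, n_doses))
    doses = tuple(float(d) for d in doses)
    if len(doses) < 2:
        raise ValueError("need at least 2 doses")
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("doses must be strictly increasing")

    rng = np.random.default_rng(seed)
    d = np.asarray(doses)
    ref_curve = baseline * 2.0 ** (dose_gain * d)   # caspase activity rises with dose
    test_curve = ref_curve * 2.0 ** (-shift)

    cols = [f"rep{i}" for i in range(1, n_replicates + 1)]

    def table(curve: np.ndarray) -> pd.DataFrame:
        if noise_sd > 0:
            jitter = 2.0 ** rng.normal(0.0, noise_sd, size=(len(d), n_replicates))
        else:
            jitter = np.ones((len(d), n_replicates))
        return pd.DataFrame(curve[:, None] * jitter, index=pd.Index(d, name="dose"),
                            columns=cols)

    return table(ref_curve), table(test_curve)


def gen_spheroid_image(radius_px: int = 40, hollow: bool = True,
                       peripheral_laminin: bool = True, noise_sd: float = 0.0,
                       seed: int = 0, pixel_size: float = 1.0,
                       intensity: float = 1.0,
                       lumen_fraction: float = 0.5,
                       rim_fraction: float = 0.1) -> SpheroidImage:
    """Synthetic two-channel equatorial spheroid section.

    Nuclear channel: annulus (lumen cleared out to ``lumen_fraction`` of
    the radius) when hollow, full disk when filled.  Membrane-marker
    channel: thin outer ring (outer ``rim_fraction`` of the radius) when
    basally polarized, uniform disk otherwise.  The segmentation-marker
    channel is always the full disk.  Additive Gaussian noise with
    standard deviation ``noise_sd`` (on the same scale as ``intensity``)
    is applied to every channel and clipped at zero.
    """
    if radius_px < 10:
        raise ValueError("radius_px must be >= 10")
    if radius_px < 20:
        warnings.warn("radius below 20 px cannot resolve 20 radial bins cleanly")
    rng = np.random.default_rng(seed)
    size = 2 * radius_px + 11
    c = size // 2
    yy, xx = np.mgrid[:size, :size]
    r = np.hypot(yy - c, xx - c)
    disk = r <= radius_px

    # strict inequality: a pixel exactly on the lumen boundary stays clear,
    # so the inner half of the radial profile is exactly empty
    nuclear = np.where(disk & (r > lumen_fraction * radius_px) if hollow else disk,
                       intensity, 0.0)
    laminin = np.where(disk & (r >= (1 - rim_fraction) * radius_px)
                       if peripheral_laminin else disk, intensity, 0.0)
    marker = np.where(disk, intensity, 0.0)

    if noise_sd > 0:
        nuclear = nuclear + rng.normal(0, noise_sd, nuclear.shape)
        laminin = laminin + rng.normal(0, noise_sd, laminin.shape)
        marker = marker + rng.normal(0, noise_sd, marker.shape)
    nuclear = np.clip(nuclear, 0, None)
    laminin = np.clip(laminin, 0, None)
    marker = np.clip(marker, 0, None)

    truth = {"hollow": bool(hollow), "peripheral_laminin": bool(peripheral_laminin),
             "radius_px": int(radius_px), "noise_sd": float(noise_sd)}
    return SpheroidImage(nuclear=nuclear, laminin=laminin, mask_marker=marker,
                         pixel_size=pixel_size, truth=truth)


def gen_anoikis_counts(n_cells: int = 1000, dead_fraction: float = 0.3,
                       seed: int = 0) -> tuple[int, int]:
    """Binomial dead/live counts for an anoikis assay."""
    if not 0.0 <= dead_fraction <= 1.0:
        raise ValueError("dead_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dead = int(rng.binomial(n_cells, dead_fraction))
    return dead, n_cells - dead


def gen_assay_replicates(true_log2fc: dict[str, float], reference: str = "WT_OE",
                         phenotype: str = "invasion", n_replicates: int = 3,
                         noise_sd: float = 0.1, reference_level: float = 100.0,
                         seed: int = 0) -> pd.DataFrame:
    """Long-format replicate assay table around planted log2 fold changes.

    Each cell line's replicates are ``reference_level * 2**(true_log2fc +
    noise)``; the reference line has true log2FC 0.  Columns: cell_line,
    phenotype, replicate_id, value — the layout consumed by
    :func:`pathphen.phenotypes.score_phenotype_table`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    lines = {reference: 0.0, **true_log2fc}
    for cell, fc in lines.items():
        eps = rng.normal(0, noise_sd, n_replicates) if noise_sd > 0 else np.zeros(n_replicates)
        for i, e in enumerate(eps, start=1):
            rows.append({"cell_line": cell, "phenotype": phenotype,
                         "replicate_id": i,
                         "value": reference_level * 2.0 ** (fc + e)})
    return pd.DataFrame(rows)


def save_spheroid_npz(image: SpheroidImage, path) -> None:
    np.savez(path, nuclear=image.nuclear, laminin=image.laminin,
             mask_marker=image.mask_marker, pixel_size=image.pixel_size)


def load_spheroid_npz(path, truth: dict | None = None) -> SpheroidImage:
    data = np.load(path)
    return SpheroidImage(nuclear=data["nuclear"], laminin=data["laminin"],
                         mask_marker=data["mask_marker"],
                         pixel_size=float(data["pixel_size"]), truth=truth)


def save_spheroid_tiff(image: SpheroidImage, path) -> None:
    """Multi-page TIFF: nuclear, laminin, mask-marker."""
    import tifffile

    stack = np.stack([image.nuclear, image.laminin, image.mask_marker]).astype(np.float32)
    tifffile.imwrite(path, stack)


def load_spheroid_tiff(path, pixel_size: float = 1.0) -> SpheroidImage:
    import tifffile

    stack = tifffile.imread(path)
    if stack.shape[0] != 3:
        raise ValueError("expected a 3-page TIFF (nuclear, laminin, mask marker)")
    return SpheroidImage(nuclear=stack[0].astype(float), laminin=stack[1].astype(float),
                         mask_marker=stack[2].astype(float), pixel_size=pixel_size)


def write_panel(out_dir, expression: pd.DataFrame, phenotype: pd.Series,
                collection: GeneSetCollection, truth: SyntheticTruth) -> None:
    """Write a generated panel as TSV + GMT + truth JSON under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expression.to_csv(out / "expression.tsv", sep="\t")
    phenotype.rename("phenotype").to_csv(out / "phenotype.tsv", sep="\t")
    write_gmt(collection, out / "pathways.gmt")
    truth.to_json(out / "truth.json")
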