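"""Multi-seed validation experiments on synthetic data.

These routines wrap the pipeline's recovery and calibration experiments —
planted-pathway recovery through the three-method integration, forward
feature selection of an informative pathway feature, hollow/filled and
polarized/diffuse spheroid classification, and the one-vs-rest DEG null
calibration — so that both the test suite and reproduction scripts run
the same, seed-controlled protocols.

Problem sizes default to the panel-scale study conditions (13 samples,
2,000 genes, 200 pathways of 20 genes, 2 planted, unit effect slope and
noise); seeds for the i-th replicate derive deterministically from a base
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .associate import associate_pathways
from .morphometrics import quantify_spheroid
from .plsr import forward_feature_selection
from .regulatory import call_deg_one_vs_rest
from .synthetic import PanelConfig, gen_panel, gen_spheroid_image


def _child_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


@dataclass
class RecoveryResult:
    per_seed_min_pct: pd.DataFrame      # seeds x pathways
    planted: list[str]
    planted_hit_fraction: dict[str, float]   # fraction of seeds with min_pct <= top_pct
    background_mean_min_pct: pd.Series       # per background pathway, mean over seeds
    top_pct: float


def recovery_experiment(n_seeds: int = 100, base_seed: int = 0,
                        config: PanelConfig | None = None,
                        n_perm: int = 500, top_pct: float = 5.0) -> RecoveryResult:
    """Planted-pathway recovery through the full association pipeline.

    For each seed a fresh panel is generated and associated; a planted
    pathway counts as recovered in a seed when its integrated minimum
    percentile rank is at most ``top_pct``.
    """
    base_cfg = config or PanelConfig()
    rows = {}
    planted: list[str] = []
    for i, seed in enumerate(_child_seeds(base_seed, n_seeds)):
        cfg = PanelConfig(**{**base_cfg.__dict__, "seed": seed})
        expr, phen, coll, truth = gen_panel(cfg)
        res = associate_pathways(expr, phen, coll, n_perm=n_perm, seed=seed)
        rows[i] = res.table["min_pct"]
        planted = sorted(truth.informative_pathways)
    per_seed = pd.DataFrame(rows).T
    hit = {p: float((per_seed[p] <= top_pct).mean()) for p in planted}
    background = [c for c in per_seed.columns if c not in planted]
    return RecoveryResult(per_seed_min_pct=per_seed, planted=planted,
                          planted_hit_fraction=hit,
                          background_mean_min_pct=per_seed[background].mean(),
                          top_pct=top_pct)


def forward_selection_experiment(n_seeds: int = 100, base_seed: int = 0,
                                 n_samples: int = 13,
                                 n_noise_features: int = 50) -> float:
    """Fraction of seeds in which the noise-free informative feature wins.

    One feature equals the phenotype exactly (a perfectly informative
    pathway summary); the rest are Gaussian noise.  Returns the fraction
    of seeds where forward selection picks the informative feature first.
    """
    hits = 0
    y = np.linspace(-2.0, 2.0, n_samples)
    for seed in _child_seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        F = pd.DataFrame(rng.normal(size=(n_samples, n_noise_features)),
                         columns=[f"noise{i:03d}" for i in range(n_noise_features)])
        F["informative"] = y
        sel = forward_feature_selection(F, y, n_select=1, seed=seed)
        hits += sel.selected[0] == "informative"
    return hits / n_seeds


@dataclass
class MorphometricsResult:
    hollowness_accuracy: float
    polarity_accuracy: float
    hollow_scores: np.ndarray
    filled_scores: np.ndarray
    peripheral_scores: np.ndarray
    diffuse_scores: np.ndarray


def morphometrics_experiment(n_per_class: int = 50, base_seed: int = 0,
                             radius_px: int = 40, max_noise: float = 0.2,
                             threshold: float = 0.5) -> MorphometricsResult:
    """Hollow-vs-filled and peripheral-vs-diffuse separation.

    Per class, ``n_per_class`` spheroids with noise levels spread
    uniformly up to ``max_noise`` of the signal intensity.  Hollowness is
    classified at the fixed ``threshold``; polarity with a two-means split
    of the pooled polarity scores.
    """
    seeds = _child_seeds(base_seed, 4 * n_per_class)
    noise = np.linspace(0.0, max_noise, n_per_class)

    def scores(hollow, peripheral, block):
        out = []
        for j in range(n_per_class):
            img = gen_spheroid_image(radius_px=radius_px, hollow=hollow,
                                     peripheral_laminin=peripheral,
                                     noise_sd=noise[j],
                                     seed=seeds[block * n_per_class + j])
            q = quantify_spheroid(img)
            out.append((q["hollowness"], q["polarity"]))
        return np.array(out)

    hollow = scores(True, True, 0)
    filled = scores(False, True, 1)
    peripheral = scores(True, True, 2)
    diffuse = scores(True, False, 3)

    hollow_acc = float(np.mean(np.r_[hollow[:, 0] < threshold,
                                     filled[:, 0] >= threshold]))

    pol = np.r_[peripheral[:, 1], diffuse[:, 1]]
    labels = np.r_[np.ones(n_per_class), np.zeros(n_per_class)]
    cut = _two_means_threshold(pol)
    pol_acc = float(np.mean((pol >= cut) == labels))
    return MorphometricsResult(hollowness_accuracy=hollow_acc,
                               polarity_accuracy=pol_acc,
                               hollow_scores=hollow[:, 0],
                               filled_scores=filled[:, 0],
                               peripheral_scores=peripheral[:, 1],
                               diffuse_scores=diffuse[:, 1])


def _two_means_threshold(values: np.ndarray, n_iter: int = 100) -> float:
    """1-D two-means split point (midpoint of the final centroids)."""
    lo, hi = float(values.min()), float(values.max())
    c = np.array([lo, hi])
    for _ in range(n_iter):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([values[assign == k].mean() if (assign == k).any() else c[k]
                        for k in range(2)])
        if np.allclose(new, c):
            break
        c = new
    return float(c.mean())


def deg_null_experiment(n_seeds: int = 100, base_seed: int = 0,
                        n_genes: int = 2000, n_samples: int = 13,
                        alpha: float = 0.05) -> dict:
    """Flagged fractions under an exchangeable Gaussian null.

    Returns the pooled fraction of genes with nominal p < alpha (expected
    about alpha) and with BH-adjusted q < alpha (expected about 0 — that
    is what FDR control of a global null means).
    """
    nominal, adjusted = [], []
    for seed in _child_seeds(base_seed, n_seeds):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(5.0, 1.0, (n_genes, n_samples)),
                         index=[f"g{i:05d}" for i in range(n_genes)],
                         columns=[f"s{i:02d}" for i in range(n_samples)])
        res = call_deg_one_vs_rest(X, "s00", q_threshold=alpha, already_log=True)
        nominal.append(float((res["p"] < alpha).mean()))
        adjusted.append(float(res["is_deg"].mean()))
    n_total = n_seeds * n_genes
    return {
        "nominal_fraction": float(np.mean(nominal)),
        "adjusted_fraction": float(np.mean(adjusted)),
        "binomial_sd": float(np.sqrt(alpha * (1 - alpha) / n_total)),
        "n_total": n_total,
    }
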