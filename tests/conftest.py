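import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """Noise-free 3-sample panel with one informative pathway."""
    from pathphen import PanelConfig, gen_panel

    cfg = PanelConfig(n_samples=3, n_genes=60, n_pathways=3, pathway_size=10,
                      n_informative=1, effect_slope=1.0, noise_sd=0.0,
                      phenotype_range=(0.0, 2.0), seed=7)
    return gen_panel(cfg)


# ---------------------------------------------------------------------------
# independent oracles (brute-force definitions, no shared code with pathphen)
# ---------------------------------------------------------------------------

def brute_force_gsea_running_sum(metric: np.ndarray, is_hit: np.ndarray,
                                 weight: float = 1.0) -> np.ndarray:
    """Position-by-position running sum of the weighted enrichment walk."""
    n = metric.size
    s = int(is_hit.sum())
    hit_w = np.abs(metric) ** weight
    denom = hit_w[is_hit].sum()
    run = np.zeros(n)
    acc = 0.0
    for i in range(n):
        if is_hit[i]:
            acc += hit_w[i] / denom
        else:
            acc -= 1.0 / (n - s)
        run[i] = acc
    return run


def brute_force_gsea_es(metric: np.ndarray, is_hit: np.ndarray,
                        weight: float = 1.0) -> float:
    """Signed maximum deviation of the running sum (ties toward positive)."""
    if is_hit.all():
        return 1.0
    run = brute_force_gsea_running_sum(metric, is_hit, weight)
    hi, lo = run.max(), min(run.min(), 0.0)
    # same tolerance-aware positive tie-break as the implementation
    return float(hi) if hi >= -lo - 1e-12 else float(lo)


def brute_force_ssgsea(expr: pd.Series, members: set, alpha: float) -> float:
    """ssGSEA by the literal summed-ECDF-difference definition."""
    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    n = len(order)
    ranks = {g: n - i for i, g in enumerate(order)}
    in_genes = [g for g in order if g in members]
    w = {g: ranks[g] ** alpha for g in in_genes}
    wsum = sum(w.values())
    n_out = n - len(in_genes)
    score, cin, cout = 0.0, 0.0, 0.0
    for g in order:
        if g in members:
            cin += w[g] / wsum
        else:
            cout += 1.0 / n_out
        score += cin - cout
    return score
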