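"""PLS1 regression with repeated cross-validation and forward selection.

Partial least squares with a single response (PLS1) extracts latent
components t_k = X_k w_k with unit-norm weight vectors w_k proportional to
X_k' y, deflating X and y after each component.  It is the standard
regression choice when predictors (pathway gene expression or enrichment
scores) far outnumber samples, as in a ~13-line cell panel.  With as many
components as the predictor rank the fit coincides with ordinary least
squares; with few components it regularizes toward the directions of
highest covariance with the response.

Model selection follows a repeated k-fold protocol: out-of-fold
predictions are pooled across all folds and repeats and a single Pearson
correlation against the observed response scores each component count
(pooling is more stable than averaging per-fold correlations when folds
hold only 2-3 samples).  Forward feature selection greedily adds the
feature whose inclusion maximizes that cross-validated correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

log = logging.getLogger(__name__)

DEFAULT_COMPONENTS = (2, 3, 4, 5)


@dataclass
class PlsModel:
    """Fitted PLS1 model with per-component coefficient paths."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray        # p x k, unit-norm columns
    x_loadings: np.ndarray     # p x k
    y_loadings: np.ndarray     # k
    scores: np.ndarray         # n x k, training latent scores
    coef_path: list[np.ndarray]  # coefficient vector after 1..k components
    kept_columns: np.ndarray   # indices of non-constant columns used in the fit
    n_features_in: int
    n_components: int

    @property
    def coef(self) -> np.ndarray:
        return self.coef_path[-1]


def pls1_fit(X, y, n_components: int, scale: bool = True) -> PlsModel:
    """Fit PLS1 by NIPALS on column-centered (and unit-scaled) predictors.

    Zero-variance columns are dropped before scaling.  ``n_components``
    must not exceed min(n_samples - 1, n_usable_features); deflation can
    exhaust the response early, in which case the realized number of
    components is smaller than requested.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p_in = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")

    col_sd = X.std(axis=0, ddof=1) if n > 1 else np.zeros(p_in)
    kept = np.nonzero(col_sd > 0)[0]
    if kept.size == 0:
        raise ValueError("all predictor columns are constant")
    max_comp = min(n - 1, kept.size)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds limit {max_comp}")

    x_mean = X[:, kept].mean(axis=0)
    x_scale = col_sd[kept] if scale else np.ones(kept.size)
    Xk = (X[:, kept] - x_mean) / x_scale
    y_mean = float(y.mean())
    yk = y - y_mean

    p = kept.size
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    coef_path: list[np.ndarray] = []
    k_real = 0
    for k in range(n_components):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.abs(yk).max()):
            break  # response fully deflated
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt <= 1e-30:
            break
        pk = Xk.T @ t / tt
        qk = float(yk @ t) / tt
        Xk = Xk - np.outer(t, pk)
        yk = yk - qk * t
        W[:, k], P[:, k], Q[k], T[:, k] = w, pk, qk, t
        k_real = k + 1
        Wk, Pk, Qk = W[:, :k_real], P[:, :k_real], Q[:k_real]
        coef_path.append(Wk @ np.linalg.solve(Pk.T @ Wk, Qk))

    if k_real == 0:
        # X carries no covariance with y; the model predicts the mean
        coef_path = [np.zeros(p)]
        k_real = 1
    return PlsModel(x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
                    weights=W[:, :k_real], x_loadings=P[:, :k_real],
                    y_loadings=Q[:k_real], scores=T[:, :k_real],
                    coef_path=coef_path, kept_columns=kept,
                    n_features_in=p_in, n_components=k_real)


def pls1_predict(model: PlsModel, X_new, n_components: int | None = None) -> np.ndarray:
    """Predict the response, applying the training centering/scaling."""
    X_new = np.asarray(X_new, float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features_in:
        raise ValueError("feature count mismatch with the fitted model")
    k = model.n_components if n_components is None else n_components
    if not 1 <= k <= model.n_components:
        raise ValueError(f"n_components must be in 1..{model.n_components}")
    Z = (X_new[:, model.kept_columns] - model.x_mean) / model.x_scale
    return model.y_mean + Z @ model.coef_path[min(k, len(model.coef_path)) - 1]


@dataclass
class CvResult:
    best_components: int
    r: float
    per_component_r: dict[int, float] = field(default_factory=dict)
    predictions: dict[int, np.ndarray] = field(default_factory=dict)
    observed: np.ndarray | None = None


def _folds(n: int, n_splits: int, n_repeats: int, seed: int):
    """Repeated shuffled k-fold test-index lists; folds of one sample are
    merged into their neighbor (logged)."""
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed + rep)
        tests = [test for _, test in kf.split(np.arange(n))]
        merged = []
        for test in tests:
            if merged and len(merged[-1]) < 2:
                log.info("merged a singleton CV fold into its neighbor")
                merged[-1] = np.concatenate([merged[-1], test])
            else:
                merged.append(test)
        if len(merged) > 1 and len(merged[-1]) < 2:
            last = merged.pop()
            merged[-1] = np.concatenate([merged[-1], last])
        yield from merged


def cv_plsr_score(X, y, components=DEFAULT_COMPONENTS, n_splits: int = 5,
                  n_repeats: int = 5, seed: int = 1, scale: bool = True) -> CvResult:
    """Repeated k-fold CV of PLS1 over a grid of component counts.

    For each component count, out-of-fold predictions are pooled across
    every fold of every repeat and scored with one Pearson r against the
    observed response; the best (largest r) count wins.  Component counts
    above the per-fold feasibility limit are clamped to it, so small
    feature sets are still scored.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = y.size
    if n < n_splits:
        raise ValueError("need at least n_splits samples")
    components = tuple(sorted(set(int(c) for c in components)))

    preds: dict[int, list[np.ndarray]] = {c: [] for c in components}
    obs: list[np.ndarray] = []
    idx = np.arange(n)
    for test in _folds(n, n_splits, n_repeats, seed):
        train = np.setdiff1d(idx, test)
        ysub = y[train]
        if np.ptp(ysub) == 0:
            continue
        Xtr = X[train]
        usable = int((Xtr.std(axis=0, ddof=1) > 0).sum())
        limit = min(train.size - 1, usable)
        if limit < 1:
            continue
        model = pls1_fit(Xtr, ysub, n_components=min(max(components), limit),
                         scale=scale)
        obs.append(y[test])
        for c in components:
            k = min(c, model.n_components)
            preds[c].append(pls1_predict(model, X[test], n_components=k))

    if not obs:
        raise ValueError("cross-validation produced no usable folds")
    observed = np.concatenate(obs)
    per_comp: dict[int, float] = {}
    pooled: dict[int, np.ndarray] = {}
    for c in components:
        yhat = np.concatenate(preds[c])
        pooled[c] = yhat
        if np.ptp(yhat) == 0 or np.ptp(observed) == 0:
            per_comp[c] = 0.0
        else:
            per_comp[c] = float(stats.pearsonr(observed, yhat).statistic)
    best = max(components, key=lambda c: (per_comp[c], -c))
    return CvResult(best_components=best, r=per_comp[best],
                    per_component_r=per_comp, predictions=pooled,
                    observed=observed)


@dataclass
class SelectionResult:
    selected: list[str]
    score_trajectory: list[float]
    stopped_early: bool


def forward_feature_selection(features: pd.DataFrame, y, n_select: int = 5,
                              scorer=None, **scorer_kwargs) -> SelectionResult:
    """Greedy forward selection maximizing a cross-validated score.

    ``features`` is samples x features; the default scorer is the pooled
    CV Pearson r of a PLS1 model (:func:`cv_plsr_score`).  Candidates are
    scanned in lexicographic column order so ties resolve to the first
    name.  Selection stops early, with a flag, if no remaining candidate
    improves on the current score.
    """
    if n_select > features.shape[1]:
        raise ValueError("n_select exceeds the number of features")
    if scorer is None:
        def scorer(Xsub, yv):
            return cv_plsr_score(Xsub, yv, **scorer_kwargs).r

    y = np.asarray(y, float).ravel()
    remaining = sorted(features.columns.astype(str))
    colmap = {str(c): c for c in features.columns}
    selected: list[str] = []
    trajectory: list[float] = []
    current = -np.inf
    for _ in range(n_select):
        best_name, best_score = None, -np.inf
        for name in remaining:
            cols = [colmap[s] for s in selected + [name]]
            score = scorer(features[cols].to_numpy(float), y)
            if score > best_score:
                best_name, best_score = name, score
        if best_name is None or best_score < current:
            return SelectionResult(selected, trajectory, stopped_early=True)
        selected.append(best_name)
        trajectory.append(best_score)
        remaining.remove(best_name)
        current = best_score
    return SelectionResult(selected, trajectory, stopped_early=False)
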