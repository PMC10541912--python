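"""Signature clustering strength and enrichment-group partitioning.

Given a samples x pathway-signature matrix of per-sample enrichment
scores, these routines quantify how tightly a designated sample group
(e.g. a molecular subtype) clusters under the signature — via the
Calinski-Harabasz (CH) index on a PCA projection — and partition samples
into high/mid/low enrichment groups by Ward agglomerative clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


def pca_project(matrix: pd.DataFrame, n_components: int = 2
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples (rows) onto top principal components.

    Columns are centered; components come from the SVD of the centered
    matrix.  Sign convention: each loading vector's largest-magnitude
    entry is made positive, so projections are deterministic.  Returns
    (scores DataFrame, explained variance ratios).
    """
    X = matrix.to_numpy(float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for PCA")
    if n_components > min(n, p):
        raise ValueError("more components than matrix rank allows")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    scores = U[:, :n_components] * S[:n_components]
    total_var = (S ** 2).sum()
    evr = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), evr


def calinski_harabasz(points, labels) -> float:
    """Calinski-Harabasz index: (SSB/(k-1)) / (SSW/(n-k)).

    SSB is the between-centroid and SSW the within-centroid sum of
    squares.  Larger values mean tighter, better-separated clusters; the
    index is invariant to a common scaling of all points.
    """
    X = np.asarray(points, float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    grand = X.mean(axis=0)
    ssb = 0.0
    ssw = 0.0
    for lab in uniq:
        grp = X[labels == lab]
        cen = grp.mean(axis=0)
        ssb += grp.shape[0] * float(((cen - grand) ** 2).sum())
        ssw += float(((grp - cen) ** 2).sum())
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def signature_clustering_strength(panel: pd.DataFrame, sample_labels: pd.Series,
                                  focus_label: str, n_components: int = 2,
                                  full_space: bool = False) -> float:
    """CH index of the focus group vs the rest under a signature panel.

    ``panel`` is samples x signature scores.  By default the index is
    computed on the 2-component PCA projection of the panel; set
    ``full_space=True`` to use the raw score space.
    """
    labels = sample_labels.reindex(panel.index)
    if labels.isna().any():
        raise KeyError("every sample needs a label")
    if focus_label not in set(labels):
        raise ValueError(f"focus label {focus_label!r} absent from labels")
    binary = np.where(labels == focus_label, focus_label, "rest")
    if full_space:
        pts = panel.to_numpy(float)
    else:
        pts, _ = pca_project(panel, n_components=n_components)
        pts = pts.to_numpy()
    return calinski_harabasz(pts, binary)


def cluster_enrichment_groups(panel: pd.DataFrame, k: int = 3) -> pd.Series:
    """Partition samples into enrichment groups by Ward clustering.

    ``panel`` is samples x signature scores.  Clusters are labeled by
    descending mean enrichment: ``high``/``mid``/``low`` for k = 3, else
    ``group1`` (highest) .. ``groupk``.  Deterministic given the input;
    the labeling does not depend on row order.
    """
    X = panel.to_numpy(float)
    n = X.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of samples")
    if k == n:
        assign = np.arange(n)
    else:
        Z = linkage(X, method="ward")
        assign = fcluster(Z, t=k, criterion="maxclust") - 1
    means = {c: X[assign == c].mean() for c in np.unique(assign)}
    order = sorted(means, key=lambda c: -means[c])
    if k == 3:
        names = ["high", "mid", "low"]
    else:
        names = [f"group{i + 1}" for i in range(k)]
    mapping = {c: names[i] for i, c in enumerate(order)}
    return pd.Series([mapping[c] for c in assign], index=panel.index, name="group")
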