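"""Classical MDS on correlation distance, and agglomerative clustering.

Sample-to-sample distances are 1 - Pearson correlation; classical
(metric, Torgerson) MDS double-centers the squared distance matrix and
embeds on the leading eigenvectors, reporting per-axis variance explained
over positive eigenvalues. Gene/sample dendrograms for heatmap cluster
definitions come from average-linkage agglomeration (scipy linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform


@dataclass
class MDSResult:
    coordinates: pd.DataFrame       # item x k
    eigenvalues: np.ndarray         # length k, nonincreasing
    variance_explained: np.ndarray  # per coordinate, over positive eigenvalues
    warnings: list[str] = field(default_factory=list)


def correlation_distance(values: pd.DataFrame, axis: str = "samples") -> pd.DataFrame:
    """d_ij = 1 - Pearson r_ij between columns (samples) or rows (probes)."""
    if axis == "probes":
        values = values.T
    elif axis != "samples":
        raise ValueError(f"axis must be 'samples' or 'probes', got {axis!r}")
    sd = values.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant vector(s): {list(constant.index)}")
    d = 1.0 - values.corr(method="pearson")
    np.fill_diagonal(d.values, 0.0)
    return d


def classical_mds(distances: pd.DataFrame, k: int = 2) -> MDSResult:
    """Torgerson scaling: B = -1/2 J D^2 J, embed on top-k eigenvectors.

    Negative eigenvalues (non-Euclidean distances) contribute zero
    coordinates and are excluded from the variance-explained denominator.
    If fewer than k positive eigenvalues exist, trailing coordinates are
    zero-padded and a warning is recorded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = distances.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    warnings = []
    n_pos = int((eigval > 1e-12).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.append(
            f"only {n_pos} positive eigenvalues; coordinates {k_eff + 1}..{k} zero-padded"
        )
    coords = np.zeros((n, k))
    coords[:, :k_eff] = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    pos_sum = eigval[eigval > 1e-12].sum()
    var_exp = np.zeros(k)
    if pos_sum > 0:
        var_exp[:k_eff] = eigval[:k_eff] / pos_sum
    return MDSResult(
        coordinates=pd.DataFrame(
            coords, index=distances.index, columns=[f"MDS{i+1}" for i in range(k)]
        ),
        eigenvalues=eigval[:k],
        variance_explained=var_exp,
        warnings=warnings,
    )


def hierarchical_cluster(distances: pd.DataFrame, method: str = "average") -> np.ndarray:
    """Agglomerative merge sequence (scipy linkage matrix) on a distance matrix."""
    if distances.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    condensed = squareform(distances.to_numpy(dtype=float), checks=False)
    return linkage(condensed, method=method)


def cut_tree_k(Z: np.ndarray, k: int, labels: list[str] | None = None) -> pd.Series:
    """Cut a linkage matrix into exactly k clusters (labels 1..k by first
    appearance)."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = cut_tree(Z, n_clusters=k).ravel()
    # relabel in order of first appearance for determinism
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    index = labels if labels is not None else range(n)
    return pd.Series(out, index=index, name="cluster")


def cophenetic_distances(Z: np.ndarray) -> np.ndarray:
    """Condensed cophenetic distance vector of a linkage matrix."""
    return cophenet(Z)
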