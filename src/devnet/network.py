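"""Signed weighted gene co-expression network construction and modules.

The network is built from pairwise Pearson correlations of probe profiles
across samples, mapped to connection strengths

    a_ij = ((1 + r_ij) / 2) ** beta,   beta = 16 by default,

so that anticorrelated probes are unconnected (signed network). The
topological overlap between two probes combines their direct connection
with the connections they share:

    TO_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{u != i} a_iu. Genes are clustered by average
linkage on the dissimilarity 1 - TO and modules are carved out of the
dendrogram with an adaptive branch cut: candidate branches are the
maximal subtrees assembled below a static cut height, each is split
wherever two sub-branches of at least ``min_module_size`` leaves have
both assembled well below their join (``deep_split`` controls how small
that height gap may be), and loosely attached stragglers are peeled off.
Leaves on no accepted branch are labeled "unassigned".

Each module is summarized by its eigengene (ME) — the first principal
component of the standardized module submatrix across samples — and each
probe by its module membership kME = cor(probe, ME); kME > 0.7 defines
hub genes, kME < 0.3 non-hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

#: height-gap thresholds (as a fraction of the dissimilarity scale) that a
#: dendrogram branch must clear to be accepted as a module, indexed by
#: deep_split 0..4; larger deep_split accepts shallower splits.
_GAP_BY_DEEP_SPLIT = (0.30, 0.20, 0.10, 0.05, 0.02)


def signed_adjacency(values: pd.DataFrame, beta: float = 16.0) -> pd.DataFrame:
    """Signed soft-thresholded adjacency ((1 + r) / 2) ** beta."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    sd = values.std(axis=1, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(
            f"constant probe(s) (remove upstream): {list(constant.index[:5])}"
        )
    r = np.corrcoef(values.to_numpy(dtype=float))
    np.clip(r, -1.0, 1.0, out=r)
    a = ((1.0 + r) / 2.0) ** beta
    return pd.DataFrame(a, index=values.index, columns=values.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a (signed) weighted adjacency.

    Matrix form: with diagonal zeroed, the shared-neighbor term for a pair
    (i, j) is (A @ A)_ij minus nothing extra, because the diagonal is
    already excluded. TO_ii = 1 by convention.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # sum_u a_iu a_uj, u != i and u != j since diag(A) = 0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    numer = shared + A
    with np.errstate(divide="ignore", invalid="ignore"):
        to = np.where(np.abs(denom) < 1e-12, 0.0, numer / denom)
    np.fill_diagonal(to, 1.0)
    return pd.DataFrame(to, index=adjacency.index, columns=adjacency.columns)


@dataclass
class ModuleAssignment:
    labels: pd.Series                   # probe -> "M1".."Mk" / "unassigned"
    dendrogram: np.ndarray              # scipy linkage matrix on 1 - TO
    module_sizes: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        sizes = self.labels.value_counts()
        modules = sorted(
            (m for m in sizes.index if m != "unassigned"),
            key=lambda m: int(m[1:]),
        )
        if "unassigned" in sizes.index:
            modules.append("unassigned")
        self.module_sizes = sizes.reindex(modules)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_sizes.index if m != "unassigned"]

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _branch_cut(
    Z: np.ndarray, min_module_size: int, min_gap: float, cut_height: float
) -> list[np.ndarray]:
    """Adaptive branch decomposition of a linkage matrix.

    Two stages. First, a static cut at ``cut_height`` yields candidate
    branches (maximal subtrees fully assembled below the cut); in a sparse
    random network, probe pairs reach dissimilarity ~1 and survive the cut
    only as fragments, so noise stays unassigned. Second, each candidate
    is split recursively: a join is divided when BOTH sub-branches hold at
    least ``min_module_size`` leaves and both have assembled well below
    the join — their mean internal merge height at least ``min_gap``
    under the join height. Using the bulk (mean) height rather than the
    branch top makes the rule robust to stragglers that attach to a tight
    branch just below the height where it joins its neighbor.
    """
    n = Z.shape[0] + 1
    n_nodes = n + Z.shape[0]
    leaves: list[np.ndarray] = [np.array([i]) for i in range(n)]
    heights = np.zeros(n_nodes)
    sum_heights = np.zeros(n_nodes)  # sum of internal merge heights
    for m, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        leaves.append(np.concatenate([leaves[a], leaves[b]]))
        heights[n + m] = h
        sum_heights[n + m] = sum_heights[a] + sum_heights[b] + h

    def size(node: int) -> int:
        return len(leaves[node])

    def bulk_height(node: int) -> float:
        return 0.0 if node < n else sum_heights[node] / (size(node) - 1)

    # maximal nodes with height <= cut_height (parent above the cut);
    # iterative walks: dendrograms can be deep enough to break recursion
    candidates: list[int] = []
    stack = [n_nodes - 1]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        if heights[node] <= cut_height:
            candidates.append(node)
        else:
            stack.extend((int(Z[node - n, 0]), int(Z[node - n, 1])))

    modules: list[np.ndarray] = []
    for cand in candidates:
        if size(cand) < min_module_size:
            continue
        stack = [cand]
        while stack:
            node = stack.pop()
            if node < n or size(node) < min_module_size:
                continue
            a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
            h = heights[node]
            big_a, big_b = size(a) >= min_module_size, size(b) >= min_module_size
            far_a = h - bulk_height(a) >= min_gap
            far_b = h - bulk_height(b) >= min_gap
            if big_a and big_b and far_a and far_b:
                stack.extend((a, b))          # two distinct branches
            elif big_a and not big_b and far_a:
                stack.append(a)               # peel straggler clump b
            elif big_b and not big_a and far_b:
                stack.append(b)               # peel straggler clump a
            else:
                modules.append(leaves[node])  # cohesive branch: accept whole
    return modules


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    merge_cut_height: float | None = None,
    values: pd.DataFrame | None = None,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TO plus adaptive branch cutting.

    ``deep_split`` in 0..4 tunes split sensitivity (larger = smaller
    height gaps accepted = more, finer modules). Modules are labeled
    "M1", "M2", ... in order of descending size; probes on no accepted
    branch are "unassigned". If ``merge_cut_height`` is given (requires
    ``values``), modules whose eigengenes correlate above
    1 - merge_cut_height are merged post hoc.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    if deep_split not in range(5):
        raise ValueError("deep_split must be in 0..4")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    branches = _branch_cut(Z, min_module_size, _GAP_BY_DEEP_SPLIT[deep_split], cut_height)

    labels = pd.Series("unassigned", index=tom.index, name="module", dtype=object)
    for m, branch in enumerate(
        sorted(branches, key=lambda b: (-len(b), b.min())), start=1
    ):
        labels.iloc[branch] = f"M{m}"
    assignment = ModuleAssignment(labels=labels, dendrogram=Z)

    if merge_cut_height is not None:
        if values is None:
            raise ValueError("merging by ME correlation requires the expression values")
        assignment = _merge_close_modules(assignment, values, merge_cut_height)
    return assignment


def _merge_close_modules(
    assignment: ModuleAssignment, values: pd.DataFrame, merge_cut_height: float
) -> ModuleAssignment:
    """Union modules whose MEs correlate above 1 - merge_cut_height."""
    while True:
        mods = assignment.modules
        if len(mods) < 2:
            return assignment
        me = module_eigengenes(values, assignment)
        corr = np.corrcoef(me.scores.to_numpy())
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < 1.0 - merge_cut_height:
            return assignment
        keep, drop = mods[i], mods[j]
        labels = assignment.labels.copy()
        labels[labels == drop] = keep
        # relabel by descending size again
        sizes = labels[labels != "unassigned"].value_counts()
        rename = {old: f"M{r}" for r, old in enumerate(sizes.index, start=1)}
        labels = labels.map(lambda x: rename.get(x, x))
        assignment = ModuleAssignment(labels=labels, dendrogram=assignment.dendrogram)


@dataclass
class EigengeneMatrix:
    scores: pd.DataFrame            # module x sample, unit-norm rows
    variance_explained: pd.Series   # per module, PC1 share


def module_eigengenes(values: pd.DataFrame, modules: ModuleAssignment) -> EigengeneMatrix:
    """First principal component of each module's standardized submatrix.

    Probes are standardized (mean 0, SD 1 across samples) before the PCA
    so high-variance probes do not dominate. Each ME has unit norm and is
    signed so that it correlates nonnegatively with the module's mean
    standardized profile.
    """
    scores = {}
    var_exp = {}
    for module in modules.modules:
        members = modules.members(module)
        if len(members) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 probes")
        sub = values.loc[members].to_numpy(dtype=float)
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        # SVD of probes x samples; right singular vector = sample-space PC1
        _, s, vt = np.linalg.svd(sub, full_matrices=False)
        me = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        scores[module] = me
        var_exp[module] = float(s[0] ** 2 / (s**2).sum())
    return EigengeneMatrix(
        scores=pd.DataFrame(scores, index=values.columns).T,
        variance_explained=pd.Series(var_exp, name="variance_explained"),
    )


def module_membership(
    values: pd.DataFrame,
    me: EigengeneMatrix,
    modules: ModuleAssignment | None = None,
    hub: float = 0.7,
    nonhub: float = 0.3,
) -> pd.DataFrame:
    """kME table: Pearson correlation of every probe with every ME.

    When a module assignment is given, columns ``kME_own``, ``hub`` and
    ``nonhub`` record each probe's membership in its own module and the
    hub / non-hub classification (intermediate probes are neither).
    """
    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)
    E = me.scores.to_numpy(dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    En = Ec / np.linalg.norm(Ec, axis=1, keepdims=True)
    kme = pd.DataFrame(
        Xn @ En.T, index=values.index, columns=[f"kME_{m}" for m in me.scores.index]
    )
    if modules is not None:
        own = np.full(len(kme), np.nan)
        for i, probe in enumerate(kme.index):
            mod = modules.labels[probe]
            if mod != "unassigned":
                own[i] = kme.at[probe, f"kME_{mod}"]
        kme["kME_own"] = own
        kme["hub"] = kme["kME_own"] > hub
        kme["nonhub"] = kme["kME_own"] < nonhub
    return kme


def trait_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Sample x trait design: one indicator per region and age level plus
    a numeric age_months column."""
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    cols = {}
    for region in sorted(meta["region"].unique()):
        cols[f"region_{region}"] = (meta["region"] == region).astype(float)
    for age in sorted(meta["age_months"].unique()):
        cols[f"age_{age}"] = (meta["age_months"] == age).astype(float)
    cols["age_months"] = meta["age_months"].astype(float)
    return pd.DataFrame(cols, index=meta.index)


def module_trait_correlation(
    me: EigengeneMatrix, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each ME with each trait column, with
    two-sided p-values from the t transform (n - 2 df)."""
    design = design.loc[me.scores.columns]
    if (design.std(ddof=1) == 0).any():
        bad = list(design.columns[design.std(ddof=1) == 0])
        raise ValueError(f"constant trait column(s): {bad}")
    n = design.shape[0]
    E = me.scores.to_numpy(dtype=float)
    T = design.to_numpy(dtype=float)
    Ec = (E - E.mean(axis=1, keepdims=True))
    Ec /= np.linalg.norm(Ec, axis=1, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)
    Tc /= np.linalg.norm(Tc, axis=0, keepdims=True)
    r = np.clip(Ec @ Tc, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    idx, cols = me.scores.index, design.columns
    return (
        pd.DataFrame(r, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
    )


def export_top_edges(
    weights: pd.DataFrame,
    modules: ModuleAssignment,
    module: str,
    n: int = 200,
    kme: pd.DataFrame | None = None,
    hub: float = 0.7,
) -> pd.DataFrame:
    """Top-n within-module edges by descending weight (ties by probe pair).

    ``weights`` may be the TOM or the adjacency. Columns: probe1, probe2,
    weight, and hub flags per endpoint when a kME table is supplied.
    """
    members = modules.members(module)
    if len(members) < 2:
        raise ValueError(f"module {module!r} has fewer than 2 probes")
    sub = weights.loc[members, members]
    rows = []
    for i, p1 in enumerate(members):
        for p2 in members[i + 1:]:
            a, b = sorted((p1, p2))
            rows.append((a, b, float(sub.at[p1, p2])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    edges = pd.DataFrame(rows[:n], columns=["probe1", "probe2", "weight"])
    if kme is not None and "kME_own" in kme.columns:
        for side in ("probe1", "probe2"):
            edges[f"{side}_hub"] = (
                kme.loc[edges[side], "kME_own"].to_numpy() > hub
            )
    return edges
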