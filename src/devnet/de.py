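"""One-way ANOVA differential expression with BH FDR and fold-change rules.

Two one-way fixed-effects F-tests — one with brain region as the factor,
one with age — define region- and age-enriched probes at a BH FDR of 0.01.
Age-specific effects use a relaxed FDR of 0.05 combined with a greater
than two-fold difference (Δlog2 > 1) between some pair of ages within a
region, and each flagged probe is labeled with the age whose group mean is
most extreme relative to the other ages. Age is always treated as an
unordered categorical factor; fold changes are differences of group mean
log2 values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DEResult:
    """Per-probe ANOVA statistics for one factor.

    ``table`` columns: F, p, q, one ``mean_<level>`` column per factor
    level, max_abs_log2_diff, flag, and (for age-specific analyses)
    age_of_effect and effect_sign.
    """

    factor: str
    table: pd.DataFrame

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flag"]])


def _group_masks(meta: pd.DataFrame, factor: str) -> dict[object, np.ndarray]:
    col = {"age": "age_months", "region": "region"}.get(factor, factor)
    if col not in meta.columns:
        raise ValueError(f"metadata lacks a {col!r} column")
    return {
        level: (meta[col] == level).to_numpy()
        for level in sorted(meta[col].unique(), key=str)
    }


def one_way_anova(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    factor: str,
    subset: list[str] | None = None,
) -> DEResult:
    """Vectorized one-way fixed-effects ANOVA over all probes.

    F = MS_between / MS_within with df (k-1, N-k); p is the upper tail of
    the F distribution. When both between- and within-group sums of
    squares vanish for a probe, p is 1 by convention.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    if subset is not None:
        meta = meta.loc[[s for s in meta.index if s in set(subset)]]
    values = values[meta.index]
    masks = _group_masks(meta, factor)
    if len(masks) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels in subset")
    small = [lvl for lvl, m in masks.items() if m.sum() < 2]
    if small:
        raise ValueError(f"levels with < 2 samples: {small}")

    X = values.to_numpy(dtype=float)
    n_total = X.shape[1]
    k = len(masks)
    grand = X.mean(axis=1)
    ss_between = np.zeros(len(X))
    ss_within = np.zeros(len(X))
    means = {}
    for level, mask in masks.items():
        sub = X[:, mask]
        mu = sub.mean(axis=1)
        means[level] = mu
        ss_between += mask.sum() * (mu - grand) ** 2
        ss_within += ((sub - mu[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_between / ms_within
    p = stats.f.sf(F, df_b, df_w)
    # zero variance everywhere: no evidence of an effect
    degenerate = (ss_within == 0) & (ss_between == 0)
    F[degenerate] = 0.0
    p[degenerate] = 1.0
    # perfect separation with zero within-group variance
    exact = (ss_within == 0) & (ss_between > 0)
    F[exact] = np.inf
    p[exact] = 0.0

    max_diff = np.zeros(len(X))
    for a, b in combinations(masks, 2):
        max_diff = np.maximum(max_diff, np.abs(means[a] - means[b]))

    table = pd.DataFrame({"F": F, "p": p}, index=values.index)
    for level, mu in means.items():
        table[f"mean_{level}"] = mu
    table["max_abs_log2_diff"] = max_diff
    return DEResult(factor=factor, table=table)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((arr < 0) | (arr > 1)) or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(arr)
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_by_factor(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    factor: str,
    fdr: float = 0.01,
    subset: list[str] | None = None,
) -> DEResult:
    """ANOVA plus BH adjustment; flag = (q < fdr)."""
    result = one_way_anova(values, meta, factor, subset=subset)
    result.table["q"] = bh_adjust(result.table["p"].to_numpy())
    result.table["flag"] = result.table["q"] < fdr
    return result


def age_pair_fold_changes(
    values: pd.DataFrame, meta: pd.DataFrame, region: str
) -> pd.Series:
    """Per-probe max |Δ mean log2| over all age pairs within one region.

    fold > 2 corresponds to a statistic > 1 on the log2 scale.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    sub = meta[meta["region"] == region]
    ages = sorted(sub["age_months"].unique())
    expected = sorted(meta["age_months"].unique())
    if ages != expected:
        raise ValueError(f"region {region!r} is missing age levels: "
                         f"have {ages}, expect {expected}")
    X = values[sub.index].to_numpy(dtype=float)
    means = {a: X[:, (sub["age_months"] == a).to_numpy()].mean(axis=1) for a in ages}
    out = np.zeros(len(values))
    for a, b in combinations(ages, 2):
        out = np.maximum(out, np.abs(means[a] - means[b]))
    return pd.Series(out, index=values.index, name=f"max_age_fc_{region}")


def _age_of_effect(table: pd.DataFrame, levels: list[object]) -> tuple[list, list]:
    """Most-extreme-level labeling: the age whose mean deviates most from
    the mean of the remaining ages; sign of that deviation recorded."""
    means = table[[f"mean_{lvl}" for lvl in levels]].to_numpy()
    k = means.shape[1]
    others = (means.sum(axis=1, keepdims=True) - means) / (k - 1)
    dev = means - others
    idx = np.abs(dev).argmax(axis=1)
    labels = [levels[i] for i in idx]
    signs = np.sign(dev[np.arange(len(dev)), idx]).astype(int).tolist()
    return labels, signs


def age_specific_de(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    fdr: float = 0.05,
    log2_fc: float = 1.0,
    scope: str = "any_region",
) -> DEResult:
    """Age-associated probes with a required fold change within a region.

    A probe is flagged when its age-ANOVA q-value (computed over the
    samples in scope) is below ``fdr`` and its largest age-pair log2
    difference exceeds ``log2_fc`` — within the named region, or within
    any single region when ``scope="any_region"``. Flagged probes are
    labeled with the age of effect (most-extreme level rule).
    """
    meta_ix = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    regions = sorted(meta_ix["region"].unique())
    if scope == "any_region":
        result = de_by_factor(values, meta, "age", fdr=fdr)
        fc = pd.concat(
            [age_pair_fold_changes(values, meta, r) for r in regions], axis=1
        ).max(axis=1)
    else:
        if scope not in regions:
            raise ValueError(f"unknown region {scope!r}")
        samples = list(meta_ix.index[meta_ix["region"] == scope])
        result = de_by_factor(values, meta, "age", fdr=fdr, subset=samples)
        fc = age_pair_fold_changes(values, meta, scope)
    table = result.table
    table["max_abs_log2_diff"] = fc
    table["flag"] = (table["q"] < fdr) & (fc > log2_fc)
    ages = sorted(meta_ix["age_months"].unique())
    labels, signs = _age_of_effect(table, ages)
    table["age_of_effect"] = labels
    table["effect_sign"] = signs
    table.loc[~table["flag"], ["age_of_effect"]] = np.nan
    return result


def per_region_age_anova(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    fdr: float = 0.05,
    log2_fc: float = 1.0,
    region_groups: dict[str, list[str]] | None = None,
) -> dict[str, DEResult]:
    """Independent age ANOVAs per region (BH within each region's family).

    ``region_groups`` may pool regions under a composite name, e.g.
    ``{"neocortex": ["mPFC", "V1"]}`` pools the two cortical areas.
    """
    meta_ix = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    if region_groups is None:
        region_groups = {r: [r] for r in sorted(meta_ix["region"].unique())}
    out = {}
    for name, members in region_groups.items():
        sub = meta_ix[meta_ix["region"].isin(members)].copy()
        sub["region"] = name
        merged = pd.concat(
            [sub, meta_ix[~meta_ix.index.isin(sub.index)]]
        ).loc[meta_ix.index]
        out[name] = age_specific_de(
            values, merged.reset_index(), fdr=fdr, log2_fc=log2_fc, scope=name
        )
    return out


def top_n_by_pvalue(de: DEResult, n: int = 1000) -> list[str]:
    """The ``n`` probes with smallest p; ties by larger F, then probe id."""
    if n > len(de.table):
        raise ValueError(f"n={n} exceeds {len(de.table)} probes")
    t = de.table
    order = sorted(t.index, key=lambda pr: (t.at[pr, "p"], -t.at[pr, "F"], pr))
    return order[:n]


def overlap_sets(named_sets: dict[str, set]) -> pd.DataFrame:
    """All Venn cells of >= 2 named sets.

    Returns a table indexed by membership pattern (a '+'-joined sorted
    tuple of set names) with the count of elements exactly in those sets.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(named_sets)
    universe = set().union(*named_sets.values())
    cells: dict[str, int] = {}
    for el in universe:
        pattern = "+".join(n for n in names if el in named_sets[n])
        cells[pattern] = cells.get(pattern, 0) + 1
    return pd.DataFrame(
        {"count": pd.Series(cells)}
    ).rename_axis("membership").sort_index()
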