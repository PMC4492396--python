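"""Sample-level quality control and probe-level preprocessing.

The QC model follows the sample-network approach used for microarray
studies: every pair of arrays is correlated over all probes (inter-array
correlation, IAC), and an array whose mean IAC is both below an absolute
floor (default 0.95) and more than a set number of standard deviations
below the cohort mean is treated as a technical outlier and removed.
Removal is iterative: after dropping the worst array the statistics are
recomputed, because a gross outlier inflates the spread and can mask a
second one.

Preprocessing then proceeds in the order the QC model assumes:
quantile normalization of the surviving arrays, log2 transform (if the
input is on the linear intensity scale), a detection-call presence
filter, and selection of the most variable probes for network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_LEVELS = ("mPFC", "V1", "HIP", "AMY", "STRv")
AGE_LEVELS = (0, 3, 12, 48)


class DegenerateSampleError(ValueError):
    """A sample column has zero variance, so Pearson correlation is undefined."""


@dataclass
class IACReport:
    """Pairwise inter-array correlations and per-sample summaries.

    Attributes
    ----------
    iac : pd.DataFrame
        Symmetric sample x sample Pearson correlation matrix, unit diagonal.
    mean_iac : pd.Series
        Per-sample mean correlation with all *other* samples.
    flagged : dict[str, list[str]]
        sample id -> reasons, each reason one of ``"mean_r"``, ``"sd"``.
        Populated by :func:`detect_outliers`.
    """

    iac: pd.DataFrame
    mean_iac: pd.Series
    flagged: dict[str, list[str]] = field(default_factory=dict)


def inter_array_correlations(values: pd.DataFrame) -> IACReport:
    """Compute the full sample x sample Pearson correlation matrix.

    Parameters
    ----------
    values : pd.DataFrame
        probe x sample expression matrix (any monotone scale; log2 by
        convention here). Must have >= 3 samples and no constant column.
    """
    if values.shape[1] < 3:
        raise ValueError(f"need >= 3 samples for IAC, got {values.shape[1]}")
    sd = values.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise DegenerateSampleError(
            f"constant expression column(s): {list(constant.index)}"
        )
    iac = values.corr(method="pearson")
    n = iac.shape[0]
    # mean of off-diagonal entries per sample
    mean_iac = (iac.sum(axis=1) - 1.0) / (n - 1)
    return IACReport(iac=iac, mean_iac=mean_iac)


def _flag_once(
    mean_iac: pd.Series,
    mean_r_threshold: float,
    sd_threshold: float,
    exclude_self: bool = True,
) -> dict[str, list[str]]:
    flags: dict[str, list[str]] = {}
    for sample, r in mean_iac.items():
        if exclude_self:
            others = mean_iac.drop(sample)
        else:
            others = mean_iac
        mu, sd = others.mean(), others.std(ddof=1)
        reasons = []
        if r < mean_r_threshold:
            reasons.append("mean_r")
        # one-sided: only unusually LOW mean IAC marks an outlier; with a
        # degenerate spread any strictly lower value counts
        if (mu - r) > sd_threshold * sd:
            reasons.append("sd")
        if reasons:
            flags[str(sample)] = reasons
    return flags


def detect_outliers(
    report: IACReport,
    mean_r_threshold: float = 0.95,
    sd_threshold: float = 2.0,
    iterative: bool = True,
    require_both: bool = True,
    exclude_self: bool = True,
) -> list[str]:
    """Identify outlier arrays from an IAC report.

    A sample is *flagged* when its mean IAC falls below ``mean_r_threshold``
    (reason ``"mean_r"``) and/or lies more than ``sd_threshold`` standard
    deviations below the mean of the *other* samples' mean IACs (reason
    ``"sd"``; one-sided, since a high IAC cannot indicate a bad array;
    set ``exclude_self=False`` to include the candidate in the mean/SD).
    With
    ``require_both=True`` (default) a sample is only *removed* when it fails
    both criteria. With ``iterative=True`` the worst flagged sample is
    removed and the criteria recomputed until none remain.

    Returns the removed sample ids in removal order; reasons for every
    sample ever flagged are recorded on ``report.flagged``.
    """
    iac = report.iac
    remaining = list(iac.index)
    removed: list[str] = []
    while True:
        if len(remaining) < 3:
            raise ValueError("fewer than 3 samples remain during outlier iteration")
        sub = iac.loc[remaining, remaining]
        mean_iac = (sub.sum(axis=1) - 1.0) / (len(remaining) - 1)
        flags = _flag_once(mean_iac, mean_r_threshold, sd_threshold, exclude_self)
        report.flagged.update(flags)
        if require_both:
            candidates = [s for s, r in flags.items() if len(r) == 2]
        else:
            candidates = list(flags)
        if not candidates:
            break
        worst = min(candidates, key=lambda s: mean_iac[s])
        removed.append(worst)
        remaining.remove(worst)
        if not iterative:
            break
    return removed


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of rank-wise means.

    Each column is sorted, the mean across columns is taken at every rank,
    and each column's values are replaced by the rank-matched means. Tied
    values within a column receive the mean of the reference values their
    ranks span, which keeps the operation deterministic and idempotent.
    """
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values are not allowed in quantile normalization")
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    if np.array_equiv(sorted_vals, sorted_vals[:, :1]):
        # all columns already share one distribution; the rank-wise mean is
        # that distribution exactly (avoids 1-ULP drift, keeps idempotence)
        reference = sorted_vals[:, 0]
    else:
        reference = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = np.empty(n, dtype=np.intp)
        ranks[order[:, j]] = np.arange(n)
        col = reference[ranks]
        # average the reference over runs of ties in the original column
        uniq, inv = np.unique(arr[:, j], return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=col, minlength=len(uniq))
            counts = np.bincount(inv, minlength=len(uniq))
            col = (sums / counts)[inv]
        out[:, j] = col
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log2_transform(values: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise ``log2(x + offset)``; errors on nonpositive arguments."""
    shifted = values + offset
    bad = shifted <= 0
    if bad.to_numpy().any():
        locs = np.argwhere(bad.to_numpy())
        r, c = locs[0]
        raise ValueError(
            f"nonpositive value at probe {values.index[r]!r}, "
            f"sample {values.columns[c]!r} with offset {offset}"
        )
    return np.log2(shifted)


def presence_filter(
    calls: pd.DataFrame,
    meta: pd.DataFrame,
    fraction: float = 0.75,
    marginal_is_present: bool = False,
) -> list[str]:
    """Retain probes robustly detected in at least one region or age group.

    A probe passes when the proportion of Present calls reaches ``fraction``
    within at least one region group or at least one age group. Marginal
    calls count as not-Present unless ``marginal_is_present``.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    calls = calls[meta.index]
    present = calls == "P"
    if marginal_is_present:
        present = present | (calls == "M")
    keep = pd.Series(False, index=calls.index)
    for factor in ("region", "age_months"):
        for _, group in meta.groupby(factor, observed=True):
            if len(group) == 0:
                raise ValueError(f"empty {factor} group in metadata")
            frac = present[group.index].mean(axis=1)
            keep |= frac >= fraction
    return list(keep.index[keep])


def top_variance_probes(values: pd.DataFrame, n: int = 20000) -> list[str]:
    """Probe ids with the ``n`` largest sample variances (ddof=1).

    Ties are broken by probe id ascending; the result is ordered by
    descending variance.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > len(values):
        raise ValueError(f"n={n} exceeds probe count {len(values)}")
    var = values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda p: (-var[p], p))
    return order[:n]
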