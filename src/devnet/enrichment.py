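"""Hypergeometric enrichment of disease gene lists in co-expression modules.

Network probes are collapsed to unique human gene symbols: unmapped
probes are dropped, and a gene whose probes land in several modules is
assigned to the module of its highest-kME probe. The background universe
is the set of unique mapped genes among network probes. Every (gene list,
module) pair with at least ``min_module_genes`` unique genes in the
module is tested with the hypergeometric upper tail, and p-values are BH-
corrected jointly across the whole table. The same machinery compares two
module partitions (module-vs-module overlap tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .network import ModuleAssignment


def collapse_probes_to_genes(
    modules: ModuleAssignment,
    annotation: pd.Series,
    kme_own: pd.Series | None = None,
) -> tuple[dict[str, set[str]], set[str]]:
    """Collapse probe-level module assignments to unique gene sets.

    Parameters
    ----------
    annotation : pd.Series
        probe -> gene symbol; empty string or NaN marks an unmapped probe.
    kme_own : pd.Series, optional
        probe -> kME to its own module, used to pick the representative
        probe for genes hit by probes in different modules. Without it the
        first module by label order wins.

    Returns ``(module -> gene set, background)`` where background is every
    unique mapped gene among the assigned or unassigned network probes.
    """
    annotation = annotation.reindex(modules.labels.index)
    mapped = annotation.fillna("").astype(str).str.strip().str.upper()
    keep = mapped != ""
    if not keep.any():
        raise ValueError("no probe maps to a gene symbol")
    background = set(mapped[keep])

    gene_best: dict[str, tuple[float, str]] = {}
    for probe in modules.labels.index[keep]:
        module = modules.labels[probe]
        if module == "unassigned":
            continue
        gene = mapped[probe]
        score = float(kme_own.get(probe, np.nan)) if kme_own is not None else np.nan
        score = -np.inf if np.isnan(score) else score
        if gene not in gene_best or score > gene_best[gene][0]:
            gene_best[gene] = (score, module)
    gene_sets: dict[str, set[str]] = {m: set() for m in modules.modules}
    for gene, (_, module) in gene_best.items():
        gene_sets[module].add(gene)
    return gene_sets, background


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` background genes of which ``K`` are in the list; ``n`` drawn
    (module size); ``k`` observed overlap. Computed via the stable
    survival function of :class:`scipy.stats.hypergeom`.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # columns: gene_list, module, N, K, n, k, p, q, flag, overlap

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]


def enrich_all(
    module_gene_sets: dict[str, set[str]],
    gene_lists: dict[str, set[str]],
    background: set[str],
    min_module_genes: int = 20,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric tests for all (list, eligible module) combinations.

    Modules with fewer than ``min_module_genes`` unique genes are excluded
    before testing. Lists are intersected with the background. BH runs
    jointly over the full table; significance is q < alpha.
    """
    N = len(background)
    if N == 0:
        raise ValueError("empty background universe")
    eligible = {
        m: s & background
        for m, s in module_gene_sets.items()
        if len(s & background) >= min_module_genes
    }
    rows = []
    for list_name in sorted(gene_lists):
        in_bg = {g.upper() for g in gene_lists[list_name]} & background
        for module in sorted(eligible, key=lambda m: (len(m), m)):
            genes = eligible[module]
            overlap = sorted(in_bg & genes)
            p = hypergeometric_upper_tail(len(overlap), len(in_bg), len(genes), N)
            rows.append(
                {
                    "gene_list": list_name,
                    "module": module,
                    "N": N,
                    "K": len(in_bg),
                    "n": len(genes),
                    "k": len(overlap),
                    "p": p,
                    "overlap": ",".join(overlap),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["flag"] = table["q"] < alpha
    else:
        table["q"] = pd.Series(dtype=float)
        table["flag"] = pd.Series(dtype=bool)
    return EnrichmentResult(table=table)


def module_overlap_test(
    modules_a: dict[str, set[str]],
    modules_b: dict[str, set[str]],
    background: set[str] | None = None,
) -> pd.DataFrame:
    """Pairwise hypergeometric overlap between two module partitions.

    Both partitions must live in the same symbol space; the background
    defaults to the union of all genes in either partition. Returns one
    row per (A-module, B-module) pair with overlap count, p and BH q.
    """
    genes_a = set().union(*modules_a.values()) if modules_a else set()
    genes_b = set().union(*modules_b.values()) if modules_b else set()
    if background is None:
        background = genes_a | genes_b
    if not (genes_a & background) or not (genes_b & background):
        import warnings

        warnings.warn("module sets share no symbols with the background")
        return pd.DataFrame(
            columns=["module_a", "module_b", "N", "K", "n", "k", "p", "q"]
        )
    N = len(background)
    rows = []
    for ma in sorted(modules_a):
        A = modules_a[ma] & background
        for mb in sorted(modules_b):
            B = modules_b[mb] & background
            k = len(A & B)
            p = hypergeometric_upper_tail(k, len(A), len(B), N)
            rows.append(
                {"module_a": ma, "module_b": mb, "N": N, "K": len(A),
                 "n": len(B), "k": k, "p": p}
            )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table
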