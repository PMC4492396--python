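"""End-to-end orchestration: QC -> normalization -> filtering -> DE/MDS ->
network -> enrichment, with a machine-readable run manifest.

Stage order mirrors the analysis it reimplements: inter-array-correlation
outlier removal on log2 data, quantile normalization of the survivors,
detection-call presence filtering, top-variance probe selection for the
network, two one-way ANOVAs (age, region), age-specific DE, per-region
ANOVAs, classical MDS of samples, signed network construction with module
detection, eigengene/trait correlation, and hypergeometric enrichment of
gene lists in modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import de, enrichment, io, network, ordination, qc


@dataclass
class PipelineConfig:
    """Thresholds and settings of one pipeline run."""

    expression: str | None = None
    metadata: str | None = None
    calls: str | None = None
    annotation: str | None = None
    gene_lists: str | None = None
    out_dir: str = "devnet_out"
    data_scale: str = "log2"            # "log2" or "linear"
    mean_r_threshold: float = 0.95
    sd_threshold: float = 2.0
    presence_fraction: float = 0.75
    top_n_variance: int = 20000
    de_fdr: float = 0.01
    age_specific_fdr: float = 0.05
    log2_fc: float = 1.0
    beta: float = 16.0
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float | None = None
    min_module_genes: int = 20
    mds_components: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.presence_fraction <= 1:
            raise ValueError(
                f"presence_fraction must lie in [0, 1], got {self.presence_fraction}"
            )
        if self.data_scale not in ("log2", "linear"):
            raise ValueError("data_scale must be 'log2' or 'linear'")
        if not 0 < self.de_fdr < 1 or not 0 < self.age_specific_fdr < 1:
            raise ValueError("FDR thresholds must lie in (0, 1)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)
    status: str = "RUNNING"

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "status": self.status, "stages": self.stages},
            indent=2,
            default=str,
        )


def run_pipeline(
    config: PipelineConfig,
    expression: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    annotation: pd.Series | None = None,
    gene_lists: dict[str, set[str]] | None = None,
    write_outputs: bool = True,
) -> RunManifest:
    """Run the full analysis; inputs come from files unless given in-memory.

    Writes all stage outputs as TSVs under ``config.out_dir`` plus a
    ``manifest.json``; on a stage failure a FAILED marker naming the stage
    is left next to whatever partial outputs exist.
    """
    config.validate()
    manifest = RunManifest(config=asdict(config))
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        if expression is None:
            expression = io.read_expression(config.expression)
        if metadata is None:
            metadata = io.read_metadata(config.metadata)
        if calls is None and config.calls:
            calls = io.read_calls(config.calls)
        if annotation is None and config.annotation:
            annotation = io.read_annotation(config.annotation)
        if gene_lists is None and config.gene_lists:
            gene_lists = io.read_gmt(config.gene_lists)
        meta_ix = metadata.set_index("sample_id")
        manifest.record(stage, n_probes=len(expression), n_samples=expression.shape[1])

        stage = "log2_transform"
        if config.data_scale == "linear":
            expression = qc.log2_transform(expression)
        manifest.record(stage, scale=config.data_scale)

        stage = "qc_outliers"
        report = qc.inter_array_correlations(expression)
        removed = qc.detect_outliers(
            report, config.mean_r_threshold, config.sd_threshold
        )
        kept = [s for s in expression.columns if s not in removed]
        expression = expression[kept]
        meta_ix = meta_ix.loc[kept]
        if calls is not None:
            calls = calls[kept]
        manifest.record(
            stage,
            samples_removed=len(removed),
            removed_ids=removed,
            samples_remaining=len(kept),
        )
        if write_outputs:
            io.write_table(report.mean_iac.to_frame("mean_iac"), out / "iac_report.tsv",
                           index_label="sample_id")

        stage = "quantile_normalize"
        expression = qc.quantile_normalize(expression)
        manifest.record(stage, n_samples=expression.shape[1])

        stage = "presence_filter"
        if calls is not None:
            retained = qc.presence_filter(
                calls, meta_ix.reset_index(), config.presence_fraction
            )
            manifest.record(
                stage,
                probes_in=len(expression),
                probes_retained=len(retained),
                probes_filtered=len(expression) - len(retained),
            )
            expression = expression.loc[retained]
        else:
            manifest.record(stage, skipped=True, probes_retained=len(expression))

        stage = "differential_expression"
        meta_reset = meta_ix.reset_index()
        age_de = de.de_by_factor(expression, meta_reset, "age", fdr=config.de_fdr)
        region_de = de.de_by_factor(expression, meta_reset, "region", fdr=config.de_fdr)
        age_specific = de.age_specific_de(
            expression, meta_reset, fdr=config.age_specific_fdr, log2_fc=config.log2_fc
        )
        per_region = de.per_region_age_anova(
            expression, meta_reset, fdr=config.age_specific_fdr, log2_fc=config.log2_fc
        )
        manifest.record(
            stage,
            n_age_de=len(age_de.flagged),
            n_region_de=len(region_de.flagged),
            n_age_specific=len(age_specific.flagged),
            per_region_de={r: len(res.flagged) for r, res in per_region.items()},
        )
        if write_outputs:
            io.write_table(age_de.table, out / "de_age.tsv", index_label="probe_id")
            io.write_table(region_de.table, out / "de_region.tsv", index_label="probe_id")
            io.write_table(age_specific.table, out / "de_age_specific.tsv",
                           index_label="probe_id")

        stage = "mds"
        dist = ordination.correlation_distance(expression, axis="samples")
        mds = ordination.classical_mds(dist, k=config.mds_components)
        manifest.record(
            stage,
            variance_explained=[round(float(v), 4) for v in mds.variance_explained],
        )
        if write_outputs:
            io.write_table(mds.coordinates, out / "mds_coordinates.tsv",
                           index_label="sample_id")

        stage = "network"
        # zero-variance probes (e.g. rank-constant after quantile
        # normalization) carry no correlation signal and are dropped
        varying = expression[expression.var(axis=1, ddof=1) > 0]
        top = qc.top_variance_probes(
            varying, min(config.top_n_variance, len(varying))
        )
        net_expr = expression.loc[top]
        adj = network.signed_adjacency(net_expr, beta=config.beta)
        tom = network.topological_overlap(adj)
        modules = network.detect_modules(
            tom,
            min_module_size=config.min_module_size,
            deep_split=config.deep_split,
            merge_cut_height=config.merge_cut_height,
            values=net_expr,
        )
        me = network.module_eigengenes(net_expr, modules)
        kme = network.module_membership(net_expr, me, modules)
        design = network.trait_design(meta_ix.reset_index())
        corr, pvals = network.module_trait_correlation(me, design)
        manifest.record(
            stage,
            n_network_probes=len(top),
            n_modules=len(modules.modules),
            module_sizes={m: int(s) for m, s in modules.module_sizes.items()},
            n_unassigned=int((modules.labels == "unassigned").sum()),
        )
        if write_outputs:
            io.write_table(
                pd.DataFrame({"module": modules.labels, "kME_own": kme["kME_own"],
                              "hub": kme["hub"]}),
                out / "modules.tsv", index_label="probe_id",
            )
            io.write_table(me.scores, out / "module_eigengenes.tsv",
                           index_label="module")
            io.write_table(corr, out / "module_trait_correlation.tsv",
                           index_label="module")
            io.write_table(pvals, out / "module_trait_pvalues.tsv",
                           index_label="module")

        stage = "enrichment"
        if annotation is not None and gene_lists and modules.modules:
            gene_sets, background = enrichment.collapse_probes_to_genes(
                modules, annotation, kme_own=kme["kME_own"]
            )
            result = enrichment.enrich_all(
                gene_sets, gene_lists, background,
                min_module_genes=config.min_module_genes,
            )
            n_hits = int(result.table["flag"].sum()) if len(result.table) else 0
            manifest.record(
                stage,
                background_genes=len(background),
                n_tests=len(result.table),
                n_significant=n_hits,
            )
            if write_outputs:
                io.write_table(result.table, out / "enrichment.tsv", index=False)
        else:
            manifest.record(stage, skipped=True)

        manifest.status = "OK"
    except Exception as err:
        manifest.status = f"FAILED at {stage}: {err}"
        if write_outputs:
            (out / "FAILED").write_text(manifest.status + "\n")
        raise
    finally:
        if write_outputs:
            (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
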