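"""Synthetic expression data with the structure the pipeline assumes.

The generator emulates a postnatal primate brain study design: five brain
regions (mPFC, V1, HIP, AMY, STRv) sampled at four ages (0, 3, 12 and 48
months) in three animals per age, giving 60 arrays. On top of per-probe
baseline levels it plants

* co-expression modules, each driven by a latent eigengene that is a
  linear combination of region indicators, age indicators and a numeric
  age ramp (so modules can be regional, temporal, or mixed);
* differentially expressed probes with group-mean shifts by age or region;
* optionally one grossly corrupted array, mimicking a failed chip;
* a probe-to-gene map with unmapped and duplicated symbols.

Everything is returned together with the ground truth needed for
parameter-recovery tests (true module labels, latent eigengenes, true DE
sets, true outliers).

Values are on the log2 scale throughout; per-probe baselines are drawn
around ``baseline_log2`` with a spread chosen so that replicate arrays
correlate at R ~ 0.96-0.98 over all probes, as is typical for expression
arrays that pass QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import AGE_LEVELS, REGION_LEVELS

#: trait keys understood by module_trait_profiles, besides region names:
#: "age_<m>" for an age-indicator contrast and "age_ramp" for a monotone
#: increase with developmental stage.
DEFAULT_MODULE_PROFILES: tuple[dict[str, float], ...] = (
    {"age_ramp": -3.0},                 # early-high, declining with age
    {"age_ramp": 3.0},                  # rising with age
    {"age_0": 3.0},                     # birth-specific burst
    {"mPFC": 2.0, "V1": 2.0},           # neocortical
    {"HIP": 3.0, "age_ramp": 1.5},      # regional + temporal mix
)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Effect sizes in ``module_trait_profiles`` and the DE effect sizes are
    in units of ``within_module_noise_sd`` and log2 units respectively.
    """

    n_probes: int = 2000
    regions: tuple[str, ...] = REGION_LEVELS
    ages: tuple[int, ...] = AGE_LEVELS
    n_animals_per_age: int = 3
    module_sizes: tuple[int, ...] = (200, 120, 80, 50, 30)
    module_trait_profiles: tuple[dict[str, float], ...] = DEFAULT_MODULE_PROFILES
    within_module_noise_sd: float = 0.5
    n_age_de: int = 100
    age_de_log2fc: float = 2.0
    n_region_de: int = 100
    region_de_log2fc: float = 2.0
    background_noise_sd: float = 0.5
    baseline_log2: float = 8.0
    probe_baseline_sd: float = 6.0
    outlier_samples: tuple[tuple[str, float], ...] = ()
    absent_fraction: float = 0.10
    unmapped_fraction: float = 0.10
    duplicate_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) + self.n_age_de + self.n_region_de > self.n_probes:
            raise ValueError(
                "module_sizes plus planted DE probes exceed n_probes "
                f"({sum(self.module_sizes)} + {self.n_age_de} + "
                f"{self.n_region_de} > {self.n_probes})"
            )
        if len(self.module_trait_profiles) < len(self.module_sizes):
            raise ValueError("need one trait profile per module")
        for sd in (
            self.within_module_noise_sd,
            self.background_noise_sd,
        ):
            if sd <= 0:
                raise ValueError(f"noise SDs must be positive, got {sd}")
        for frac in (self.absent_fraction, self.unmapped_fraction, self.duplicate_fraction):
            if not 0 <= frac <= 1:
                raise ValueError(f"fractions must lie in [0, 1], got {frac}")


@dataclass
class GroundTruth:
    """What was actually planted, for recovery tests."""

    module_labels: pd.Series            # probe -> "M1".."Mk" or "unassigned"
    eigengenes: pd.DataFrame            # module x sample latent profiles (unit SD)
    de_probes: dict[str, list[str]]     # factor ("age"/"region") -> probe ids
    outlier_samples: list[str]
    probe_to_gene: pd.Series            # probe -> symbol ("" if unmapped)


def _sample_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for age_i, age in enumerate(config.ages):
        for animal in range(1, config.n_animals_per_age + 1):
            animal_id = f"A{age_i * config.n_animals_per_age + animal:02d}"
            for region in config.regions:
                rows.append(
                    {
                        "sample_id": f"{region}_{age}m_{animal_id}",
                        "region": region,
                        "age_months": age,
                        "animal_id": animal_id,
                    }
                )
    return pd.DataFrame(rows)


def _trait_vector(trait: str, meta: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    if trait in config.regions:
        return (meta["region"] == trait).to_numpy(float)
    if trait == "age_ramp":
        # monotone in developmental stage; rank-based so 0->3 months counts
        # as much as 12->48 (log-like developmental time)
        ranks = {a: i for i, a in enumerate(config.ages)}
        return meta["age_months"].map(ranks).to_numpy(float)
    if trait.startswith("age_"):
        age = int(trait[4:])
        return (meta["age_months"] == age).to_numpy(float)
    raise ValueError(f"unknown trait {trait!r}")


def _latent_eigengene(
    profile: dict[str, float], meta: pd.DataFrame, config: SyntheticConfig
) -> tuple[np.ndarray, float]:
    """Standardized latent profile and its amplitude in log2 units."""
    raw = np.zeros(len(meta))
    for trait, weight in profile.items():
        z = _trait_vector(trait, meta, config)
        z = (z - z.mean()) / z.std()
        raw += weight * z
    sd = raw.std()
    if sd == 0:
        raise ValueError(f"degenerate trait profile {profile}")
    amplitude = float(np.sqrt(sum(w * w for w in profile.values())))
    return raw / sd, amplitude * config.within_module_noise_sd


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one dataset.

    Returns ``(expression, metadata, detection_calls, annotation, truth)``
    where expression is a probe x sample log2 matrix, detection_calls is a
    P/M/A matrix of the same shape, and annotation maps probe ids to human
    gene symbols (blank where unmapped). Bit-identical for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config)
    n_samples = len(meta)
    probe_ids = [f"PR{i:05d}" for i in range(config.n_probes)]

    baselines = config.baseline_log2 + config.probe_baseline_sd * rng.standard_normal(
        config.n_probes
    )
    X = baselines[:, None] + config.background_noise_sd * rng.standard_normal(
        (config.n_probes, n_samples)
    )

    # planted modules occupy the first probes, then age-DE, then region-DE
    labels = pd.Series("unassigned", index=probe_ids, name="module")
    eigengenes = {}
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        latent, amplitude = _latent_eigengene(
            config.module_trait_profiles[m - 1], meta, config
        )
        block = slice(pos, pos + size)
        X[block] += amplitude * latent[None, :]
        labels.iloc[block] = f"M{m}"
        eigengenes[f"M{m}"] = latent
        pos += size

    de_probes: dict[str, list[str]] = {"age": [], "region": []}
    for factor, count, effect in (
        ("age", config.n_age_de, config.age_de_log2fc),
        ("region", config.n_region_de, config.region_de_log2fc),
    ):
        levels = list(config.ages if factor == "age" else config.regions)
        col = "age_months" if factor == "age" else "region"
        for i in range(count):
            level = levels[int(rng.integers(len(levels)))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mask = (meta[col] == level).to_numpy()
            X[pos + i, mask] += sign * effect
            de_probes[factor].append(probe_ids[pos + i])
        pos += count

    expr = pd.DataFrame(X, index=probe_ids, columns=meta["sample_id"].tolist())

    outliers = []
    for sample_id, corruption_sd in config.outlier_samples:
        expr = inject_outlier(expr, sample_id, corruption_sd, rng=rng)
        outliers.append(sample_id)

    # detection calls: a random subset of background probes is Absent
    # everywhere; everything else Present with a sprinkle of Marginal
    calls = np.full((config.n_probes, n_samples), "P", dtype="<U1")
    n_structured = pos
    n_absent = int(round(config.absent_fraction * config.n_probes))
    absent_pool = np.arange(n_structured, config.n_probes)
    if n_absent > len(absent_pool):
        n_absent = len(absent_pool)
    absent_rows = rng.choice(absent_pool, size=n_absent, replace=False)
    calls[absent_rows, :] = "A"
    marginal = rng.random((config.n_probes, n_samples)) < 0.01
    calls[marginal & (calls == "P")] = "M"
    calls_df = pd.DataFrame(calls, index=probe_ids, columns=expr.columns)

    # probe -> gene map with unmapped and duplicated symbols
    symbols = np.array([f"GENE{i:05d}" for i in range(config.n_probes)], dtype=object)
    n_dup = int(round(config.duplicate_fraction * config.n_probes))
    if n_dup:
        dup_targets = rng.choice(config.n_probes, size=n_dup, replace=False)
        dup_sources = rng.choice(config.n_probes, size=n_dup, replace=True)
        symbols[dup_targets] = symbols[dup_sources]
    n_unmapped = int(round(config.unmapped_fraction * config.n_probes))
    if n_unmapped:
        unmapped = rng.choice(config.n_probes, size=n_unmapped, replace=False)
        symbols[unmapped] = ""
    annot = pd.DataFrame({"probe_id": probe_ids, "gene_symbol": symbols})

    truth = GroundTruth(
        module_labels=labels,
        eigengenes=pd.DataFrame(eigengenes, index=expr.columns).T,
        de_probes=de_probes,
        outlier_samples=outliers,
        probe_to_gene=pd.Series(symbols, index=probe_ids, name="gene_symbol"),
    )
    return expr, meta, calls_df, annot, truth


def inject_outlier(
    expr: pd.DataFrame,
    sample_id: str,
    corruption_sd: float,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Return a copy of ``expr`` with Gaussian noise added to one column."""
    if sample_id not in expr.columns:
        raise KeyError(f"unknown sample {sample_id!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    out = expr.copy()
    if corruption_sd > 0:
        out[sample_id] = out[sample_id] + corruption_sd * rng.standard_normal(len(expr))
    return out


def default_outlier_config(seed: int = 0, corruption_sd: float = 3.0) -> SyntheticConfig:
    """Default design plus one corrupted striatum array at birth."""
    cfg = SyntheticConfig(seed=seed)
    sample = f"STRv_{cfg.ages[0]}m_A01"
    cfg.outlier_samples = ((sample, corruption_sd),)
    return cfg


def generate_gene_lists(
    truth: GroundTruth,
    target_module: str,
    in_module_fraction: float,
    list_size: int,
    seed: int = 0,
    name: str | None = None,
) -> tuple[str, set[str]]:
    """Build a gene list with a controlled overlap with one planted module.

    ``round(in_module_fraction * list_size)`` symbols come from the target
    module's mapped genes, the rest from mapped genes outside it.
    """
    if not 0 <= in_module_fraction <= 1:
        raise ValueError("in_module_fraction must lie in [0, 1]")
    mapped = truth.probe_to_gene[truth.probe_to_gene != ""]
    in_module = sorted(set(mapped[truth.module_labels[mapped.index] == target_module]))
    out_module = sorted(set(mapped) - set(in_module))
    if not in_module and in_module_fraction > 0:
        raise ValueError(f"module {target_module!r} has no mapped genes")
    n_in = round(in_module_fraction * list_size)
    n_out = list_size - n_in
    if n_in > len(in_module) or n_out > len(out_module):
        raise ValueError(
            f"list_size {list_size} exceeds available genes "
            f"(module {len(in_module)}, background {len(out_module)})"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(in_module, size=n_in, replace=False)) + list(
        rng.choice(out_module, size=n_out, replace=False)
    )
    return (name or f"list_{target_module}", set(chosen))
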