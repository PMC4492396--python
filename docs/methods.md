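# Methods

This note documents the models and procedures `devnet` implements, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter when
reproducing results.

## Study design assumed

The pipeline is built around a balanced two-factor bulk expression
design: R brain regions × A ages × n animals, one array per
(region, age, animal) cell. The defaults mirror a postnatal rhesus
macaque design: regions {mPFC, V1, HIP, AMY, STRv}, ages
{0, 3, 12, 48} months, three animals per age, 60 arrays. Animals are
treated as exchangeable replicates: all ANOVAs are one-way
fixed-effects, with no random effect for animal. Age is always an
unordered categorical factor in testing; a numeric age covariate exists
only in the module–trait design matrix.

## Sample QC

For arrays i, j the inter-array correlation IAC(i,j) is the Pearson
correlation of their full log2 expression vectors. Sample i's summary
is its mean IAC over the other arrays. Two criteria flag an outlier:

* **absolute**: mean IAC < `mean_r_threshold` (default 0.95);
* **relative**: mean IAC more than `sd_threshold` (default 2) standard
  deviations below the mean of the *other* samples' means (one-sided;
  an unusually high IAC is never evidence of a failed chip).

The relative criterion is leave-one-out: the candidate is excluded from
the location and scale it is compared against, so a gross outlier
cannot mask itself by inflating the spread. By default a sample is only
removed when it fails **both** criteria (`require_both=True`), and
removal is iterative — drop the worst array, recompute, repeat — since
one gross outlier perturbs every other array's mean IAC. Both choices
are exposed as flags. Iteration refuses to go below 3 remaining arrays.

QC runs on log2 data *before* quantile normalization; normalization is
applied to the surviving arrays only, so a corrupted array never
contaminates the reference distribution.

## Quantile normalization

Every column is replaced by the rank-matched means of the sorted
columns. Ties within a column receive the mean of the reference values
their ranks span, which makes the map deterministic and exactly
idempotent; when all columns already share one distribution the
reference is taken as that distribution directly rather than re-averaged
(a floating-point mean of k identical values need not reproduce the
value bit-for-bit).

## Probe filtering

Presence filtering keeps a probe when the fraction of Present detection
calls reaches 0.75 within at least one region group or one age group —
a probe robustly expressed only in, say, hippocampus, or only at birth,
survives. Marginal calls count as not-Present by default (flag to
change). Variance selection ranks probes by unbiased sample variance
(N−1), ties broken by probe id, and keeps the top 20 000 (or all, if
fewer). Probes with exactly zero variance — possible after quantile
normalization when a probe occupies the same rank in every array — are
excluded before network construction, since their correlations are
undefined.

## Differential expression

One-way fixed-effects ANOVA per probe, F = MS_between/MS_within with
df (k−1, N−k), vectorized over probes. Degenerate probes (zero between-
and within-group variance) get p = 1; perfect separation (zero within,
positive between) gets p = 0. Benjamini–Hochberg adjustment is the
standard step-up, one family per ANOVA run. Main DE calls use FDR
< 0.01.

Fold changes are differences of group-mean log2 values, so "fold > 2"
is Δlog2 > 1; no anti-logging. Age-specific DE combines the age-ANOVA
q-value (FDR < 0.05) with max pairwise age difference > 1 within a
region — within any single region when scope is `"any_region"` (the
q-value then comes from the all-sample age ANOVA), or within the named
region (q-value from that region's samples only). Flagged probes are
labeled with an **age of effect**: the age whose group mean deviates
most from the mean of the remaining ages, with the sign of that
deviation. This most-extreme-level rule is one reasonable convention —
nothing in the model forces it — and is only attached to flagged
probes. Per-region analyses rerun the same machinery per region with BH
within each region's probe family; regions can be pooled (e.g. a
neocortex composite of mPFC + V1) through `region_groups`.

## Ordination

Sample distances are 1 − Pearson correlation (range [0, 2]). Classical
(Torgerson) MDS double-centers the squared distance matrix,
eigendecomposes, and scales the top-k eigenvectors by √eigenvalue.
Correlation distances are not guaranteed Euclidean, so negative
eigenvalues can appear: they contribute zero coordinates and are
excluded from the variance-explained denominator (variance explained =
λᵢ / Σ positive λ). If fewer than k positive eigenvalues exist the
remaining coordinates are zero-padded and a warning is recorded on the
result. Tests compare reconstructed distances and eigenvalues, never
raw coordinate signs, which are arbitrary.

Gene/sample dendrograms for heatmap-style cluster definitions use
average linkage (scipy); the linkage choice is configurable since
nothing downstream depends on it.

## Signed co-expression network

* **Adjacency** aᵢⱼ = ((1 + rᵢⱼ)/2)^β, β = 16. The signed map sends
  r = −1 to 0, so anticorrelated genes are unconnected; β sharpens the
  map (raising β weakens every connection with |r| < 1 — a property
  test). β is fixed, not fitted: no scale-free-topology selection.
* **Topological overlap** TOᵢⱼ = (Σ_{u≠i,j} aᵢᵤaᵤⱼ + aᵢⱼ) /
  (min(kᵢ,kⱼ) + 1 − aᵢⱼ), kᵢ = Σ_{u≠i} aᵢᵤ, TOᵢᵢ = 1, computed in
  matrix form (diagonal zeroed so the shared-neighbor sum excludes the
  endpoints). Denominators below 1e-12 yield TO = 0. Clustering runs on
  the dissimilarity 1 − TO.

### Module detection (adaptive branch cut)

Modules come from a two-stage cut of the average-linkage dendrogram,
implemented from scratch:

1. **Static cut** at `cut_height` (default 0.99 on the 1 − TO scale).
   Candidate branches are the maximal subtrees fully assembled below the
   cut. Probe pairs in a sparse random network have dissimilarity ≈ 1,
   so under the null the forest below 0.99 is fragments smaller than
   `min_module_size` and everything stays unassigned.
2. **Recursive split with straggler peeling.** Within a candidate, a
   join is split when **both** sub-branches have at least
   `min_module_size` leaves and both have *bulk* assembly heights — the
   mean of a subtree's internal merge heights — at least `min_gap`
   below the join. When only one side is large and lies well below the
   join, the small side is peeled off as a straggler and descent
   continues; when neither condition holds the whole branch is one
   module. Using the bulk height rather than the branch top makes the
   rule robust to caterpillar-like attachment of weakly connected
   probes just under a join, which would otherwise erase the height gap
   between two real modules.

`deep_split` ∈ {0..4} maps to `min_gap` ∈ {0.30, 0.20, 0.10, 0.05,
0.02} (default 2 → 0.10): larger values accept shallower splits and
produce more, finer modules. `min_module_size` defaults to 30 and must
be ≥ 3. Labels are "M1", "M2", … by descending size; leaves in no
accepted branch are "unassigned". Optional post-hoc merging unions
modules whose eigengenes correlate above 1 − `merge_cut_height`
(off by default).

On planted data (five modules, sizes 30–200, within-module noise SD
0.5, 60 arrays) this cut recovers the planted partition with adjusted
Rand index ≳ 0.95 and leaves pure-noise matrices entirely unassigned;
both behaviors are pinned by tests.

### Eigengenes, kME, traits

Module probes are standardized (mean 0, SD 1 across samples) before the
module's PCA so high-variance probes cannot dominate PC1; the eigengene
is the first right singular vector (unit norm), signed so its
correlation with the module's mean standardized profile is nonnegative.
kME is the Pearson correlation of each probe with each eigengene; hub
genes have kME > 0.7 to their own module, non-hubs < 0.3, the rest are
unlabeled. Module–trait analysis correlates eigengenes with a design of
one indicator column per region, one per age, plus numeric months;
p-values use the t transform with n − 2 df. Edge export returns the top
within-module pairs by TOM (or adjacency) weight, ties broken by probe
pair.

## Enrichment

Unmapped probes are dropped. A gene hit by probes in different modules
is assigned to the module of its highest-kME probe (ties and missing
kME fall back to the first module encountered). The background universe
is every unique mapped gene among network probes — including genes on
unassigned probes — configurable upstream by passing a different
annotation. Modules with fewer than 20 unique background genes are
excluded from testing. For each (list, module) pair the upper-tail
hypergeometric probability P(X ≥ k) is computed with the stable
survival function; BH runs jointly over the whole list × module table
(per-list correction is a caller-side option by testing lists
separately). Module-vs-module overlap between two partitions uses the
same tail over a shared background. Symbol matching is case-insensitive
exact match; no alias resolution.

## Synthetic data generator

The generator produces log2-scale probe × sample matrices with the
statistical structure the pipeline assumes, plus ground truth:

* **Baselines.** Per-probe baseline ~ N(8, 6²) log2 units. The spread
  is what makes arrays correlate: with the default structure and noise
  the clean arrays have mean IAC ≈ 0.97, i.e. the generator emulates
  arrays that *pass* the 0.95 QC floor, as the study design assumes for
  retained samples.
* **Modules.** Each planted module has a latent eigengene: a linear
  combination of region indicators, age indicators and a monotone
  age-rank ramp (per-module trait profile), standardized to unit
  variance and scaled by ‖profile‖ × noise SD. Module probes are
  baseline + scaled latent + i.i.d. N(0, noise²). Effect sizes are in
  units of the within-module noise SD; the default profiles give two
  opposite age ramps, a birth-specific burst, a neocortical module and
  a mixed hippocampus/age module — the regional, temporal and mixed
  patterns the analysis is meant to resolve. With effect 3 and noise
  0.5 the within-module correlation is ≈ 0.9.
* **DE probes.** Separate background probes receive a ±2 log2 shift of
  one random age (or region) level.
* **Outliers.** A named array gets independent N(0, corruption²) noise
  added (default configuration: the birth-age striatum array,
  corruption SD 3).
* **Detection calls.** A configurable fraction of background probes is
  Absent in all samples; ~1% of remaining calls are Marginal.
* **Annotation.** Probe → symbol map with configurable unmapped and
  duplicated-symbol fractions, to exercise collapsing.
* **Gene lists.** `generate_gene_lists` draws a controlled fraction of
  a list from one module's mapped genes, the rest from outside — the
  positive control for enrichment.

Everything is driven by one `numpy` generator seeded from the config:
fixed config ⇒ bit-identical outputs.

**What it does not emulate:** probe-level intensity distributions and
scanner artifacts (values are already summarized, noise is Gaussian and
homoscedastic on the log2 scale), correlated noise between probes
outside planted modules, animal (replicate) random effects, batch
structure, and realistic gene-symbol vocabularies. Consequently,
passing recovery tests shows the algorithms are correct under the
assumed model, not that the model captures every failure mode of real
microarray data — in particular, heteroscedastic or heavy-tailed noise
could degrade β = 16 networks in ways these tests will not reveal.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at 700–2 000 probes
and 59–60 arrays, with 10–50 seeded replicates per recovery benchmark —
sizes at which the planted-structure checks are already
well-conditioned while the whole suite stays fast. All randomness flows
through explicit seeds; reruns are bit-identical, and the end-to-end
manifest is verified identical across repeated runs.

## Known limitations

* The branch cut is an original implementation of the adaptive
  tree-cut idea; it does not reproduce any specific published
  implementation merge-for-merge, and module counts on real data will
  depend on `deep_split` and `cut_height`.
* Tie-breaking inside the agglomeration follows scipy's deterministic
  convention; with continuous data ties have probability zero.
* No blockwise processing: the full TOM is held in memory, practical to
  ~20 000 probes (≈ 3.2 GB double precision).
* One-way ANOVAs ignore animal pairing across regions; a mixed model
  would be more efficient for designs with strong animal effects.
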