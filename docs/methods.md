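# Methods

This note records the models, numerical choices and known limitations of
`traitscape`, in the order the pipeline runs.

## Synthetic world

The generator produces every input the mapping-and-evaluation workflow
needs, with the statistical structure such data have in the field.

**Landscape.** An `n_rows × n_cols` equal-area grid (nominal 20-km cell
edge, metadata only). Elevation is a broad Gaussian ridge (0–~2600 m)
plus Gaussian-filtered white noise (σ = 3 cells); the three environmental
covariates are a temperature-like row gradient, a precipitation-like
column gradient, and an elevation-tracking layer, each with its own
smoothed noise. All layers are therefore spatially autocorrelated, which
the range, abundance and SAR machinery downstream assumes.

**Species pool.** Log body mass ~ N(3.5, 1.2²) (median ≈ 33 g) and log
generation length ~ N(1.0, 0.4²) (median ≈ 2.7 y) give the right-skewed
natural-scale distributions typical of bird assemblages. Migratory
class frequencies default to non-migrant 0.60 / latitudinal 0.30 /
altitudinal 0.07 / nomad 0.03 and diet classes to invertebrate 0.45 /
mixed 0.20 / fruit 0.10 / plant 0.10 / vertebrate 0.10 / nectar 0.05 — a
temperate-avifauna-like mix; both are configurable. Elevational limits
are drawn wide enough that refinement prunes ranges without routinely
emptying them.

**Abundance surfaces.** Expected local abundance is log-linear in the
standardized covariates, `λ_s(cell) = exp(b0_s + Σ_j b_js z_j(cell))`,
with `b0_s ~ N(1.0, 1.0²)` (median λ ≈ 2.7 individuals per cell, a
strongly right-skewed species-abundance distribution) and env slopes
~ N(0, 0.3²). The log-linear form itself is a modelling convenience:
real spatial abundance surfaces are unknown, and this form is a
configurable stand-in, not a claim. `trait_abundance_coupling` adds
`coupling × z(log mass)` to `b0`; at 0 (the default) local abundance is
unrelated to every trait — the null regime in which ignoring abundance
is harmless — and positive values create the biased regime.

**Population bookkeeping.** Each species' regional total is its expected
per-cell abundance × unrefined range size; dividing by a drawn occupied-
area fraction (U(0.5, 1)) and widening by a relative uncertainty
(U(0.2, 0.8)) yields the global min/max interval, so the
midpoint-×-area-fraction rule recovers a regional total consistent with
the simulated surfaces.

**Ranges.** Contiguous cell sets grown from a seed cell by uniform-random
4-neighbour accretion. Contiguity is the only property of real extent-of-
occurrence polygons the pipeline uses, so nothing fancier is warranted.

**Surveys.** Counts are `Poisson(λ × effort × p)`, with log-normal
observer-hours (default median 8 h, σ_log 0.4) and a per-species logistic
detection probability in z(log mass), migratory class and z(log range
size) (defaults: intercept 1.5, mass 0.5, range 0.5, migrant offsets up
to 0.5 — detection is good but trait-biased, as found for real count
schemes; `DetectabilityModel.perfect()` switches it off). Detection
affects only the simulated surveys, never the truth maps. Records are
emitted, including zero counts, for every site–year–species combination
with positive true abundance.

What the generator does **not** emulate: commission/omission errors in
the range maps themselves (inside its refined range a species is truly
present everywhere), phylogenetic trait correlation, temporal population
trends, and real georeferencing. Passing end-to-end tests therefore show
the estimators behave correctly *when the range maps are right*; they say
nothing about polygon quality in real atlases.

## Ranges and stacking

Elevational refinement keeps exactly the extent cells whose elevation
lies inside the species' reported limits, bounds inclusive. Cell
elevation is the single grid value — effectively the cell mean — so a
species straddling its limit inside one cell is kept or dropped by that
mean; real data at 20-km resolution face the same ambiguity. Species
whose refined range is empty stay in the stack as all-zero rows (and are
logged), keeping species indexing stable. The stack is serialized as a
sparse occupancy CSV plus a species-index CSV: plain text, diffable, and
loss-free for binary data.

## Abundance schemes

All four schemes produce zero abundance outside each species' refined
range, and each covers only the species whose inputs exist
(`eligible_species`): uniform covers everything, pop_over_range the
species with population estimates, survey_mean the species recorded at
≥ 1 training site, env_model the species with ≥ `min_records` (default
30) training-site records. `restrict_to_species` supports comparisons on
the common subset.

**Effort correction.** One rule everywhere a survey abundance is needed:
divide each count by its observer-hours, average over the years in which
the species was recorded (zero-count years do not enter), round up to the
nearest integer. The round-up means any recorded species has abundance
≥ 1.

**Environmental models (scheme d).** Per species, an additive model with
one fixed 5-df B-spline smooth per covariate (no automatic smoothness
selection — the effective degrees of freedom are the point), log link by
default. The default family is Poisson-type on the integer
effort-corrected abundances: it shares the mean structure
`log μ = β₀ + Σ f_j(z_j)` with a Gaussian log-link fit but its IRLS is
far better behaved; Gaussian log-link and Gaussian identity are available
via `gam_family`. Noiseless data make the IRLS degenerate (the fit is
exact), in which case the identical mean structure is obtained in closed
form by least squares on the (log) response. Predictions clamp each
covariate to its training min/max before evaluating the splines —
unbounded spline extrapolation produces absurd abundances on large
grids — and are floored at zero; a constant training response short-
circuits to a constant model.

## Metrics

**Gower distances.** Mean over the four traits of range-normalized
absolute differences (continuous) and class-mismatch indicators
(categorical). Continuous traits are normalized by the *global* pool
range, never per community, so distances are comparable across cells; a
zero-range trait contributes 0 (no discriminating information). Species
with missing trait values are rejected — the pipeline's synthetic traits
are complete by construction, mirroring the upstream exclusion of
incomplete species in real compilations.

**PCoA.** Classical metric scaling: double-centre `−D²/2`, symmetric
eigendecomposition, drop axes with eigenvalue ≤ max(λ)·1e-10, scale
eigenvectors by √λ. For Euclidean-embeddable D the embedding reproduces
the distances to numerical precision (tested at 1e-6).

**Convex-hull richness.** The hull is built on the smallest number of
leading PCoA axes explaining ≥ 95% of retained eigenvalue mass, capped at
3 (configurable): a fixed dimensionality is required for volumes to be
comparable across cells, and the cap keeps most species-poor cells above
the points-per-dimension threshold. Communities with ≤ `axes` species, or
affinely dependent coordinates, get volume 0 with a `degenerate` flag
rather than an error, so maps stay computable everywhere.

**Rao and its numbers equivalent.** `Q = pᵀ D p` with relative
abundances p; single-species communities give 0. The numbers equivalent
is `1/(1−Q)`, the standard effective-species transform for quadratic
entropy with distances in [0, 1]: S equally abundant, maximally distinct
species give exactly S (verified algebraically for S = 2..10).

Map-cell metrics and survey-site metrics go through one code path
(`community_metrics`), so observed and estimated values can never diverge
by implementation.

## Evaluation

Sites are split into training and evaluation subsets by stratified random
sampling over grid quadrants (largest-remainder allocation) — the
synthetic analogue of reserving one site per political unit. For each
metric × scheme, OLS of estimate on observation yields R², the
correlation p-value, the slope, and `t = (slope − 1)/SE` with a two-sided
p by default (one-sided available). Estimates at a site come from the
grid cell containing it; a 3×3 neighbourhood mean is available by config.
Zero-variance observations refuse the fit; numerically exact fits report
t = 0 rather than 0/0 noise.

**SAR refit.** Spatial-error model `y = Xβ + u, u = λWu + ε` with
row-standardized Delaunay-neighbour weights, estimated by concentrated
maximum likelihood over λ (log-determinant via the eigenvalues of W;
duplicate site coordinates are deterministically jittered). Reported per
comparison as whether the slope stays significant spatially, plus an LR
test of λ = 0.

**Screens.** Per site with ≥ 3 species: Pearson r of log abundance vs
each continuous trait, one-way ANOVA across classes of each categorical
trait (requiring ≥ 2 classes and ≥ 1 within-group df); summarised as mean
r ± SE and significant-site counts. Detectability: quasi-Poisson GLM of
sites-recorded on log range size, log mass and migratory class, with a
sequential (range → mass → migration) percent-deviance partition; a
constant response short-circuits to all-zero coefficients.

## Pipeline and reproducibility

A run is fully determined by `PipelineConfig`. The master seed fans out
via `numpy.random.SeedSequence(seed).generate_state(n_stages)` to one
child seed per stage, so any stage is reproducible in isolation; every
artifact is plain text (grids as whitespace tables, everything else CSV/
JSON/YAML) under the output directory, with a manifest recording the
config hash. Re-running with an unchanged config reloads completed
stages (simulate/ranges/surveys/abundance) and recomputes the cheap
metric and evaluation stages, giving identical numbers either way.

## Problem sizes

The default configuration (24×24 grid, 40 species, 80 sites, 16
evaluation sites, 5 survey years) exercises every stage in seconds and is
the size the acceptance script reports. The end-to-end contrast
experiment — strong mass–abundance coupling making the equal-abundance
overlay biased while the environmental-model scheme stays calibrated —
uses denser sampling (300 sites, 10 years, perfect detection, coupling
2.0 on z(log mass)) because the contrast is a statement about the
estimators, and it only manifests cleanly when the abundance models are
fitted on data that actually cover the species pool; with sparse surveys
the heaviest (most abundant) species fall below the 30-record eligibility
threshold and both schemes degrade together.

## Known limitations

- Within its refined range a synthetic species is present everywhere, so
  composition mismatch (Jaccard < 1) arises only from detection and
  sampling noise, not from polygon error as in real atlases.
- The SAR implementation is a single spatial-error specification; no
  model selection among SAR variants is attempted.
- Hull-based richness depends on the retained dimensionality; values are
  comparable within a run, not across runs with different axis caps.
- The quasi-Poisson detectability partition is sequential, so the shares
  attributed to mass and migration depend on the stated term order.
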