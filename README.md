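# traitscape

Mapping the functional-trait composition of ecological communities from
stacked species range maps — and testing how good such maps actually are.

## The problem

Macroecologists increasingly summarise communities not by which species are
present but by the *traits* those species carry: body mass, generation
length, migratory behaviour, diet. Large-extent maps of community trait
composition are usually built by overlaying expert-drawn range maps, which
silently assumes every species is equally abundant everywhere in its range.
`traitscape` implements that mapping workflow, three progressively more
data-hungry alternatives that fold in abundance information, and an
evaluation loop that scores every resulting map against site-level survey
observations. Because the real inputs for such studies (range polygons,
survey schemes, population estimates) are rarely redistributable, the
package ships a first-class synthetic-data generator that emulates all of
them, so the whole pipeline is runnable and testable end to end.

## What it computes

Per grid cell (and per survey site), for each trait and for all traits
jointly:

- **CWM** — community-weighted mean, `Σ_s A_s x_s / A` for a continuous
  trait `x` (log scale for mass and generation length); for categorical
  traits, the proportion of individuals in each class.
- **FRICH** — functional richness: the trait range (continuous), the
  number of classes present (categorical), or the volume of the convex
  hull of the community in principal-coordinate (PCoA) trait space (all
  traits jointly). Computed only under the equal-abundance scheme, since
  richness of trait space ignores abundance by construction.
- **FDIV** — functional divergence via Rao's quadratic entropy
  `Q = Σ_s Σ_s' d(s,s') (A_s/A)(A_s'/A)`, converted to its numbers
  equivalent `1/(1−Q)` so it reads as an effective number of maximally
  distinct species. Trait distances `d` are Gower distances on the global
  species pool.

Abundance `A_s` per occupied cell comes from one of four schemes:
(a) **uniform** — 1 everywhere in the range; (b) **pop_over_range** —
regional population (midpoint of the global estimate × occupied-area
fraction) divided by range size; (c) **survey_mean** — the species' mean
effort-corrected abundance over training survey sites; (d) **env_model** —
per-species generalized additive models (one fixed 5-df smooth per
environmental covariate, log link) predicted at each cell.

The evaluation regresses each map-based estimate on the corresponding
survey-observed metric at held-out sites: R² measures precision, the OLS
slope with a t-test against the ideal y = x slope of 1 measures accuracy.
Robustness checks include a spatial-error SAR refit (Delaunay neighbour
weights), the Jaccard similarity of estimated vs observed species
composition, per-site trait–abundance screens, and a quasi-Poisson model
of species detectability (sites recorded ~ range size + mass + migration).

## Worked example

```sh
traitscape run-all --outdir out --seed 1
```

simulates the default world (24×24 equal-area grid of 20-km cells, 40
species, 80 survey sites of which 16 are held out for evaluation), writes
all artifacts under `out/` and prints the evaluation report, which starts:

```
metric                 trait_scope     method_tag      r2    p_corr  slope  t_unity  p_unity  n_sites
CWM                       log_mass        uniform   0.725  2.82e-05  0.686    -2.79   0.0146       16
CWM                  log_genlength        uniform   0.145     0.145  0.198    -6.27 2.05e-05       16
CWM    migratory_class=altitudinal        uniform   0.893  3.45e-08  0.349    -20.2 9.21e-12       16
```

Read: the community-weighted mean of log body mass estimated by plain
range overlay (`uniform`) explains 72.5% of the variation in the observed
site values, but its slope of 0.686 is significantly below 1
(p = 0.015) — the map compresses the real gradient, exactly the
behaviour expected when true abundances vary among species. The same run
reports species richness recovered with R² = 1.00 and slope 1.00, and a
mean Jaccard similarity of estimated vs observed species composition of
1.0 — in this synthetic world ranges are exact and detection is strong,
so composition errors come only from sampling noise.

The same pipeline is available as a library:

```python
from traitscape import PipelineConfig, run_pipeline
state = run_pipeline(PipelineConfig(seed=1), "out")
print(state.report.head())
```

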