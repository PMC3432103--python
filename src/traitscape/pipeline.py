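"""End-to-end orchestration: simulate -> ranges -> abundance -> metrics -> evaluate.

A run is fully determined by a :class:`~traitscape.config.PipelineConfig`;
the master seed fans out to one child seed per stage (via
``numpy.random.SeedSequence(master).generate_state``) so each stage is
reproducible in isolation.  Every stage writes its artifacts as plain-text
tables/grids under the output directory together with a manifest recording
the config hash; a rerun with the same config reuses completed stages and
reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    AbundanceField,
    METHOD_LETTER,
    fit_all_env_models,
    method_a_uniform,
    method_b_pop_over_range,
    method_c_survey_mean,
    method_d_env_model,
    site_species_abundance,
    total_abundance_map,
)
from .config import PipelineConfig, validate_config
from .evaluation import (
    EvaluationResult,
    detectability_glm,
    evaluation_report,
    jaccard,
    observed_site_communities,
    regress_estimate_on_observed,
    sar_error_model,
    split_sites,
    trait_abundance_screen,
)
from .metrics import (
    Community,
    MetricConfig,
    TraitDistanceMatrix,
    TraitSpaceCoordinates,
    community_metrics,
    gower_distance,
    pcoa,
    per_trait_distances,
)
from .ranges import (
    PresenceStack,
    build_stack,
    read_stack,
    refine_all,
    species_richness_map,
    write_stack,
)
from .synthetic import (
    Landscape,
    SpeciesPool,
    generate_landscape,
    generate_species_pool,
    grow_all_ranges,
    place_sites,
    simulate_surveys,
    true_abundance,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ranges", "surveys", "abundance", "metrics", "evaluate")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return {name: int(s) for name, s in zip(STAGES, state)}


@dataclass
class PipelineState:
    """In-memory artifacts of a (possibly partial) run."""

    config: PipelineConfig
    landscape: Landscape | None = None
    pool: SpeciesPool | None = None
    sites: pd.DataFrame | None = None
    extents: dict[str, np.ndarray] | None = None
    stack: PresenceStack | None = None
    truth: np.ndarray | None = None
    records: pd.DataFrame | None = None
    training_sites: list[str] | None = None
    evaluation_sites: list[str] | None = None
    fields: dict[str, AbundanceField] = field(default_factory=dict)
    distances: dict[str, TraitDistanceMatrix] | None = None
    coords: TraitSpaceCoordinates | None = None
    maps: dict[str, dict[tuple[str, str], np.ndarray]] = field(default_factory=dict)
    report: pd.DataFrame | None = None
    jaccard_stats: dict | None = None
    screen_summary: dict | None = None
    detectability: dict | None = None


# ---------------------------------------------------------------------------
# in-memory stages
# ---------------------------------------------------------------------------

def run_simulate(state: PipelineState, seeds: dict[str, int]) -> None:
    cfg = state.config
    state.landscape = generate_landscape(
        cfg.landscape.n_rows,
        cfg.landscape.n_cols,
        seed=seeds["simulate"],
        cell_km=cfg.landscape.cell_km,
        smooth_sigma=cfg.landscape.smooth_sigma,
    )
    state.pool = generate_species_pool(
        cfg.n_species, state.landscape, cfg.pool, seed=seeds["simulate"] + 1
    )
    state.sites = place_sites(state.landscape, cfg.survey.n_sites, seed=seeds["simulate"] + 2)
    logger.info("simulated %d species on a %dx%d grid, %d sites",
                cfg.n_species, cfg.landscape.n_rows, cfg.landscape.n_cols, cfg.survey.n_sites)


def run_ranges(state: PipelineState, seeds: dict[str, int]) -> None:
    cfg = state.config
    state.extents = grow_all_ranges(state.pool, state.landscape, seed=seeds["ranges"])
    refined = refine_all(state.extents, state.pool.table, state.landscape.elevation)
    state.stack = build_stack(refined, state.landscape.shape, cell_km=cfg.landscape.cell_km)
    n_empty = int((state.stack.occupancy.sum(axis=1) == 0).sum())
    logger.info("presence stack built: %d species, %d with empty refined ranges",
                state.stack.n_species, n_empty)


def run_surveys(state: PipelineState, seeds: dict[str, int]) -> None:
    cfg = state.config
    state.truth = true_abundance(state.pool, state.landscape, state.stack.occupancy)
    state.records = simulate_surveys(
        state.pool,
        state.truth,
        state.sites["cell"].to_numpy(),
        cfg.survey.years,
        cfg.survey.effort,
        cfg.survey.detectability,
        seed=seeds["surveys"],
        site_ids=list(state.sites["site_id"]),
    )
    sites = state.sites.copy()
    if cfg.split.stratify_by_quadrant:
        half_r = state.landscape.n_rows / 2
        half_c = state.landscape.n_cols / 2
        sites["quadrant"] = (sites["row"] >= half_r).astype(int) * 2 + (
            sites["col"] >= half_c
        ).astype(int)
        strat = "quadrant"
    else:
        strat = None
    state.training_sites, state.evaluation_sites = split_sites(
        sites, cfg.split.n_eval, stratify_by=strat, seed=seeds["surveys"] + 1
    )
    logger.info("surveys: %d records; split %d training / %d evaluation sites",
                len(state.records), len(state.training_sites), len(state.evaluation_sites))


def run_abundance(state: PipelineState, seeds: dict[str, int]) -> None:
    cfg = state.config
    pop = state.pool.table[["species_id", "global_pop_min", "global_pop_max", "area_fraction"]]
    for letter in cfg.methods.methods:
        tag = METHOD_LETTER[letter]
        if letter == "a":
            state.fields[tag] = method_a_uniform(state.stack)
        elif letter == "b":
            state.fields[tag] = method_b_pop_over_range(state.stack, pop)
        elif letter == "c":
            state.fields[tag] = method_c_survey_mean(
                state.stack, state.records, state.training_sites
            )
        elif letter == "d":
            models = fit_all_env_models(
                state.records,
                state.sites,
                state.landscape,
                state.training_sites,
                min_records=cfg.methods.min_records,
                df=cfg.methods.gam_df,
                family=cfg.methods.gam_family,
            )
            state.fields[tag] = method_d_env_model(state.stack, models, state.landscape)
        logger.info("method %s (%s): %d eligible species",
                    letter, tag, len(state.fields[tag].eligible_species))


def metric_config(cfg: PipelineConfig) -> MetricConfig:
    return MetricConfig(
        hull_mass_frac=cfg.metrics.hull_mass_frac, hull_max_axes=cfg.metrics.hull_max_axes
    )


def compute_metric_maps(
    field_: AbundanceField,
    traits: pd.DataFrame,
    distances: dict[str, TraitDistanceMatrix],
    coords: TraitSpaceCoordinates,
    cfg: MetricConfig,
    include_hull: bool,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-cell metric grids for one abundance field.

    Returns {(metric, trait_scope): flat array}; cells with no species are
    NaN.  The hull-based multivariate FRICH is included only for the
    abundance-ignoring field.
    """
    n_cells = field_.values.shape[1]
    maps: dict[tuple[str, str], np.ndarray] = {}
    for cell in range(n_cells):
        sids, abund = field_.cell_community(cell)
        if not sids:
            continue
        vals = community_metrics(
            Community(sids, abund),
            traits,
            distances,
            coords,
            cfg,
            method_tag=field_.method_tag,
            include_hull=include_hull,
        )
        for mv in vals:
            key = (mv.metric, mv.trait_scope)
            if key not in maps:
                maps[key] = np.full(n_cells, np.nan)
            maps[key][cell] = mv.value
    return maps


def run_metrics(state: PipelineState, seeds: dict[str, int]) -> None:
    cfg = state.config
    traits = state.pool.traits()
    mcfg = metric_config(cfg)
    state.distances = per_trait_distances(traits, mcfg)
    state.coords = pcoa(state.distances["all"])
    for tag, field_ in state.fields.items():
        state.maps[tag] = compute_metric_maps(
            field_, traits, state.distances, state.coords, mcfg, include_hull=(tag == "uniform")
        )
    logger.info("metric maps computed for %d methods", len(state.maps))


def _estimate_at_cell(grid: np.ndarray, cell: int, shape: tuple[int, int], neighbourhood: bool) -> float:
    if not neighbourhood:
        return float(grid[cell])
    n_rows, n_cols = shape
    r, c = divmod(cell, n_cols)
    vals = [
        grid[rr * n_cols + cc]
        for rr in range(max(r - 1, 0), min(r + 2, n_rows))
        for cc in range(max(c - 1, 0), min(c + 2, n_cols))
    ]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def run_evaluate(state: PipelineState, seeds: dict[str, int]) -> None:
    cfg = state.config
    traits = state.pool.traits()
    mcfg = metric_config(cfg)
    site_cell = state.sites.set_index("site_id")["cell"]
    communities = observed_site_communities(state.records, state.evaluation_sites)
    eval_ids = [s for s in state.evaluation_sites if s in communities]

    # observed metrics per site (same code path as the map cells)
    observed: dict[str, dict[tuple[str, str], float]] = {}
    for sid in eval_ids:
        vals = community_metrics(
            communities[sid], traits, state.distances, state.coords, mcfg,
            method_tag="observed", include_hull=True,
        )
        observed[sid] = {(m.metric, m.trait_scope): m.value for m in vals}
        observed[sid][("richness", "all")] = communities[sid].n_species
        observed[sid][("total_abundance", "all")] = communities[sid].total

    coords_xy = np.column_stack(
        [site_cell.loc[eval_ids].to_numpy() % state.landscape.n_cols,
         site_cell.loc[eval_ids].to_numpy() // state.landscape.n_cols]
    ).astype(float)
    richness = species_richness_map(state.stack).ravel().astype(float)

    results: list[EvaluationResult] = []
    for tag, maps in state.maps.items():
        maps = dict(maps)
        if tag == "uniform":
            maps[("richness", "all")] = richness
        else:
            maps[("total_abundance", "all")] = total_abundance_map(state.fields[tag])
        for (metric, scope), grid in maps.items():
            if metric == "FRICH" and tag != "uniform":
                continue  # richness of trait space is composition-only
            x = np.array([observed[s].get((metric, scope), np.nan) for s in eval_ids])
            y = np.array(
                [
                    _estimate_at_cell(grid, int(site_cell.loc[s]), state.landscape.shape,
                                      cfg.metrics.neighbourhood_mean)
                    for s in eval_ids
                ]
            )
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            try:
                fit = regress_estimate_on_observed(x[ok], y[ok], sided=cfg.slope_test_sided)
            except ValueError:
                continue
            sar_flag = "not_run"
            if cfg.run_sar and ok.sum() >= 10 and np.isfinite(fit["slope"]):
                try:
                    sar = sar_error_model(x[ok], y[ok], coords_xy[ok], seed=seeds["evaluate"])
                    sar_flag = "yes" if sar["slope_p"] < 0.05 else "no"
                except (ValueError, np.linalg.LinAlgError):
                    sar_flag = "not_run"
            results.append(
                EvaluationResult(
                    metric=metric, trait_scope=scope, method_tag=tag,
                    r2=fit["r2"], p_corr=fit["p_corr"], slope=fit["slope"],
                    t_unity=fit["t_unity"], p_unity=fit["p_unity"],
                    n_sites=fit["n"], sar_significant=sar_flag,
                )
            )
    state.report = evaluation_report(results)

    # composition similarity of the range-overlay estimate
    if "uniform" in state.fields:
        jac = []
        for sid in eval_ids:
            est_species, _ = state.fields["uniform"].cell_community(int(site_cell.loc[sid]))
            jac.append(jaccard(communities[sid].species_ids, est_species))
        jac = np.array(jac, dtype=float)
        state.jaccard_stats = {
            "mean": float(np.nanmean(jac)) if len(jac) else float("nan"),
            "min": float(np.nanmin(jac)) if len(jac) else float("nan"),
            "max": float(np.nanmax(jac)) if len(jac) else float("nan"),
            "n_sites": int(len(jac)),
        }

    # per-site trait-abundance screens over every surveyed site
    site_abund = site_species_abundance(state.records)
    _, state.screen_summary = trait_abundance_screen(site_abund, traits)

    # detectability: sites recording each species vs range size and traits
    n_sites_recorded = (
        site_abund.groupby("species_id")["site_id"].nunique().rename("n_sites_recorded")
    )
    stats_df = state.pool.table[["species_id", "log_mass", "migratory_class"]].copy()
    stats_df["range_size"] = state.stack.range_sizes().loc[stats_df["species_id"]].to_numpy()
    stats_df["n_sites_recorded"] = (
        stats_df["species_id"].map(n_sites_recorded).fillna(0).astype(float)
    )
    stats_df = stats_df[stats_df["range_size"] > 0]
    try:
        state.detectability = detectability_glm(stats_df)
    except ValueError as e:
        logger.info("detectability model not run: %s", e)
        state.detectability = None
    logger.info("evaluation complete: %d metric/method comparisons", len(state.report))


# ---------------------------------------------------------------------------
# artifact I/O and resumable runs
# ---------------------------------------------------------------------------

def _save_grid(path: Path, grid: np.ndarray) -> None:
    np.savetxt(path, np.asarray(grid), fmt="%.10g")


def _save_field(field_: AbundanceField, shape: tuple[int, int], csv_path: Path, meta_path: Path) -> None:
    sp, cell = np.nonzero(field_.values)
    rows, cols = np.divmod(cell, shape[1])
    pd.DataFrame(
        {
            "species_id": [field_.species_ids[i] for i in sp],
            "row": rows,
            "col": cols,
            "value": field_.values[sp, cell],
        }
    ).to_csv(csv_path, index=False)
    meta_path.write_text(
        json.dumps(
            {
                "method_tag": field_.method_tag,
                "species_ids": field_.species_ids,
                "eligible_species": field_.eligible_species,
            }
        )
    )


def _load_field(shape: tuple[int, int], csv_path: Path, meta_path: Path) -> AbundanceField:
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(csv_path)
    n_cells = shape[0] * shape[1]
    values = np.zeros((len(meta["species_ids"]), n_cells))
    idx = {s: i for i, s in enumerate(meta["species_ids"])}
    if len(df):
        values[
            df["species_id"].map(idx).to_numpy(),
            df["row"].to_numpy() * shape[1] + df["col"].to_numpy(),
        ] = df["value"].to_numpy()
    return AbundanceField(
        species_ids=meta["species_ids"],
        values=values,
        method_tag=meta["method_tag"],
        eligible_species=meta["eligible_species"],
    )


def run_pipeline(config: PipelineConfig, outdir) -> PipelineState:
    """Run (or resume) the full pipeline, writing artifacts under outdir.

    Stages completed in a previous run with the same config hash are
    loaded from disk rather than recomputed; numeric outputs are
    identical either way because every stage is seeded.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": config.config_hash(), "version": __version__,
                "numpy": np.__version__, "stages_done": []}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == manifest["config_hash"]:
            manifest["stages_done"] = old.get("stages_done", [])
        else:
            logger.info("config changed; ignoring previous artifacts")
    config.to_yaml(out / "config.yaml")
    state = PipelineState(config=config)
    shape = (config.landscape.n_rows, config.landscape.n_cols)

    def done(stage: str) -> bool:
        return stage in manifest["stages_done"]

    def mark(stage: str) -> None:
        if stage not in manifest["stages_done"]:
            manifest["stages_done"].append(stage)
        manifest_path.write_text(json.dumps(manifest, indent=1))

    # -- simulate ---------------------------------------------------------
    if done("simulate"):
        layers = {n: np.loadtxt(out / f"{n}.txt") for n in ("elevation", "env1", "env2", "env3")}
        state.landscape = Landscape(cell_km=config.landscape.cell_km, **layers)
        table = pd.read_csv(out / "pool.csv")
        state.pool = SpeciesPool(table=table)
        state.sites = pd.read_csv(out / "sites.csv")
        logger.info("simulate: loaded from %s", out)
    else:
        run_simulate(state, seeds)
        for n in ("elevation", "env1", "env2", "env3"):
            _save_grid(out / f"{n}.txt", getattr(state.landscape, n))
        state.pool.table.to_csv(out / "pool.csv", index=False)
        cols = ["species_id", "log_mass", "log_genlength", "migratory_class", "diet_class",
                "elev_min", "elev_max", "global_pop_min", "global_pop_max", "area_fraction"]
        state.pool.table[cols].to_csv(out / "traits.csv", index=False)
        state.sites.to_csv(out / "sites.csv", index=False)
        mark("simulate")

    # -- ranges -----------------------------------------------------------
    if done("ranges"):
        state.stack = read_stack(out / "stack_cells.csv", out / "stack_index.csv")
        ext = read_stack(out / "extent_cells.csv", out / "stack_index.csv")
        state.extents = ext.to_cell_sets()
    else:
        run_ranges(state, seeds)
        write_stack(state.stack, out / "stack_cells.csv", out / "stack_index.csv")
        ext_stack = build_stack(state.extents, shape, cell_km=config.landscape.cell_km)
        write_stack(ext_stack, out / "extent_cells.csv", out / "_extent_index.csv")
        _save_grid(out / "species_richness.txt", species_richness_map(state.stack))
        mark("ranges")

    # -- surveys ----------------------------------------------------------
    if done("surveys"):
        state.truth = true_abundance(state.pool, state.landscape, state.stack.occupancy)
        state.records = pd.read_csv(out / "surveys.csv")
        split = json.loads((out / "split.json").read_text())
        state.training_sites = split["training"]
        state.evaluation_sites = split["evaluation"]
    else:
        run_surveys(state, seeds)
        state.records.to_csv(out / "surveys.csv", index=False)
        (out / "split.json").write_text(
            json.dumps({"training": state.training_sites, "evaluation": state.evaluation_sites})
        )
        mark("surveys")

    # -- abundance --------------------------------------------------------
    tags = [METHOD_LETTER[m] for m in config.methods.methods]
    if done("abundance"):
        for tag in tags:
            state.fields[tag] = _load_field(
                shape, out / f"abundance_{tag}.csv", out / f"abundance_{tag}.json"
            )
    else:
        run_abundance(state, seeds)
        for tag, f in state.fields.items():
            _save_field(f, shape, out / f"abundance_{tag}.csv", out / f"abundance_{tag}.json")
        mark("abundance")

    # -- metrics and evaluation (cheap; recomputed each run) --------------
    run_metrics(state, seeds)
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    for tag, maps in state.maps.items():
        for (metric, scope), grid in maps.items():
            name = f"{metric}_{scope.replace('=', '-')}_{tag}.txt"
            _save_grid(maps_dir / name, grid.reshape(shape))
    run_evaluate(state, seeds)
    state.report.to_csv(out / "report.csv", index=False)
    summary = {
        "jaccard": state.jaccard_stats,
        "trait_abundance_screen": state.screen_summary,
        "detectability": state.detectability,
        "n_species_by_method": {t: len(state.fields[t].eligible_species) for t in state.fields},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    mark("metrics")
    mark("evaluate")
    return state


def run_in_memory(config: PipelineConfig) -> PipelineState:
    """Full pipeline without touching disk (used by tests and scripts)."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    seeds = stage_seeds(config.seed)
    state = PipelineState(config=config)
    run_simulate(state, seeds)
    run_ranges(state, seeds)
    run_surveys(state, seeds)
    run_abundance(state, seeds)
    run_metrics(state, seeds)
    run_evaluate(state, seeds)
    return state
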