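"""Synthetic landscapes, species pools, ranges and survey records.

This module generates data with the statistical structure the rest of the
pipeline assumes: smooth environmental gradients on an equal-area grid,
contiguous species ranges, log-normal body mass and generation length,
categorical migratory and diet classes, abundance surfaces that are
log-linear in the environmental covariates, and effort-dependent,
detectability-biased Poisson survey counts.  Everything is deterministic
given a seed; each operation draws from its own RNG stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

MIGRATORY_CLASSES = ("non-migrant", "nomad", "altitudinal", "latitudinal")
DIET_CLASSES = ("fruit", "nectar", "plant", "invertebrate", "vertebrate", "mixed")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Gridded study region: elevation plus three environmental covariates.

    Layers are 2-D arrays of identical shape.  Cells are equal-area; the
    nominal cell edge (km) is metadata only — all computation is on the
    abstract grid.
    """

    elevation: np.ndarray
    env1: np.ndarray
    env2: np.ndarray
    env3: np.ndarray
    cell_km: float = 20.0

    def __post_init__(self) -> None:
        shp = self.elevation.shape
        for name in ("env1", "env2", "env3"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"layer {name} shape {getattr(self, name).shape} != {shp}")
        for name in ("elevation", "env1", "env2", "env3"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"layer {name} contains non-finite values")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def n_cells(self) -> int:
        return self.elevation.size

    def env_table(self) -> np.ndarray:
        """(n_cells, 3) covariate matrix in flat cell order (row-major)."""
        return np.column_stack([self.env1.ravel(), self.env2.ravel(), self.env3.ravel()])


@dataclass
class PoolConfig:
    """Distributional settings for the species pool.

    Continuous traits are stored log-transformed; defaults give a median
    body mass of ~33 g and a median generation length of ~2.7 years, both
    right-skewed on the natural scale.  Class frequencies default to a
    temperate-avifauna-like mix.  ``trait_abundance_coupling`` links the
    species' abundance intercept to standardized log mass; 0 = the null
    regime in which local abundance is unrelated to traits.
    """

    mass_log_mean: float = 3.5
    mass_log_sd: float = 1.2
    genlength_log_mean: float = 1.0
    genlength_log_sd: float = 0.4
    migratory_probs: dict[str, float] = field(
        default_factory=lambda: {
            "non-migrant": 0.60, "latitudinal": 0.30, "altitudinal": 0.07, "nomad": 0.03,
        }
    )
    diet_probs: dict[str, float] = field(
        default_factory=lambda: {
            "invertebrate": 0.45, "mixed": 0.20, "fruit": 0.10,
            "plant": 0.10, "vertebrate": 0.10, "nectar": 0.05,
        }
    )
    # range-size as a fraction of the grid: Beta(a,b) rescaled to [lo, hi]
    range_frac_beta: tuple[float, float] = (2.0, 2.0)
    range_frac_bounds: tuple[float, float] = (0.05, 0.75)
    # expected local abundance: lambda = exp(b0 + sum_j b_j * z(env_j))
    abundance_intercept_mean: float = 1.0
    abundance_intercept_sd: float = 1.0
    abundance_env_coef_sd: float = 0.3
    trait_abundance_coupling: float = 0.0
    # population-size bookkeeping for the pop/range method
    area_fraction_bounds: tuple[float, float] = (0.5, 1.0)
    population_uncertainty_bounds: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        # YAML round-trips deliver lists; normalise to tuples
        for name in ("range_frac_beta", "range_frac_bounds",
                     "area_fraction_bounds", "population_uncertainty_bounds"):
            setattr(self, name, tuple(getattr(self, name)))

    def validate(self) -> None:
        for label in self.migratory_probs:
            if label not in MIGRATORY_CLASSES:
                raise ValueError(f"unknown migratory class {label!r}")
        for label in self.diet_probs:
            if label not in DIET_CLASSES:
                raise ValueError(f"unknown diet class {label!r}")


@dataclass
class SpeciesPool:
    """Per-species traits, range parameters and abundance coefficients.

    ``table`` has one row per species: species_id, log_mass, log_genlength,
    migratory_class, diet_class, elev_min, elev_max, range_seed_cell,
    range_size, b0..b3 (abundance coefficients on standardized covariates),
    global_pop_min, global_pop_max, area_fraction.
    """

    table: pd.DataFrame

    @property
    def species_ids(self) -> list[str]:
        return list(self.table["species_id"])

    @property
    def n_species(self) -> int:
        return len(self.table)

    def traits(self) -> pd.DataFrame:
        """Trait table indexed by species_id (the metrics-module input)."""
        return self.table.set_index("species_id")[
            ["log_mass", "log_genlength", "migratory_class", "diet_class"]
        ]


@dataclass
class EffortModel:
    """Observer-hours per (site, year): log-normal, constant if log_sd=0."""

    log_mean: float = float(np.log(8.0))
    log_sd: float = 0.4

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.log_sd == 0:
            return np.full(n, np.exp(self.log_mean))
        return rng.lognormal(self.log_mean, self.log_sd, size=n)


@dataclass
class DetectabilityModel:
    """Logistic detection probability from log mass, migration and range size.

    p = sigmoid(intercept + mass_coef * z(log mass) + migratory_offsets[class]
                + range_coef * z(log range size)).
    All coefficients may be zero; ``perfect()`` gives p = 1 exactly.
    """

    intercept: float = 1.5
    mass_coef: float = 0.5
    range_coef: float = 0.5
    migratory_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "non-migrant": 0.0, "nomad": 0.25, "altitudinal": 0.25, "latitudinal": 0.5,
        }
    )
    perfect_detection: bool = False

    @classmethod
    def perfect(cls) -> "DetectabilityModel":
        return cls(perfect_detection=True)

    def probabilities(self, pool: SpeciesPool) -> np.ndarray:
        if self.perfect_detection:
            return np.ones(pool.n_species)
        t = pool.table
        z_mass = _zscore(t["log_mass"].to_numpy())
        z_range = _zscore(np.log(t["range_size"].to_numpy().astype(float)))
        mig = t["migratory_class"].map(self.migratory_offsets).fillna(0.0).to_numpy()
        eta = self.intercept + self.mass_coef * z_mass + self.range_coef * z_range + mig
        return 1.0 / (1.0 + np.exp(-eta))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_landscape(
    n_rows: int,
    n_cols: int,
    seed: int,
    cell_km: float = 20.0,
    smooth_sigma: float = 3.0,
) -> Landscape:
    """Smooth spatially autocorrelated elevation and covariate layers.

    Each layer is a low-order spatial trend plus Gaussian-filtered white
    noise, so neighbouring cells are more similar than distant ones.
    Deterministic given ``seed``.
    """
    if n_rows < 4 or n_cols < 4:
        raise ValueError("grid must be at least 4x4")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    r = rr / max(n_rows - 1, 1)
    c = cc / max(n_cols - 1, 1)

    def smooth_noise(scale: float) -> np.ndarray:
        raw = rng.normal(0.0, 1.0, size=(n_rows, n_cols))
        sm = gaussian_filter(raw, sigma=smooth_sigma, mode="reflect")
        sd = sm.std()
        return scale * (sm / sd if sd > 0 else sm)

    # elevation: a broad ridge plus roughness, clipped at sea level
    elevation = 2200.0 * np.exp(-(((r - 0.5) ** 2 + (c - 0.35) ** 2) / 0.18)) + smooth_noise(450.0)
    elevation = np.clip(elevation, 0.0, None)
    # temperature-like gradient along rows, precipitation-like along columns,
    # and a third covariate tracking elevation
    env1 = 25.0 - 30.0 * r + smooth_noise(3.0)
    env2 = 400.0 + 1400.0 * c + smooth_noise(180.0)
    env3 = 10.0 - 0.006 * elevation + smooth_noise(2.0)
    return Landscape(elevation=elevation, env1=env1, env2=env2, env3=env3, cell_km=cell_km)


def generate_species_pool(
    n_species: int,
    landscape: Landscape,
    trait_config: PoolConfig | None = None,
    seed: int = 0,
) -> SpeciesPool:
    """Draw a species pool whose traits and abundance parameters follow
    the configured distributions.

    With ``trait_abundance_coupling == 0`` the abundance intercept is
    independent of every trait (the null regime in which ignoring abundance
    is harmless); a positive coupling makes heavier species systematically
    more abundant.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    cfg = trait_config or PoolConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_cells = landscape.n_cells

    log_mass = rng.normal(cfg.mass_log_mean, cfg.mass_log_sd, n_species)
    log_gen = rng.normal(cfg.genlength_log_mean, cfg.genlength_log_sd, n_species)
    mig_labels = list(cfg.migratory_probs)
    mig = rng.choice(mig_labels, size=n_species, p=_normed(cfg.migratory_probs, mig_labels))
    diet_labels = list(cfg.diet_probs)
    diet = rng.choice(diet_labels, size=n_species, p=_normed(cfg.diet_probs, diet_labels))

    elev = landscape.elevation
    e_lo, e_hi = float(elev.min()), float(elev.max())
    e_span = max(e_hi - e_lo, 1.0)
    elev_min = rng.uniform(e_lo, e_lo + 0.3 * e_span, n_species)
    elev_max = rng.uniform(elev_min + 0.3 * e_span, e_hi + 0.2 * e_span)

    a, b = cfg.range_frac_beta
    lo, hi = cfg.range_frac_bounds
    frac = lo + (hi - lo) * rng.beta(a, b, n_species)
    range_size = np.maximum(1, np.round(frac * n_cells).astype(int))
    range_seed_cell = rng.integers(0, n_cells, n_species)

    b0 = rng.normal(cfg.abundance_intercept_mean, cfg.abundance_intercept_sd, n_species)
    if cfg.trait_abundance_coupling != 0.0:
        b0 = b0 + cfg.trait_abundance_coupling * _zscore(log_mass)
    env_coefs = rng.normal(0.0, cfg.abundance_env_coef_sd, size=(n_species, 3))

    # population bookkeeping consistent with the realized abundance surface:
    # regional total ~ expected individuals over the (unrefined) range size,
    # widened into a min/max interval and inflated to a global figure
    lam_mean = np.exp(b0)  # expected lambda at an average cell (z-covariates ~ 0)
    regional = lam_mean * range_size
    area_fraction = rng.uniform(*cfg.area_fraction_bounds, n_species)
    unc = rng.uniform(*cfg.population_uncertainty_bounds, n_species)
    global_mid = regional / area_fraction
    global_min = global_mid / (1.0 + unc)
    global_max = global_mid * (1.0 + unc)

    width = max(4, len(str(n_species)))
    ids = [f"sp{idx:0{width}d}" for idx in range(n_species)]
    table = pd.DataFrame(
        {
            "species_id": ids,
            "log_mass": log_mass,
            "log_genlength": log_gen,
            "migratory_class": mig,
            "diet_class": diet,
            "elev_min": elev_min,
            "elev_max": elev_max,
            "range_seed_cell": range_seed_cell,
            "range_size": range_size,
            "b0": b0,
            "b1": env_coefs[:, 0],
            "b2": env_coefs[:, 1],
            "b3": env_coefs[:, 2],
            "global_pop_min": global_min,
            "global_pop_max": global_max,
            "area_fraction": area_fraction,
        }
    )
    return SpeciesPool(table=table)


def _normed(probs: dict[str, float], order: list[str]) -> np.ndarray:
    p = np.array([probs[k] for k in order], dtype=float)
    return p / p.sum()


def grow_range(
    range_seed_cell: int,
    range_size: int,
    landscape: Landscape,
    seed: int,
) -> np.ndarray:
    """Contiguous range of exactly ``range_size`` cells by random accretion.

    Starting from the seed cell, repeatedly annexes a uniformly random
    4-neighbour of the current cell set.  Returns sorted flat cell indices.
    This is the unrefined extent; elevational refinement is downstream.
    """
    n_rows, n_cols = landscape.shape
    n_cells = landscape.n_cells
    if not (0 <= range_seed_cell < n_cells):
        raise ValueError(f"seed cell {range_seed_cell} outside grid of {n_cells} cells")
    if not (1 <= range_size <= n_cells):
        raise ValueError(f"range_size {range_size} not in [1, {n_cells}]")
    rng = np.random.default_rng(seed)
    in_range = np.zeros(n_cells, dtype=bool)
    in_range[range_seed_cell] = True
    frontier = set(_neighbours(range_seed_cell, n_rows, n_cols))
    size = 1
    while size < range_size:
        cand = sorted(frontier)
        pick = cand[rng.integers(0, len(cand))]
        frontier.discard(pick)
        in_range[pick] = True
        size += 1
        for nb in _neighbours(pick, n_rows, n_cols):
            if not in_range[nb]:
                frontier.add(nb)
    return np.flatnonzero(in_range)


def _neighbours(cell: int, n_rows: int, n_cols: int) -> list[int]:
    r, c = divmod(cell, n_cols)
    out = []
    if r > 0:
        out.append(cell - n_cols)
    if r < n_rows - 1:
        out.append(cell + n_cols)
    if c > 0:
        out.append(cell - 1)
    if c < n_cols - 1:
        out.append(cell + 1)
    return out


def grow_all_ranges(pool: SpeciesPool, landscape: Landscape, seed: int) -> dict[str, np.ndarray]:
    """Unrefined extents for every species, one child RNG stream each."""
    seeds = np.random.SeedSequence(seed).generate_state(pool.n_species)
    out: dict[str, np.ndarray] = {}
    for i, row in enumerate(pool.table.itertuples(index=False)):
        out[row.species_id] = grow_range(
            int(row.range_seed_cell), int(row.range_size), landscape, int(seeds[i])
        )
    return out


def true_abundance(
    pool: SpeciesPool, landscape: Landscape, occupancy: np.ndarray
) -> np.ndarray:
    """Species x cell expected abundance: exp(b0 + b.z(env)), masked to range.

    ``occupancy`` is the (n_species, n_cells) 0/1 matrix in pool row order.
    """
    env = landscape.env_table()
    envz = (env - env.mean(axis=0)) / np.where(env.std(axis=0) > 0, env.std(axis=0), 1.0)
    t = pool.table
    coefs = t[["b1", "b2", "b3"]].to_numpy()
    eta = t["b0"].to_numpy()[:, None] + coefs @ envz.T
    lam = np.exp(eta)
    return lam * occupancy


def simulate_surveys(
    pool: SpeciesPool,
    abundance_truth: np.ndarray,
    site_cells: np.ndarray,
    years: list[int],
    effort_model: EffortModel | None = None,
    detectability_model: DetectabilityModel | None = None,
    seed: int = 0,
    site_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Poisson survey counts at fixed sites over multiple years.

    count ~ Poisson(true abundance x effort x detection probability); the
    detection probability is a per-species logistic function of traits (see
    DetectabilityModel).  Records are emitted for every (site, species, year)
    where the species' true abundance at the site's cell is positive — zero
    counts are kept, so downstream effort correction sees the full record.
    Returns a DataFrame with columns site_id, species_id, year, count, effort.
    """
    site_cells = np.asarray(site_cells)
    if site_cells.size == 0:
        raise ValueError("site list must be non-empty")
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    n_cells = abundance_truth.shape[1]
    if site_cells.min() < 0 or site_cells.max() >= n_cells:
        raise ValueError("site cell outside grid")
    rng = np.random.default_rng(seed)
    effort_model = effort_model or EffortModel()
    det = (detectability_model or DetectabilityModel()).probabilities(pool)

    n_sites = site_cells.size
    if site_ids is None:
        width = max(4, len(str(n_sites)))
        site_ids = [f"site{idx:0{width}d}" for idx in range(n_sites)]
    elif len(site_ids) != n_sites:
        raise ValueError("site_ids length must match site_cells")
    lam_site = abundance_truth[:, site_cells]  # species x sites

    rows = []
    for year in years:
        effort = effort_model.draw(rng, n_sites)
        mean = lam_site * effort[None, :] * det[:, None]
        counts = rng.poisson(mean)
        sp_idx, si_idx = np.nonzero(lam_site > 0)
        rows.append(
            pd.DataFrame(
                {
                    "site_id": [site_ids[j] for j in si_idx],
                    "species_id": [pool.species_ids[i] for i in sp_idx],
                    "year": year,
                    "count": counts[sp_idx, si_idx],
                    "effort": effort[si_idx],
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    return records.sort_values(["site_id", "species_id", "year"], ignore_index=True)


def place_sites(landscape: Landscape, n_sites: int, seed: int) -> pd.DataFrame:
    """Distinct random site cells: DataFrame(site_id, cell, row, col)."""
    if n_sites > landscape.n_cells:
        raise ValueError("more sites than cells")
    rng = np.random.default_rng(seed)
    cells = rng.choice(landscape.n_cells, size=n_sites, replace=False)
    width = max(4, len(str(n_sites)))
    rows, cols = np.divmod(cells, landscape.n_cols)
    return pd.DataFrame(
        {
            "site_id": [f"site{idx:0{width}d}" for idx in range(n_sites)],
            "cell": cells,
            "row": rows,
            "col": cols,
        }
    )
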