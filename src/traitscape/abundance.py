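"""Four abundance-estimation schemes over a presence stack.

The schemes differ in how much abundance information they use:

* ``uniform`` (a)      — every species equally abundant (1) everywhere in
  its range: pure range overlay.
* ``pop_over_range`` (b) — species differ in abundance but are uniform
  within the range: regional population total / range size.
* ``survey_mean`` (c)  — species differ: mean effort-corrected survey
  abundance over training sites, uniform within the range.
* ``env_model`` (d)    — abundance varies among species and across space:
  per-species additive models of survey abundance against three
  environmental covariates (one fixed 5-df smooth per covariate),
  predicted at every occupied cell.

Each scheme only covers the species for which its input data exist; the
``eligible_species`` attribute records that subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .ranges import PresenceStack
from .synthetic import Landscape

logger = logging.getLogger(__name__)

METHOD_TAGS = ("uniform", "pop_over_range", "survey_mean", "env_model")
METHOD_LETTER = {"a": "uniform", "b": "pop_over_range", "c": "survey_mean", "d": "env_model"}


@dataclass
class AbundanceField:
    """Species x cell non-negative abundance estimates under one scheme."""

    species_ids: list[str]
    values: np.ndarray  # (n_species, n_cells), zero outside each range
    method_tag: str
    eligible_species: list[str]

    def __post_init__(self) -> None:
        if self.method_tag not in METHOD_TAGS:
            raise ValueError(f"unknown method_tag {self.method_tag!r}")
        if np.any(self.values < 0):
            raise ValueError("abundance values must be non-negative")

    def total_map(self, shape: tuple[int, int]) -> np.ndarray:
        return total_abundance_map(self).reshape(shape)

    def cell_community(self, cell: int) -> tuple[list[str], np.ndarray]:
        """Species present (value > 0) at one cell with their abundances."""
        col = self.values[:, cell]
        idx = np.flatnonzero(col > 0)
        return [self.species_ids[i] for i in idx], col[idx]


# ---------------------------------------------------------------------------
# methods (a) and (b)
# ---------------------------------------------------------------------------

def method_a_uniform(stack: PresenceStack) -> AbundanceField:
    """Range overlay: abundance 1 inside every range, 0 outside."""
    return AbundanceField(
        species_ids=list(stack.species_ids),
        values=stack.occupancy.astype(float),
        method_tag="uniform",
        eligible_species=list(stack.species_ids),
    )


def regional_population(global_min: float, global_max: float, area_fraction: float) -> float:
    """Regional population: midpoint of the global min/max estimate, scaled
    by the fraction of occupied-country area inside the study region."""
    if global_min < 0 or global_max < 0 or global_min > global_max:
        raise ValueError("need 0 <= global_min <= global_max")
    if not (0.0 <= area_fraction <= 1.0):
        raise ValueError("area_fraction must be in [0, 1]")
    return 0.5 * (global_min + global_max) * area_fraction


def method_b_pop_over_range(stack: PresenceStack, populations: pd.DataFrame) -> AbundanceField:
    """Regional population total spread uniformly over the occupied cells.

    ``populations``: DataFrame(species_id, global_pop_min, global_pop_max,
    area_fraction); species absent from it, or with an empty refined range,
    are excluded from ``eligible_species``.
    """
    pop = populations.set_index("species_id")
    values = np.zeros_like(stack.occupancy, dtype=float)
    eligible = []
    sizes = stack.occupancy.sum(axis=1)
    for i, sid in enumerate(stack.species_ids):
        if sid not in pop.index:
            continue
        row = pop.loc[sid]
        total = regional_population(
            float(row["global_pop_min"]), float(row["global_pop_max"]), float(row["area_fraction"])
        )
        if sizes[i] == 0:
            if total > 0:
                logger.warning("%s has population %.0f but empty range; excluded", sid, total)
            continue
        values[i] = stack.occupancy[i] * (total / sizes[i])
        eligible.append(sid)
    return AbundanceField(
        species_ids=list(stack.species_ids),
        values=values,
        method_tag="pop_over_range",
        eligible_species=eligible,
    )


# ---------------------------------------------------------------------------
# survey-based abundance: effort correction and method (c)
# ---------------------------------------------------------------------------

def effort_corrected_abundance(counts, efforts) -> float | None:
    """Observed abundance of one species at one site.

    Counts are divided by effort, averaged over the years in which the
    species was recorded (count > 0), and rounded up to the nearest
    integer.  Returns None when the species was never recorded there.
    """
    counts = np.asarray(counts, dtype=float)
    efforts = np.asarray(efforts, dtype=float)
    if np.any(efforts <= 0):
        raise ValueError("efforts must be positive")
    recorded = counts > 0
    if not recorded.any():
        return None
    return float(math.ceil(np.mean(counts[recorded] / efforts[recorded])))


def site_species_abundance(records: pd.DataFrame) -> pd.DataFrame:
    """Per (site, species) effort-corrected abundance table.

    Input columns: site_id, species_id, year, count, effort.  Output:
    site_id, species_id, abundance (positive integers); (site, species)
    pairs never recorded are dropped.
    """
    rec = records[records["count"] > 0]
    if rec.empty:
        return pd.DataFrame(columns=["site_id", "species_id", "abundance"])
    rate = rec["count"] / rec["effort"]
    out = (
        rate.groupby([rec["site_id"], rec["species_id"]])
        .mean()
        .apply(math.ceil)
        .rename("abundance")
        .reset_index()
    )
    return out


def method_c_survey_mean(
    stack: PresenceStack,
    records: pd.DataFrame,
    training_sites: list[str],
) -> AbundanceField:
    """Species mean of per-site observed abundance, uniform within range.

    Only training-site records are used; species recorded at no training
    site are excluded.
    """
    training = set(training_sites)
    site_abund = site_species_abundance(records[records["site_id"].isin(training)])
    means = site_abund.groupby("species_id")["abundance"].mean()
    values = np.zeros_like(stack.occupancy, dtype=float)
    eligible = []
    for i, sid in enumerate(stack.species_ids):
        if sid in means.index and stack.occupancy[i].any():
            values[i] = stack.occupancy[i] * float(means.loc[sid])
            eligible.append(sid)
    return AbundanceField(
        species_ids=list(stack.species_ids),
        values=values,
        method_tag="survey_mean",
        eligible_species=eligible,
    )


# ---------------------------------------------------------------------------
# method (d): environmental abundance models
# ---------------------------------------------------------------------------

@dataclass
class EnvAbundanceModel:
    """Fitted per-species additive abundance model.

    One fixed 5-df B-spline smooth per covariate (no automatic smoothness
    selection), Gaussian family with a log link by default so predictions
    are strictly positive.  Covariates are clamped to their training range
    before prediction to avoid wild spline extrapolation.
    """

    species_id: str
    result: object
    cov_min: np.ndarray
    cov_max: np.ndarray
    n_records: int
    explained_variance: float
    clamp: bool = True

    def predict(self, covariates: np.ndarray) -> np.ndarray:
        X = np.asarray(covariates, dtype=float)
        if self.clamp:
            outside = (X < self.cov_min) | (X > self.cov_max)
            if outside.any():
                logger.debug(
                    "%s: clamping %d covariate values outside the training hull",
                    self.species_id,
                    int(outside.sum()),
                )
            X = np.clip(X, self.cov_min, self.cov_max)
        pred = self.result.predict(exog=np.ones((len(X), 1)), exog_smooth=X)
        return np.maximum(np.asarray(pred, dtype=float), 0.0)


def fit_env_abundance_model(
    species_id: str,
    site_abundance: np.ndarray,
    site_covariates: np.ndarray,
    min_records: int = 30,
    df: int = 5,
    family: str = "poisson",
) -> EnvAbundanceModel | None:
    """Fit the additive abundance model for one species.

    ``site_abundance``: per-site effort-corrected abundance (positive);
    ``site_covariates``: matching (n_sites, 3) environmental values.
    Species with fewer than ``min_records`` sites are skipped (None).

    The family/link is configurable; the default is a Poisson-type
    log-link fit, which shares its mean structure with a Gaussian log-link
    fit but has far more stable IRLS behaviour on the integer
    effort-corrected abundances the surveys provide.
    """
    y = np.asarray(site_abundance, dtype=float)
    X = np.asarray(site_covariates, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("site_abundance and site_covariates must align")
    if y.size < min_records:
        logger.info("%s: %d records < %d, skipped", species_id, y.size, min_records)
        return None
    if family == "poisson":
        fam = sm.families.Poisson()
    elif family == "gaussian-log":
        fam = sm.families.Gaussian(sm.families.links.Log())
    elif family == "gaussian":
        fam = sm.families.Gaussian()
    else:
        raise ValueError(f"unknown family {family!r}")
    n_cov = X.shape[1]
    if np.ptp(y) == 0.0:
        # constant response: splines are unidentified, intercept suffices
        const = float(y[0])
        return _ConstantModel(species_id, const, X.min(axis=0), X.max(axis=0), y.size)
    smoother = BSplines(X, df=[df] * n_cov, degree=[3] * n_cov)
    model = GLMGam(y, exog=np.ones((y.size, 1)), smoother=smoother, family=fam, alpha=0.0)
    try:
        result = model.fit()
    except PerfectSeparationError:
        # noiseless data are fitted exactly and the IRLS loop degenerates;
        # the identical mean structure log mu = eta is then obtained in
        # closed form by least squares on the log response
        logger.info("%s: exact fit; using closed-form spline least squares", species_id)
        result = _SplineLstsqResult(smoother, y, log_link=(family != "gaussian"))
    fitted = np.asarray(result.predict(exog=np.ones((y.size, 1)), exog_smooth=X))
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ev = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return EnvAbundanceModel(
        species_id=species_id,
        result=result,
        cov_min=X.min(axis=0),
        cov_max=X.max(axis=0),
        n_records=y.size,
        explained_variance=ev,
    )


class _SplineLstsqResult:
    """Closed-form least squares on the spline basis (log or identity link)."""

    def __init__(self, smoother, y: np.ndarray, log_link: bool = True):
        self._smoother = smoother
        self._log_link = log_link
        design = np.column_stack([np.ones(len(y)), smoother.basis])
        resp = np.log(y) if log_link else y
        self._params, *_ = np.linalg.lstsq(design, resp, rcond=None)

    def predict(self, exog: np.ndarray, exog_smooth: np.ndarray) -> np.ndarray:
        basis = self._smoother.transform(np.asarray(exog_smooth, dtype=float))
        design = np.column_stack([np.asarray(exog, dtype=float), basis])
        eta = design @ self._params
        return np.exp(eta) if self._log_link else eta


class _ConstantModel(EnvAbundanceModel):
    """Degenerate additive model for a constant response."""

    def __init__(self, species_id, const, cov_min, cov_max, n):
        self.species_id = species_id
        self._const = const
        self.cov_min = cov_min
        self.cov_max = cov_max
        self.n_records = n
        self.explained_variance = 1.0
        self.result = None
        self.clamp = True

    def predict(self, covariates: np.ndarray) -> np.ndarray:
        return np.full(len(np.asarray(covariates)), max(self._const, 0.0))


def fit_all_env_models(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    landscape: Landscape,
    training_sites: list[str],
    min_records: int = 30,
    df: int = 5,
    family: str = "poisson",
) -> dict[str, EnvAbundanceModel]:
    """Fit the method-(d) model for every species with enough records."""
    env = landscape.env_table()
    site_cell = sites.set_index("site_id")["cell"]
    training = set(training_sites)
    site_abund = site_species_abundance(records[records["site_id"].isin(training)])
    models: dict[str, EnvAbundanceModel] = {}
    for sid, grp in site_abund.groupby("species_id"):
        cells = site_cell.loc[grp["site_id"]].to_numpy()
        m = fit_env_abundance_model(
            sid, grp["abundance"].to_numpy(), env[cells], min_records=min_records, df=df,
            family=family,
        )
        if m is not None:
            models[sid] = m
    logger.info("fitted environmental models for %d species", len(models))
    return models


def method_d_env_model(
    stack: PresenceStack,
    models: dict[str, EnvAbundanceModel],
    landscape: Landscape,
) -> AbundanceField:
    """Predicted abundance at every occupied cell, zero outside the range."""
    if not models:
        raise ValueError("need at least one fitted model")
    env = landscape.env_table()
    values = np.zeros_like(stack.occupancy, dtype=float)
    eligible = []
    for i, sid in enumerate(stack.species_ids):
        if sid not in models:
            continue
        cells = np.flatnonzero(stack.occupancy[i])
        if cells.size == 0:
            continue
        values[i, cells] = models[sid].predict(env[cells])
        eligible.append(sid)
    return AbundanceField(
        species_ids=list(stack.species_ids),
        values=values,
        method_tag="env_model",
        eligible_species=eligible,
    )


def total_abundance_map(field: AbundanceField) -> np.ndarray:
    """Per-cell total abundance over the eligible species (flat vector)."""
    idx = [field.species_ids.index(s) for s in field.eligible_species]
    if not idx:
        return np.zeros(field.values.shape[1])
    return field.values[idx].sum(axis=0)


def restrict_to_species(field: AbundanceField, species: list[str]) -> AbundanceField:
    """Field restricted to a common species subset (for method comparisons)."""
    keep = [s for s in field.eligible_species if s in set(species)]
    mask = np.array([s in set(keep) for s in field.species_ids])
    values = field.values.copy()
    values[~mask] = 0.0
    return AbundanceField(
        species_ids=list(field.species_ids),
        values=values,
        method_tag=field.method_tag,
        eligible_species=keep,
    )
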