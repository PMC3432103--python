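"""Trait distances and community-composition metrics.

Three families of metrics summarise the trait composition of a community
(a grid-cell assemblage or a surveyed site):

* community-weighted mean (CWM): abundance-weighted mean trait value; for
  categorical traits, the proportion of individuals in each class;
* functional richness (FRICH): the extent of trait space occupied — trait
  range (continuous), number of classes present (categorical), or the
  volume of the convex hull of the community in principal-coordinate
  space (all traits jointly);
* functional divergence (FDIV): Rao's quadratic entropy Q — the expected
  trait distance between two randomly drawn individuals — converted to
  its numbers equivalent 1 / (1 - Q) so it reads as an effective number
  of maximally distinct species.

Trait distances are Gower distances: the unweighted mean, over traits, of
range-normalised absolute differences (continuous) and mismatch
indicators (categorical).  Continuous traits are normalised by the GLOBAL
species-pool range so distances are comparable across cells.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

CONTINUOUS_TRAITS = ("log_mass", "log_genlength")
CATEGORICAL_TRAITS = ("migratory_class", "diet_class")
ALL_TRAITS = CONTINUOUS_TRAITS + CATEGORICAL_TRAITS


@dataclass
class TraitDistanceMatrix:
    species_ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.species_ids), len(self.species_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("Gower distances must lie in [0, 1]")
        self.d = d

    def submatrix(self, species: list[str]) -> np.ndarray:
        idx = [self.species_ids.index(s) for s in species]
        return self.d[np.ix_(idx, idx)]


@dataclass
class TraitSpaceCoordinates:
    """Principal-coordinate embedding of the species pool."""

    species_ids: list[str]
    coords: np.ndarray  # (n_species, n_axes), axes by decreasing eigenvalue
    eigenvalues: np.ndarray

    def subset(self, species: list[str], n_axes: int | None = None) -> np.ndarray:
        idx = [self.species_ids.index(s) for s in species]
        pts = self.coords[idx]
        return pts if n_axes is None else pts[:, :n_axes]


@dataclass
class Community:
    """Species present with positive abundances (A_s > 0, A = sum A_s)."""

    species_ids: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if len(self.species_ids) == 0:
            raise ValueError("community must contain at least one species")
        if a.shape != (len(self.species_ids),) or np.any(a <= 0):
            raise ValueError("abundances must be positive, one per species")
        self.abundances = a

    @property
    def total(self) -> float:
        return float(self.abundances.sum())

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


@dataclass
class MetricValue:
    metric: str  # CWM | FRICH | FDIV | richness
    trait_scope: str  # trait name, "trait=class" for CWM proportions, or "all"
    value: float
    method_tag: str = ""
    flag: str = ""  # "", "degenerate", "too_few_species"


# ---------------------------------------------------------------------------
# Gower distances and PCoA
# ---------------------------------------------------------------------------

def gower_distance(
    traits: pd.DataFrame,
    species: list[str] | None = None,
    trait_names: tuple[str, ...] = ALL_TRAITS,
) -> TraitDistanceMatrix:
    """Pairwise Gower distances among species.

    ``traits`` is indexed by species_id; the full table defines the pool
    whose continuous-trait ranges normalise the differences, while
    ``species`` (default: all) selects the rows of the output.  Each
    trait contributes equally; a continuous trait with zero pool range
    contributes 0.  Species with missing values are rejected — the
    pipeline excludes incomplete species upstream.
    """
    if traits[list(trait_names)].isna().any().any():
        raise ValueError("species with missing trait values must be excluded")
    ids = list(traits.index) if species is None else list(species)
    if len(ids) < 2:
        raise ValueError("need at least 2 species")
    n = len(ids)
    sub = traits.loc[ids]
    contrib = np.zeros((n, n))
    for name in trait_names:
        if name in CONTINUOUS_TRAITS:
            rng = float(traits[name].max() - traits[name].min())
            x = sub[name].to_numpy(dtype=float)
            if rng > 0:
                contrib += np.abs(x[:, None] - x[None, :]) / rng
        else:
            labels = sub[name].to_numpy()
            contrib += (labels[:, None] != labels[None, :]).astype(float)
    d = contrib / len(trait_names)
    np.fill_diagonal(d, 0.0)
    return TraitDistanceMatrix(species_ids=ids, d=np.clip(d, 0.0, 1.0))


def pcoa(dist: TraitDistanceMatrix, eig_tol: float = 1e-10) -> TraitSpaceCoordinates:
    """Principal coordinates analysis of a distance matrix.

    Classical metric scaling: double-centre -D^2/2, eigendecompose, keep
    axes with positive eigenvalues and scale eigenvectors by sqrt(lambda).
    For Euclidean-embeddable distances the coordinates reproduce the
    distances exactly.
    """
    D = dist.d
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * eig_tol if n else 0.0
    keep = vals > tol
    if not keep.any():
        logger.info("all-zero distances: zero-dimensional coordinates")
        return TraitSpaceCoordinates(list(dist.species_ids), np.zeros((n, 0)), np.empty(0))
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return TraitSpaceCoordinates(list(dist.species_ids), coords, vals[keep])


def choose_hull_axes(coords: TraitSpaceCoordinates, mass_frac: float = 0.95, max_axes: int = 3) -> int:
    """Smallest number of leading axes explaining >= mass_frac of retained
    eigenvalue mass, capped at ``max_axes`` so species-poor cells can still
    form a non-degenerate hull."""
    ev = coords.eigenvalues
    if ev.size == 0:
        return 0
    cum = np.cumsum(ev) / ev.sum()
    k = int(np.searchsorted(cum, mass_frac) + 1)
    return min(k, max_axes, ev.size)


# ---------------------------------------------------------------------------
# per-community metrics
# ---------------------------------------------------------------------------

def cwm_continuous(community: Community, values: pd.Series) -> float:
    """Abundance-weighted mean trait value, sum(A_s x_s) / A."""
    x = values.loc[community.species_ids].to_numpy(dtype=float)
    return float(np.dot(community.abundances, x) / community.total)


def cwm_categorical(community: Community, labels: pd.Series, class_name: str) -> float:
    """Proportion of individuals in one class, sum_{s in k} A_s / A."""
    lab = labels.loc[community.species_ids].to_numpy()
    if class_name not in set(labels.unique()):
        raise ValueError(f"unknown class {class_name!r}")
    return float(community.abundances[lab == class_name].sum() / community.total)


def frich_single(species_ids: list[str], values: pd.Series, categorical: bool) -> float:
    """Functional richness for one trait; abundance is ignored by design.

    Continuous: range (max - min) of values among species present.
    Categorical: number of distinct classes present.
    """
    v = values.loc[list(species_ids)]
    if categorical:
        return float(v.nunique())
    return float(v.max() - v.min())


def frich_hull(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume of the community in trait space.

    Returns (volume, degenerate).  Communities with too few species for
    the dimensionality, or affinely dependent points, are degenerate with
    volume 0 rather than an error, so maps stay computable at
    species-poor cells.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] == 0 or pts.shape[0] <= pts.shape[1]:
        return 0.0, True
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False


def rao_q(community: Community, dist: TraitDistanceMatrix) -> float:
    """Rao quadratic entropy: Q = sum_s sum_s' d(s,s') (A_s/A)(A_s'/A)."""
    p = community.abundances / community.total
    D = dist.submatrix(community.species_ids)
    return float(p @ D @ p)


def numbers_equivalent(q: float) -> float:
    """Numbers equivalent of Rao's Q: 1 / (1 - Q).

    Maps Q onto an effective number of equally abundant, maximally
    distinct species; S such species (pairwise d = 1) have
    Q = (S - 1)/S and numbers equivalent exactly S.
    """
    if not (0.0 <= q < 1.0):
        raise ValueError("Q must lie in [0, 1)")
    return 1.0 / (1.0 - q)


# ---------------------------------------------------------------------------
# composition: the full metric set for one community
# ---------------------------------------------------------------------------

@dataclass
class MetricConfig:
    hull_mass_frac: float = 0.95
    hull_max_axes: int = 3
    continuous_traits: tuple[str, ...] = CONTINUOUS_TRAITS
    categorical_traits: tuple[str, ...] = CATEGORICAL_TRAITS


def per_trait_distances(traits: pd.DataFrame, cfg: MetricConfig | None = None) -> dict[str, TraitDistanceMatrix]:
    """Gower matrices for each trait alone and for all traits jointly."""
    cfg = cfg or MetricConfig()
    names = cfg.continuous_traits + cfg.categorical_traits
    out = {name: gower_distance(traits, trait_names=(name,)) for name in names}
    out["all"] = gower_distance(traits, trait_names=names)
    return out


def community_metrics(
    community: Community,
    traits: pd.DataFrame,
    distances: dict[str, TraitDistanceMatrix],
    coords: TraitSpaceCoordinates | None = None,
    config: MetricConfig | None = None,
    method_tag: str = "",
    include_hull: bool = True,
) -> list[MetricValue]:
    """All composition metrics for one community.

    Emits CWM per continuous trait, CWM proportions per categorical class,
    FRICH per trait, FRICH hull over all traits (only meaningful for the
    abundance-ignoring scheme; gated by ``include_hull``), and FDIV
    (numbers equivalent of Rao's Q) per trait and over all traits.
    Single-species communities get CWM but degenerate-flagged FDIV/hull.
    """
    cfg = config or MetricConfig()
    out: list[MetricValue] = []
    sids = community.species_ids
    for name in cfg.continuous_traits:
        out.append(MetricValue("CWM", name, cwm_continuous(community, traits[name]), method_tag))
    for name in cfg.categorical_traits:
        for cls in sorted(traits[name].unique()):
            out.append(
                MetricValue(
                    "CWM", f"{name}={cls}", cwm_categorical(community, traits[name], cls), method_tag
                )
            )
    for name in cfg.continuous_traits:
        out.append(MetricValue("FRICH", name, frich_single(sids, traits[name], False), method_tag))
    for name in cfg.categorical_traits:
        out.append(MetricValue("FRICH", name, frich_single(sids, traits[name], True), method_tag))
    if include_hull and coords is not None:
        n_axes = choose_hull_axes(coords, cfg.hull_mass_frac, cfg.hull_max_axes)
        vol, degenerate = frich_hull(coords.subset(sids, n_axes))
        out.append(
            MetricValue("FRICH", "all", vol, method_tag, flag="degenerate" if degenerate else "")
        )
    for scope in list(cfg.continuous_traits) + list(cfg.categorical_traits) + ["all"]:
        if community.n_species < 2:
            out.append(MetricValue("FDIV", scope, 1.0, method_tag, flag="too_few_species"))
        else:
            out.append(
                MetricValue("FDIV", scope, numbers_equivalent(rao_q(community, distances[scope])), method_tag)
            )
    return out


def metrics_to_frame(values: list[MetricValue]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": [m.metric for m in values],
            "trait_scope": [m.trait_scope for m in values],
            "value": [m.value for m in values],
            "method_tag": [m.method_tag for m in values],
            "flag": [m.flag for m in values],
        }
    )


# ---------------------------------------------------------------------------
# brute-force oracles (kept here for reuse by tests and validation scripts)
# ---------------------------------------------------------------------------

def hull_volume_bruteforce(points: np.ndarray) -> float:
    """Combinatorial convex-hull volume for 2-D/3-D point sets.

    Independent of scipy's Qhull: finds hull facets by testing every
    point pair (2-D) or triple (3-D) for the all-points-on-one-side
    property, then sums signed simplex volumes against the centroid.
    Quadratic/cubic — for small validation sets only.
    """
    pts = np.asarray(points, dtype=float)
    n, dim = pts.shape
    centroid = pts.mean(axis=0)
    vol = 0.0
    if dim == 2:
        for i, j in itertools.permutations(range(n), 2):
            edge = pts[j] - pts[i]
            normal = np.array([edge[1], -edge[0]])
            side = (pts - pts[i]) @ normal
            if np.all(side <= 1e-12):  # facet with outward normal
                h = (centroid - pts[i]) @ normal
                vol += abs(np.cross(edge, centroid - pts[i])) / 2.0 if h < 0 else 0.0
        return vol
    if dim == 3:
        for i, j, k in itertools.permutations(range(n), 3):
            if not (i < j < k):
                continue
            for orient in ((i, j, k), (i, k, j)):
                a, b, c = (pts[t] for t in orient)
                normal = np.cross(b - a, c - a)
                if np.linalg.norm(normal) < 1e-12:
                    continue
                side = (pts - a) @ normal
                if np.all(side <= 1e-12):
                    h = (centroid - a) @ normal
                    if h < 0:
                        vol += abs(np.dot(normal, centroid - a)) / 6.0
        return vol
    raise ValueError("brute-force hull supports 2-D and 3-D only")
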