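"""Elevational refinement of species extents and the presence stack.

Expert-drawn extents over-predict local presence; clipping each extent to
the species' reported elevational limits removes cells the species is
unlikely to inhabit.  The refined per-species cell sets are stacked into a
species x cell binary occupancy matrix from which the species-richness map
and all abundance fields derive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PresenceStack:
    """Species x cell binary occupancy on the study grid.

    Row order follows ``species_ids``; ``shape`` is the (n_rows, n_cols)
    grid and ``cell_km`` the nominal cell edge.
    """

    species_ids: list[str]
    occupancy: np.ndarray  # (n_species, n_cells) of 0/1
    shape: tuple[int, int]
    cell_km: float = 20.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 2 or occ.shape[0] != len(self.species_ids):
            raise ValueError("occupancy must be (n_species, n_cells)")
        if occ.shape[1] != self.shape[0] * self.shape[1]:
            raise ValueError("occupancy columns must match grid size")
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy entries must be 0/1")
        self.occupancy = occ.astype(np.uint8)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_cells(self) -> int:
        return self.occupancy.shape[1]

    def range_cells(self, species_id: str) -> np.ndarray:
        """Flat cell indices occupied by one species."""
        i = self.species_ids.index(species_id)
        return np.flatnonzero(self.occupancy[i])

    def range_sizes(self) -> pd.Series:
        return pd.Series(self.occupancy.sum(axis=1), index=self.species_ids, name="range_size")

    def to_cell_sets(self) -> dict[str, np.ndarray]:
        return {sid: np.flatnonzero(self.occupancy[i]) for i, sid in enumerate(self.species_ids)}


def refine_by_elevation(
    extent_cells,
    elevation_grid: np.ndarray,
    elev_min: float,
    elev_max: float,
) -> np.ndarray:
    """Keep extent cells whose elevation lies within [elev_min, elev_max].

    Bounds are inclusive: only cells strictly outside the reported limits
    are excluded.  Cell elevation is the (single) grid value, i.e. the cell
    mean in real data.  An empty result is legal and logged.
    """
    if elev_min > elev_max:
        raise ValueError("elev_min must not exceed elev_max")
    cells = np.asarray(sorted(extent_cells), dtype=int)
    if cells.size == 0:
        return cells
    elev = np.asarray(elevation_grid).ravel()
    e = elev[cells]
    kept = cells[(e >= elev_min) & (e <= elev_max)]
    if kept.size == 0:
        logger.info("elevational refinement emptied a range (limits %.0f-%.0f m)", elev_min, elev_max)
    return kept


def refine_all(
    extents: dict[str, np.ndarray],
    pool_table: pd.DataFrame,
    elevation_grid: np.ndarray,
) -> dict[str, np.ndarray]:
    """Apply elevational refinement to every species extent.

    ``pool_table`` must carry species_id, elev_min, elev_max.
    """
    limits = pool_table.set_index("species_id")[["elev_min", "elev_max"]]
    out = {}
    for sid, cells in extents.items():
        lo, hi = limits.loc[sid]
        out[sid] = refine_by_elevation(cells, elevation_grid, lo, hi)
    n_empty = sum(1 for c in out.values() if len(c) == 0)
    if n_empty:
        logger.info("%d species have empty refined ranges", n_empty)
    return out


def build_stack(
    refined_ranges,
    shape: tuple[int, int],
    cell_km: float = 20.0,
) -> PresenceStack:
    """Assemble per-species cell sets into a PresenceStack.

    ``refined_ranges`` maps species_id -> cell indices (a dict or an
    ordered iterable of pairs; duplicate ids are rejected).  Species with
    empty ranges are kept as all-zero rows so that species indexing stays
    stable across modules.
    """
    pairs = list(refined_ranges.items()) if hasattr(refined_ranges, "items") else list(refined_ranges)
    ids = [sid for sid, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species_id")
    n_cells = shape[0] * shape[1]
    occ = np.zeros((len(ids), n_cells), dtype=np.uint8)
    for i, (sid, cells) in enumerate(pairs):
        cells = np.asarray(cells, dtype=int)
        if cells.size:
            if cells.min() < 0 or cells.max() >= n_cells:
                raise ValueError(f"cell index outside grid for {sid}")
            occ[i, cells] = 1
    return PresenceStack(species_ids=ids, occupancy=occ, shape=shape, cell_km=cell_km)


def species_richness_map(stack: PresenceStack) -> np.ndarray:
    """Per-cell species count as a (n_rows, n_cols) integer grid."""
    return stack.occupancy.sum(axis=0, dtype=np.int64).reshape(stack.shape)


# ---------------------------------------------------------------------------
# text serialization (sparse occupancy CSV + species index)
# ---------------------------------------------------------------------------

def write_stack(stack: PresenceStack, cells_path, index_path) -> None:
    """Write the stack as a sparse cells CSV plus a species-index CSV."""
    sp, cell = np.nonzero(stack.occupancy)
    rows, cols = np.divmod(cell, stack.shape[1])
    pd.DataFrame(
        {"species_id": [stack.species_ids[i] for i in sp], "row": rows, "col": cols}
    ).to_csv(cells_path, index=False)
    pd.DataFrame(
        {
            "species_id": stack.species_ids,
            "n_rows": stack.shape[0],
            "n_cols": stack.shape[1],
            "cell_km": stack.cell_km,
        }
    ).to_csv(index_path, index=False)


def read_stack(cells_path, index_path) -> PresenceStack:
    cells = pd.read_csv(cells_path)
    index = pd.read_csv(index_path)
    shape = (int(index["n_rows"].iloc[0]), int(index["n_cols"].iloc[0]))
    ids = list(index["species_id"])
    ranges = {sid: np.empty(0, dtype=int) for sid in ids}
    if len(cells):
        flat = cells["row"].to_numpy() * shape[1] + cells["col"].to_numpy()
        for sid, grp in pd.Series(flat).groupby(cells["species_id"].to_numpy()):
            ranges[sid] = grp.to_numpy()
    return build_stack(ranges, shape, cell_km=float(index["cell_km"].iloc[0]))
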