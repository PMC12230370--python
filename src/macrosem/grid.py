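"""Equal-area grid assembly: land filtering, presence-absence matrices,
per-cell richness, climate-change velocity, and variable normalization.

Cells are indexed row-major from 0 on an ``n_rows x n_cols`` planar grid of
square cells of side ``cell_size`` km; the centroid of the cell in row ``r``,
column ``c`` sits at ``((c + 0.5) * s, (r + 0.5) * s)``.  The grid is
equal-area by construction, so all distances are planar Euclidean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "filter_land_cells",
    "build_pam",
    "richness",
    "climate_velocity",
    "normalize",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular equal-area grid with per-cell land fractions.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.
    cell_size
        Side length of each (square) cell in km.
    land_fraction
        Fraction of each cell covered by land, length ``n_rows * n_cols``
        in row-major order.  Defaults to all-land.
    retained
        Sorted ids of the cells kept for analysis (default: every cell).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 100.0
    land_fraction: np.ndarray = field(default=None)  # type: ignore[assignment]
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        lf = self.land_fraction
        if lf is None:
            lf = np.ones(self.n_cells_total)
        lf = np.asarray(lf, dtype=float)
        if lf.shape != (self.n_cells_total,):
            raise ValueError("land_fraction must have one entry per grid cell")
        if np.any((lf < 0) | (lf > 1)):
            raise ValueError("land_fraction values must lie in [0, 1]")
        object.__setattr__(self, "land_fraction", lf)
        ret = self.retained
        if ret is None:
            ret = np.arange(self.n_cells_total)
        ret = np.asarray(ret, dtype=int)
        object.__setattr__(self, "retained", ret)

    @property
    def n_cells_total(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_cells(self) -> int:
        """Number of retained cells."""
        return len(self.retained)

    def rowcol(self, cell_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(cell_ids, dtype=int)
        return ids // self.n_cols, ids % self.n_cols

    def centroids(self, cell_ids: np.ndarray | None = None) -> np.ndarray:
        """Planar centroid coordinates (x, y) in km, one row per cell."""
        if cell_ids is None:
            cell_ids = self.retained
        rows, cols = self.rowcol(cell_ids)
        s = self.cell_size
        return np.column_stack([(cols + 0.5) * s, (rows + 0.5) * s])


def filter_land_cells(grid: GridSpec, min_land_fraction: float = 0.25) -> GridSpec:
    """Drop cells whose land fraction is below ``min_land_fraction``.

    Cells exactly at the threshold are kept; ordering is preserved.
    """
    if not 0.0 <= min_land_fraction <= 1.0:
        raise ValueError("min_land_fraction must lie in [0, 1]")
    keep = grid.retained[grid.land_fraction[grid.retained] >= min_land_fraction]
    if len(keep) == 0:
        raise ValueError("no cells pass the land-coverage filter")
    return GridSpec(
        n_rows=grid.n_rows,
        n_cols=grid.n_cols,
        cell_size=grid.cell_size,
        land_fraction=grid.land_fraction,
        retained=keep,
    )


def build_pam(ranges: dict[str, set[int]], grid: GridSpec) -> pd.DataFrame:
    """Assemble a presence-absence matrix (retained cells x species).

    ``ranges`` maps species name to the set of occupied cell ids.  Occupancy
    is restricted to the grid's retained cells; species whose entire range
    falls outside them are dropped with a logged warning.  Unknown cell ids
    raise, naming the offending species.
    """
    retained = grid.retained
    valid = set(range(grid.n_cells_total))
    index = pd.Index(retained, name="cell_id")
    cols = {}
    dropped = []
    pos = {cid: i for i, cid in enumerate(retained)}
    for sp in sorted(ranges):
        cells = ranges[sp]
        bad = set(cells) - valid
        if bad:
            raise ValueError(f"species {sp!r} occupies unknown cell ids {sorted(bad)}")
        col = np.zeros(len(retained), dtype=np.int8)
        hit = [pos[c] for c in cells if c in pos]
        if not hit:
            dropped.append(sp)
            continue
        col[hit] = 1
        cols[sp] = col
    if dropped:
        logger.warning(
            "dropped %d species with no occurrence on retained cells: %s",
            len(dropped), ", ".join(dropped),
        )
    pam = pd.DataFrame(cols, index=index, dtype=np.int8)
    return pam


def richness(pam: pd.DataFrame) -> pd.Series:
    """Species count per cell (row sums of the PAM)."""
    if pam.shape[1] == 0:
        return pd.Series(np.zeros(len(pam), dtype=int), index=pam.index, name="richness")
    return pam.sum(axis=1).astype(int).rename("richness")


def climate_velocity(
    paleo_layers: list[tuple[float, np.ndarray]],
    current: np.ndarray,
    grid: GridSpec,
    gradient_floor: float = 1e-6,
) -> np.ndarray:
    """Mean climate-change velocity (km/yr) per grid cell.

    For each paleo snapshot ``(age_yr, values)`` the temporal rate is
    ``|current - paleo| / age`` (units/yr).  The spatial gradient of the
    *current* layer is the magnitude of the central-difference gradient,
    ``sqrt((dv/dx)^2 + (dv/dy)^2)`` in units/km, with one-sided differences
    at grid edges.  Velocity per snapshot is the ratio of the two, and the
    returned layer is the mean across snapshots.  Gradients below
    ``gradient_floor`` are floored (flat terrain would otherwise divide by
    zero); affected cells are logged.

    Layers are full-grid arrays, either flat (row-major) or 2-D
    ``(n_rows, n_cols)``.  The result is a flat full-grid array; subset to
    retained cells downstream.
    """
    cur = np.asarray(current, dtype=float).reshape(grid.n_rows, grid.n_cols)
    if not paleo_layers:
        raise ValueError("at least one paleo snapshot is required")
    # gradient of the current layer, spacing = cell size in km
    gy, gx = np.gradient(cur, grid.cell_size)
    grad = np.hypot(gx, gy)
    n_floor = int(np.sum(grad < gradient_floor))
    if n_floor:
        logger.warning(
            "spatial gradient below floor (%.1e units/km) in %d cells; "
            "velocity there is temporal rate / floor", gradient_floor, n_floor,
        )
    grad = np.maximum(grad, gradient_floor)
    vels = []
    for age, layer in paleo_layers:
        if age <= 0:
            raise ValueError("paleo snapshot ages must be positive (years)")
        lay = np.asarray(layer, dtype=float)
        if lay.size != cur.size:
            raise ValueError("paleo snapshot grid does not match the current layer")
        lay = lay.reshape(grid.n_rows, grid.n_cols)
        temporal = np.abs(cur - lay) / age
        vels.append(temporal / grad)
    return np.mean(vels, axis=0).ravel()


def normalize(
    cell_table: pd.DataFrame,
    columns: list[str] | None = None,
    keep_richness: bool = True,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score covariates over retained cells (population sd, divide by n).

    Returns the normalized table and a mapping ``column -> (mean, sd)`` so
    the transformation is invertible.  ``richness`` is kept as the raw count
    and additionally z-scored into ``richness_z`` for modelling.  Constant
    columns raise, naming the column.
    """
    if len(cell_table) < 2:
        raise ValueError("need at least 2 cells to normalize")
    out = cell_table.copy()
    if columns is None:
        columns = [c for c in out.columns if c != "richness"]
        if keep_richness and "richness" in out.columns:
            out["richness_z"] = out["richness"].astype(float)
            columns.append("richness_z")
    constants: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        mu = float(np.mean(vals[mask]))
        sd = float(np.std(vals[mask]))  # population sd
        if sd == 0.0:
            raise ValueError(f"variable {col!r} has zero variance; cannot normalize")
        out[col] = (vals - mu) / sd
        constants[col] = (mu, sd)
    return out, constants
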