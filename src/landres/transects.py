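"""All-pairs straight-line transect networks on the 1-km grid.

Each unordered pair of individuals is joined by the segment between their
cell centres; the cells that segment touches (its *supercover*) carry the
pair's elevation profile and land-use tallies.  Distance conventions follow
the analysis grid: individuals in the same cell are 0 km apart, individuals
in 8-neighbouring cells are 1 km apart, and everything else is the
centre-to-centre Euclidean distance.

The supercover is computed with exact integer arithmetic (coordinates are
doubled so cell centres become odd integers), so segments that pass exactly
through a cell corner deterministically pick up both off-diagonal
neighbours — every cell whose closed square the segment touches is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LandresError
from .rasters import LandscapeRaster

Cell = tuple[int, int]


def _check_bounds(cell: Cell, raster: LandscapeRaster) -> None:
    if not raster.in_bounds(cell):
        raise LandresError(
            f"cell {cell} outside raster of shape {raster.shape}"
        )


def euclidean_km(cell_a: Cell, cell_b: Cell, cell_size_km: float = 1.0) -> float:
    """Grid distance between two cells.

    Same cell -> 0; any of the 8 neighbouring cells -> 1 cell size (the
    grid approximation); otherwise the centre-to-centre Euclidean distance.
    """
    dr = abs(cell_a[0] - cell_b[0])
    dc = abs(cell_a[1] - cell_b[1])
    if dr == 0 and dc == 0:
        return 0.0
    if dr <= 1 and dc <= 1:
        return 1.0 * cell_size_km
    return float(np.hypot(dr, dc)) * cell_size_km


def supercover_cells(cell_a: Cell, cell_b: Cell) -> list[Cell]:
    """All cells whose closed square the centre-to-centre segment touches.

    Returns the cells ordered along the segment from ``cell_a`` to
    ``cell_b``.  Exact corner crossings contribute both off-diagonal
    neighbours.
    """
    if cell_a == cell_b:
        return [tuple(cell_a)]
    (r0, c0), (r1, c1) = cell_a, cell_b
    # doubled coordinates: centre of (r, c) is (2r + 1, 2c + 1)
    Y0, X0 = 2 * r0 + 1, 2 * c0 + 1
    Y1, X1 = 2 * r1 + 1, 2 * c1 + 1
    flipped = Y1 < Y0
    if flipped:
        Y0, X0, Y1, X1 = Y1, X1, Y0, X0
    dY, dX = Y1 - Y0, X1 - X0

    cells: list[Cell] = []
    if dY == 0:
        r = (Y0 - 1) // 2
        step = 1 if dX > 0 else -1
        for c in range(c0 if not flipped else c1, (c1 if not flipped else c0) + step, step):
            cells.append((r, c))
        return cells if not flipped else cells  # single row already a->b order

    lo_col = min(c0, c1)
    hi_col = max(c0, c1)
    for r in range((Y0 - 1) // 2, (Y1 - 1) // 2 + 1):
        # strip of row r in doubled coords: y in [2r, 2r+2], clipped to segment
        ya = max(Y0, 2 * r)
        yb = min(Y1, 2 * r + 2)
        # x at the strip edges, as exact fractions num/dY (dY > 0)
        xa = X0 * dY + (ya - Y0) * dX
        xb = X0 * dY + (yb - Y0) * dX
        lo, hi = (xa, xb) if xa <= xb else (xb, xa)
        # cell col c intersects iff 2c*dY <= hi and (2c+2)*dY >= lo
        c_max = hi // (2 * dY)
        c_min = -((-lo) // (2 * dY)) - 1
        c_min = max(c_min, lo_col)
        c_max = min(c_max, hi_col)
        cols = range(c_min, c_max + 1)
        if dX < 0:
            cols = reversed(cols)
        for c in cols:
            cells.append((r, c))
    if flipped:
        cells.reverse()
    return cells


def elevation_profile(cells: list[Cell], elevation: LandscapeRaster
                      ) -> tuple[float, float, float, float]:
    """(mean, maxdiff, sd, cv) of elevation over the transect cells.

    ``sd`` is the sample standard deviation (n - 1 denominator; a single
    cell gives 0).  ``cv = sd / mean`` is returned as ``nan`` when the mean
    is non-positive; matrix construction turns that into an error naming
    the pair.
    """
    if not cells:
        raise LandresError("empty transect")
    for cell in cells:
        _check_bounds(cell, elevation)
    vals = np.array([elevation.values[c] for c in cells], dtype=float)
    if (vals == elevation.nodata).any():
        raise LandresError(f"nodata elevation on transect {cells[0]}..{cells[-1]}")
    mean = float(vals.mean())
    maxdiff = float(vals.max() - vals.min())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    cv = sd / mean if mean > 0 else float("nan")
    return mean, maxdiff, sd, cv


def landuse_tally(cells: list[Cell], landuse: LandscapeRaster
                  ) -> tuple[dict[int, int], dict[int, int]]:
    """Per-class cell counts and presence indicators along the transect."""
    if not cells:
        raise LandresError("empty transect")
    counts = {code: 0 for code in landuse.class_codes}
    for cell in cells:
        _check_bounds(cell, landuse)
        code = int(landuse.values[cell])
        if code not in counts:
            raise LandresError(f"unknown land-use code {code} at cell {cell}")
        counts[code] += 1
    presence = {code: int(n >= 1) for code, n in counts.items()}
    return counts, presence


@dataclass
class TransectProfile:
    """Summary of the straight-line transect between one pair."""

    pair: tuple[str, str]
    euclid_km: float
    cells: list[Cell]
    elev_mean: float
    elev_maxdiff: float
    elev_sd: float
    elev_cv: float
    landuse_counts: dict[int, int]
    landuse_presence: dict[int, int]


@dataclass
class PairNetwork:
    """One :class:`TransectProfile` per unordered pair of individuals."""

    ids: list[str]
    locations: dict[str, Cell]
    profiles: dict[tuple[str, str], TransectProfile] = field(default_factory=dict)
    class_codes: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_pairs(self) -> int:
        return len(self.profiles)

    def profile(self, id_i: str, id_j: str) -> TransectProfile:
        key = (id_i, id_j) if (id_i, id_j) in self.profiles else (id_j, id_i)
        return self.profiles[key]

    def pairs(self):
        return combinations(self.ids, 2)

    def to_tsv(self, path: str | Path) -> None:
        from .rasters import LANDUSE_CLASSES
        rows = []
        for (a, b), p in self.profiles.items():
            row = {
                "id_i": a, "id_j": b, "euclid_km": p.euclid_km,
                "n_cells": len(p.cells),
                "elev_mean": p.elev_mean, "elev_maxdiff": p.elev_maxdiff,
                "elev_sd": p.elev_sd, "elev_cv": p.elev_cv,
            }
            for code in self.class_codes:
                row[f"count_{LANDUSE_CLASSES.get(code, code)}"] = p.landuse_counts[code]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_network(locations: dict[str, Cell], elevation: LandscapeRaster,
                  landuse: LandscapeRaster) -> PairNetwork:
    """Build the all-pairs transect network over a common grid.

    ``locations`` maps individual id to its 0-based (row, col) cell.  Both
    rasters must share the analysis-grid shape.
    """
    if elevation.shape != landuse.shape:
        raise ConfigurationError(
            f"raster shape mismatch: elevation {elevation.shape} vs "
            f"landuse {landuse.shape}"
        )
    ids = list(locations)
    for ind, cell in locations.items():
        _check_bounds(cell, elevation)
    network = PairNetwork(ids=ids, locations=dict(locations),
                          class_codes=tuple(landuse.class_codes))
    for a, b in combinations(ids, 2):
        ca, cb = locations[a], locations[b]
        cells = supercover_cells(ca, cb)
        mean, maxdiff, sd, cv = elevation_profile(cells, elevation)
        counts, presence = landuse_tally(cells, landuse)
        network.profiles[(a, b)] = TransectProfile(
            pair=(a, b),
            euclid_km=euclidean_km(ca, cb, elevation.cell_size_km),
            cells=cells,
            elev_mean=mean, elev_maxdiff=maxdiff, elev_sd=sd, elev_cv=cv,
            landuse_counts=counts, landuse_presence=presence,
        )
    return network
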