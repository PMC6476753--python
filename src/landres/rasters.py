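"""Gridded landscape layers on the 1-km analysis grid.

A :class:`LandscapeRaster` is either a continuous elevation surface (metres)
or a categorical land-use map with integer class codes.  Cell addressing is
0-based ``(row, col)`` with row 0 at the top; cell centres sit at
``(row + 0.5, col + 0.5)`` in kilometre units, so the grid itself is the
coordinate system.

I/O uses the ESRI ASCII grid format (``.asc``): a six-line header
(ncols / nrows / xllcorner / yllcorner / cellsize / NODATA_value) followed by
rows of whitespace-separated values, top row first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ParseError

#: Canonical land-use classes, code -> name.  Code order follows decreasing
#: areal share in a forest-dominated temperate landscape.
LANDUSE_CLASSES: dict[int, str] = {
    1: "forest",
    2: "grass_field",
    3: "farmland",
    4: "urban",
    5: "open_water",
    6: "special_matrix",
    7: "wetland",
}

LANDUSE_CODES: dict[str, int] = {v: k for k, v in LANDUSE_CLASSES.items()}

NODATA_DEFAULT = -9999.0


@dataclass
class LandscapeRaster:
    """A rectangular grid layer with 1-km cells.

    Parameters
    ----------
    values
        2-D array; float elevations (m) or integer land-use codes.
    kind
        ``"elevation"`` or ``"landuse"``.
    cell_size_km
        Edge length of a cell; the analysis grid uses 1 km.
    nodata
        Sentinel written to/read from ``.asc`` files.
    """

    values: np.ndarray
    kind: str
    cell_size_km: float = 1.0
    nodata: float = NODATA_DEFAULT
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    class_codes: tuple[int, ...] = field(default=tuple(LANDUSE_CLASSES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConfigurationError("raster values must be a 2-D array")
        if self.kind not in ("elevation", "landuse"):
            raise ConfigurationError(f"unknown raster kind: {self.kind!r}")
        if self.kind == "landuse":
            codes = np.unique(self.values[self.values != self.nodata])
            bad = set(int(c) for c in codes) - set(self.class_codes)
            if bad:
                raise ConfigurationError(
                    f"land-use raster contains undeclared class codes: {sorted(bad)}"
                )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def __getitem__(self, cell: tuple[int, int]):
        return self.values[cell]


def read_ascii_grid(path: str | Path, kind: str) -> LandscapeRaster:
    """Read an ESRI ASCII grid (``.asc``) file.

    Header keys are matched case-insensitively; ``NODATA_value`` is optional.
    """
    path = Path(path)
    header: dict[str, float] = {}
    keys = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in keys:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise ParseError(f"{path}: missing ASCII-grid header key {required!r}")
    try:
        values = np.loadtxt(lines[n_header:], ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed data section: {exc}") from None
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    if kind == "landuse":
        values = values.astype(int)
    return LandscapeRaster(
        values=values,
        kind=kind,
        cell_size_km=header["cellsize"],
        nodata=header.get("nodata_value", NODATA_DEFAULT),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
    )


def write_ascii_grid(raster: LandscapeRaster, path: str | Path) -> None:
    """Write ``raster`` as an ESRI ASCII grid; round-trips values bit-exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.xllcorner}\n")
        fh.write(f"yllcorner {raster.yllcorner}\n")
        fh.write(f"cellsize {raster.cell_size_km}\n")
        fh.write(f"NODATA_value {int(raster.nodata)}\n")
        for row in raster.values:
            if raster.kind == "landuse":
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def resample_mean(raster: LandscapeRaster, factor: int) -> LandscapeRaster:
    """Aggregate a finer raster to the analysis grid by block averaging.

    Emulates bringing a 200-m digital elevation model onto the 1-km grid:
    ``factor`` fine cells along each axis collapse into one coarse cell whose
    value is the block mean.  Only defined for continuous rasters.
    """
    if raster.kind != "elevation":
        raise ConfigurationError("mean resampling is only defined for elevation rasters")
    if factor < 1:
        raise ConfigurationError("resampling factor must be >= 1")
    nr = raster.n_rows // factor
    nc = raster.n_cols // factor
    if nr == 0 or nc == 0:
        raise ConfigurationError("raster smaller than one coarse cell")
    trimmed = raster.values[: nr * factor, : nc * factor]
    coarse = trimmed.reshape(nr, factor, nc, factor).mean(axis=(1, 3))
    return LandscapeRaster(
        values=coarse,
        kind="elevation",
        cell_size_km=raster.cell_size_km * factor,
        nodata=raster.nodata,
        xllcorner=raster.xllcorner,
        yllcorner=raster.yllcorner,
    )
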