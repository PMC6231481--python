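"""Climate raster container and ESRI ASCII grid I/O.

Rasters are stored as plain 2-D float arrays (row 0 = northernmost row) with a
simple square-cell geotransform, and serialised as ESRI ASCII grids (``.asc``),
a whitespace text format readable by every GIS.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: canonical climate variable names: temperature seasonality, minimum
#: temperature of the coldest month, precipitation seasonality, and
#: precipitation of the wettest quarter.
CLIMATE_VARS = ("bio4", "bio6", "bio15", "bio16")

NODATA = -9999.0


@dataclass
class ClimateGrid:
    """A stack of co-registered climate rasters for one epoch.

    Parameters
    ----------
    data
        Mapping from variable name to a ``(ny, nx)`` float array.
    x0, y0
        Longitude/latitude of the *lower-left corner* of the grid, degrees.
    cell
        Cell size in degrees (square cells).
    epoch
        ``"current"`` or ``"future-mean"``.
    members
        For a future-mean grid, the individual ensemble-member grids that
        were averaged (kept so the averaging can be audited).
    """

    data: dict[str, np.ndarray]
    x0: float
    y0: float
    cell: float
    epoch: str = "current"
    members: list["ClimateGrid"] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) != 1:
            raise ValueError(f"variable rasters disagree in shape: {shapes}")
        for name, arr in self.data.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in raster {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.data.values())).shape

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.data)

    def cell_index(self, lon: float | np.ndarray, lat: float | np.ndarray):
        """Row/column of the cell containing (lon, lat); row 0 is the top."""
        ny, nx = self.shape
        col = np.clip(((np.asarray(lon) - self.x0) / self.cell).astype(int), 0, nx - 1)
        row_from_bottom = np.clip(
            ((np.asarray(lat) - self.y0) / self.cell).astype(int), 0, ny - 1
        )
        return ny - 1 - row_from_bottom, col

    def value_at(self, var: str, lon, lat):
        r, c = self.cell_index(lon, lat)
        return self.data[var][r, c]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude/latitude of every cell center, as ``(ny, nx)`` arrays."""
        ny, nx = self.shape
        lon = self.x0 + (np.arange(nx) + 0.5) * self.cell
        lat_bottom_up = self.y0 + (np.arange(ny) + 0.5) * self.cell
        lat = lat_bottom_up[::-1]  # row 0 = north
        return np.meshgrid(lon, lat)

    def aligned_with(self, other: "ClimateGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
            and self.variables == other.variables
        )


def write_esri_ascii(path: str | Path, grid: np.ndarray, x0: float, y0: float,
                     cell: float) -> None:
    path = Path(path)
    ny, nx = grid.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {x0!r}\nyllcorner {y0!r}\n"
        f"cellsize {cell!r}\nNODATA_value {NODATA}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in grid)
    try:
        path.write_text(header + body + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing raster {path}: {exc}") from exc


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read one ESRI ASCII grid; returns (array, x0, y0, cell)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    }:
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    arr = np.loadtxt(lines[i:])
    arr = np.atleast_2d(arr)
    if arr.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise ValueError(f"raster {path}: body shape {arr.shape} disagrees with header")
    return arr, hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"]


def write_climate_grid(grid: ClimateGrid, outdir: str | Path, prefix: str) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for var in grid.variables:
        p = outdir / f"{prefix}_{var}.asc"
        write_esri_ascii(p, grid.data[var], grid.x0, grid.y0, grid.cell)
        paths.append(p)
    return paths


def read_climate_grid(outdir: str | Path, prefix: str, epoch: str = "current",
                      variables=CLIMATE_VARS) -> ClimateGrid:
    outdir = Path(outdir)
    data = {}
    geo = None
    for var in variables:
        arr, x0, y0, cell = read_esri_ascii(outdir / f"{prefix}_{var}.asc")
        if geo is None:
            geo = (x0, y0, cell)
        elif not np.allclose(geo, (x0, y0, cell)):
            raise ValueError(f"raster {var} misaligned with the others")
        data[var] = arr
    assert geo is not None
    return ClimateGrid(data, *geo, epoch=epoch)
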