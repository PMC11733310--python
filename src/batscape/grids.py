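"""Analysis-grid geometry, core raster containers, and plain-text raster I/O.

The whole pipeline works on a single regular grid of square pixels in a
projected coordinate system (meters). Radar scans arrive as binary
presence/absence scenes on that grid; seasonal aggregation produces an
:class:`ActivityRaster` of per-pixel detection counts.

Rasters are persisted as ESRI ASCII grids (``.asc``) — a simple,
georeferenced, text-only raster format. Missing values use a NODATA
sentinel in files and ``NaN`` (float) or an explicit validity mask
(counts) in memory; missing is never silently coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Geometry of the analysis grid.

    Parameters
    ----------
    nrows, ncols
        Grid shape; row 0 is the northernmost row (raster convention).
    pixel_size
        Pixel edge length in meters (70 m in the radar product this
        package emulates; one 70 m pixel covers 0.49 ha).
    x_origin, y_origin
        Projected coordinates (m) of the lower-left corner of the grid.
    """

    nrows: int
    ncols: int
    pixel_size: float = 70.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def pixel_area_ha(self) -> float:
        """Pixel area in hectares: (edge/100)^2 for edge in meters."""
        return (self.pixel_size / 100.0) ** 2

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates, each shaped (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.pixel_size
        # row 0 is the top row
        y = self.y_origin + (self.nrows - rows - 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def center_lonlat(
        self, ref_lon: float = -121.7, ref_lat: float = 38.5
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pixel centers as (lon, lat) degrees via a local equirectangular
        approximation anchored at the grid's lower-left corner."""
        x, y = self.pixel_centers()
        m_per_deg_lat = 111_320.0
        m_per_deg_lon = m_per_deg_lat * np.cos(np.deg2rad(ref_lat))
        lon = ref_lon + (x - self.x_origin) / m_per_deg_lon
        lat = ref_lat + (y - self.y_origin) / m_per_deg_lat
        return lon, lat


@dataclass(frozen=True)
class PresenceScene:
    """One radar scan's binary bat detections on the analysis grid."""

    values: np.ndarray  # uint8 {0, 1}, shape = grid.shape
    grid: Grid
    timestamp: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != self.grid.shape:
            raise ValueError(
                f"scene shape {v.shape} does not match grid {self.grid.shape}"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("presence scenes must be strictly binary")
        object.__setattr__(self, "values", v.astype(np.uint8))


@dataclass
class ActivityRaster:
    """Seasonal per-pixel occurrence counts.

    ``counts[i, j]`` is the number of scans in which pixel (i, j) held a
    detection. ``valid`` marks pixels that survive masking; statistics
    must exclude invalid pixels rather than treat them as zero.
    """

    counts: np.ndarray  # int64
    grid: Grid
    n_nights: int
    n_scenes: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if self.n_nights < 1:
            raise ValueError("n_nights must be >= 1")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.n_scenes and (self.counts > self.n_scenes).any():
            raise ValueError("a pixel count exceeds the number of scenes")
        if self.valid is None:
            self.valid = np.ones(self.counts.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.counts.shape:
                raise ValueError("validity mask shape does not match grid")

    @property
    def pixel_area_ha(self) -> float:
        return self.grid.pixel_area_ha


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: Grid) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN becomes NODATA."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape does not match grid")
    out = np.where(np.isnan(values), NODATA, values)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid; NODATA becomes NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float)
    grid = Grid(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        pixel_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
    )
    values = np.atleast_2d(values).reshape(grid.shape)
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return values, grid
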