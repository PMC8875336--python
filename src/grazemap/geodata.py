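"""Raster data model, NDVI, terrain derivatives, and plain-text raster I/O.

The package works on small single-band rasters over a local planar
coordinate system (metres).  Row 0 is the northernmost row; a cell
``(row, col)`` covers the half-open square
``[x0 + col*s, x0 + (col+1)*s) x (y0 - (row+1)*s, y0 - row*s]``
where ``(x0, y0)`` is the outer (north-west) corner of the top-left cell
and ``s`` the cell size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: Recognised band meanings.
BAND_MEANINGS = frozenset(
    {"dem", "nir", "red", "ndvi", "slope", "aspect", "density", "intensity", "grades"}
)

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band regular grid of one variable.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; ``nodata`` marks missing cells.
    origin : (float, float)
        Planar (x, y) of the north-west corner of the top-left cell, metres.
    cell_size : float
        Cell edge length in metres.
    nodata : float
        Sentinel for missing cells.
    band_meaning : str
        One of :data:`BAND_MEANINGS`.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = DEFAULT_NODATA
    band_meaning: str = "dem"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster values must be a 2-D grid with >= 1 cell")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.band_meaning not in BAND_MEANINGS:
            raise ValueError(f"unknown band_meaning {self.band_meaning!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return ~np.isclose(self.values, self.nodata)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing planar point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nrows, ncols = self.shape
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({x:.2f}, {y:.2f}) outside raster extent {self.extent}")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of all cell-centre coordinates, shape (nrows, ncols)."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def copy_with(self, values: np.ndarray, band_meaning: str | None = None) -> "Raster":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            band_meaning=band_meaning or self.band_meaning,
        )


def _check_aligned(a: Raster, b: Raster) -> None:
    if a.shape != b.shape:
        raise ValueError(f"raster shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.origin, b.origin) or not np.isclose(a.cell_size, b.cell_size):
        raise ValueError("raster origin/cell_size mismatch")


def compute_ndvi(nir: Raster, red: Raster, *, clamp_negative: bool = True) -> Raster:
    """Normalized difference vegetation index, (NIR - red) / (NIR + red).

    Cells with a zero denominator become nodata.  Negative values (bare
    soil, water) are clamped to 0 by default so the output lies in [0, 1];
    the number of clamped cells is logged.
    """
    _check_aligned(nir, red)
    valid = nir.mask() & red.mask()
    denom = nir.values + red.values
    out = np.full(nir.shape, nir.nodata, dtype=float)
    ok = valid & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[ok] = (nir.values[ok] - red.values[ok]) / denom[ok]
    if clamp_negative:
        neg = ok & (out < 0)
        n_neg = int(neg.sum())
        if n_neg:
            logger.info("compute_ndvi: clamped %d negative NDVI cells to 0", n_neg)
        out[neg] = 0.0
    return Raster(out, nir.origin, nir.cell_size, nir.nodata, "ndvi")


def compute_slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope and aspect from a DEM by Horn's 3x3 finite differences.

    Slope is ``atan(|grad z|)`` in degrees [0, 90].  Aspect is the compass
    bearing of the downslope direction (0 deg = north, clockwise, [0, 360));
    flat cells (gradient magnitude < 1e-8) get aspect nodata.  Border cells
    are handled by odd reflection (linear extrapolation), which keeps an
    inclined plane exactly planar up to the edge.
    """
    nrows, ncols = dem.shape
    if nrows < 3 or ncols < 3:
        raise ValueError("DEM must be at least 3x3 for slope/aspect")
    z = np.pad(dem.values, 1, mode="reflect", reflect_type="odd")
    s = dem.cell_size
    # Horn kernel neighbours (a..i, row-major around the centre e)
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * s)
    # row index grows southwards, so the north derivative flips sign
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * s)
    grad = np.hypot(dz_dx, dz_dy)
    slope = np.degrees(np.arctan(grad))
    # downslope unit direction is -grad; bearing measured from north, clockwise
    aspect = (np.degrees(np.arctan2(-dz_dx, -dz_dy))) % 360.0
    flat = grad < 1e-8
    aspect[flat] = dem.nodata
    return (
        Raster(slope, dem.origin, dem.cell_size, dem.nodata, "slope"),
        Raster(aspect, dem.origin, dem.cell_size, dem.nodata, "aspect"),
    )


def sample_raster(
    raster: Raster, point: tuple[float, float], *, method: str = "nearest"
) -> float:
    """Sample a raster at a planar point.

    ``nearest`` returns the containing cell's value.  ``bilinear``
    interpolates between the four surrounding cell centres (clamped at the
    border) and propagates nodata from any contributing cell.
    """
    x, y = point
    xmin, ymin, xmax, ymax = raster.extent
    if not (xmin <= x < xmax and ymin < y <= ymax):
        raise ValueError(
            f"point ({x:.3f}, {y:.3f}) outside raster extent "
            f"x[{xmin:.3f}, {xmax:.3f}) y({ymin:.3f}, {ymax:.3f}]"
        )
    if method == "nearest":
        row, col = raster.cell_of(x, y)
        return float(raster.values[row, col])
    if method != "bilinear":
        raise ValueError(f"unknown sampling method {method!r}")
    nrows, ncols = raster.shape
    x0, y0 = raster.origin
    s = raster.cell_size
    # fractional position in cell-centre coordinates
    fc = (x - x0) / s - 0.5
    fr = (y0 - y) / s - 0.5
    c0 = int(np.clip(np.floor(fc), 0, ncols - 1))
    r0 = int(np.clip(np.floor(fr), 0, nrows - 1))
    c1 = min(c0 + 1, ncols - 1)
    r1 = min(r0 + 1, nrows - 1)
    tx = float(np.clip(fc - c0, 0.0, 1.0))
    ty = float(np.clip(fr - r0, 0.0, 1.0))
    corners = raster.values[[r0, r0, r1, r1], [c0, c1, c0, c1]]
    if np.any(np.isclose(corners, raster.nodata)):
        return float(raster.nodata)
    v00, v01, v10, v11 = corners
    top = v00 * (1 - tx) + v01 * tx
    bot = v10 * (1 - tx) + v11 * tx
    return float(top * (1 - ty) + bot * ty)


# -- ESRI ASCII grid I/O --------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (plain text)."""
    nrows, ncols = raster.shape
    x0, y0 = raster.origin
    yll = y0 - nrows * raster.cell_size
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {x0!r}",
        f"yllcorner {yll!r}",
        f"cellsize {raster.cell_size!r}",
        f"NODATA_value {raster.nodata!r}",
    ]
    body = "\n".join(
        " ".join(np.format_float_positional(v, trim="0") for v in row)
        for row in raster.values.astype(np.float32)
    )
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_ascii_grid(path: str | Path, band_meaning: str = "dem") -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any tool)."""
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    idx = 0
    for idx, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"ASCII grid header missing: {sorted(missing)}")
    values = np.loadtxt(text[idx:], dtype=float)
    values = np.atleast_2d(values)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"grid body {values.shape} does not match header ({nrows}, {ncols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Raster(values, origin, cell, header.get("nodata_value", DEFAULT_NODATA), band_meaning)


# -- planar <-> geographic ------------------------------------------------

EARTH_RADIUS_M = 6_371_000.0


def planar_to_lonlat(
    x: np.ndarray | float,
    y: np.ndarray | float,
    anchor: tuple[float, float] = (39.0, 107.6),
) -> tuple[np.ndarray, np.ndarray]:
    """Local metres -> (lon, lat) via equirectangular projection about ``anchor``.

    ``anchor`` is (latitude, longitude) in degrees at local (0, 0).  Exact
    inverse of :func:`lonlat_to_planar`; adequate over the few-kilometre
    extent of a grazing paddock.
    """
    lat0, lon0 = anchor
    lat = lat0 + np.degrees(np.asarray(y) / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(np.asarray(x) / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    return lon, lat


def lonlat_to_planar(
    lon: np.ndarray | float,
    lat: np.ndarray | float,
    anchor: tuple[float, float] = (39.0, 107.6),
) -> tuple[np.ndarray, np.ndarray]:
    """(lon, lat) degrees -> local planar metres about ``anchor``."""
    lat0, lon0 = anchor
    x = np.radians(np.asarray(lon) - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(np.asarray(lat) - lat0) * EARTH_RADIUS_M
    return x, y
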