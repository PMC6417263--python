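"""Raster data model, I/O and harmonisation onto a common analysis grid.

All layers of one model run live on a single projected metric CRS (the
original study pre-projected everything to one Gauss-Krueger zone); no
reprojection is performed here.  The coordinate convention used throughout
the package is fixed once:

* ``origin`` is the (x, y) of the **upper-left corner of the upper-left
  cell**; the row index grows southward.
* cell ``(i, j)`` covers the half-open square
  ``[x0 + j*c, x0 + (j+1)*c) x (y0 - (i+1)*c, y0 - i*c]``
  with ``c`` the cell size -- i.e. a point on a shared vertical edge
  belongs to the cell on its right, a point on a shared horizontal edge
  to the cell above.

Supported on-disk formats are ESRI ASCII grid (``.asc``/``.agr``/``.txt``)
and single-band GeoTIFF (``.tif``/``.tiff``); both carry an explicit
nodata value.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "Semantics",
    "GridRaster",
    "GridSpec",
    "RasterFormatError",
    "GridAlignmentError",
    "SemanticsError",
    "read_raster",
    "write_raster",
    "resample_to_grid",
]

Semantics = Literal["categorical", "suitability", "wind", "climate"]

#: semantics for which cell values are discrete codes
CATEGORICAL: frozenset[str] = frozenset({"categorical"})


class RasterFormatError(ValueError):
    """Raised for unreadable, malformed or unsupported grid files."""


class GridAlignmentError(ValueError):
    """Raised when an operation requires identical grids and they differ."""


class SemanticsError(ValueError):
    """Raised when an operation is incompatible with a raster's semantics."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an analysis grid: cell size and extent in map units (m).

    The extent is ``(xmin, ymin, xmax, ymax)``; its width and height must
    be integer multiples of ``cell_size``.  The origin (upper-left corner)
    is ``(xmin, ymax)``.
    """

    cell_size: float
    extent: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive width and height")
        for span in (xmax - xmin, ymax - ymin):
            ratio = span / self.cell_size
            if abs(ratio - round(ratio)) > 1e-6:
                raise ValueError(
                    "extent dimensions must be integer multiples of cell_size"
                )

    @property
    def ncols(self) -> int:
        xmin, _, xmax, _ = self.extent
        return round((xmax - xmin) / self.cell_size)

    @property
    def nrows(self) -> int:
        _, ymin, _, ymax = self.extent
        return round((ymax - ymin) / self.cell_size)

    @property
    def origin(self) -> tuple[float, float]:
        xmin, _, _, ymax = self.extent
        return (xmin, ymax)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 1-D arrays (cols, rows)."""
        x0, y0 = self.origin
        c = self.cell_size
        xs = x0 + (np.arange(self.ncols) + 0.5) * c
        ys = y0 - (np.arange(self.nrows) + 0.5) * c
        return xs, ys


@dataclass
class GridRaster:
    """A 2-D cell array with uniform cell size, origin and nodata sentinel.

    ``semantics`` declares what the numbers mean and gates which
    operations are allowed:

    ``categorical``
        integer land-use class codes; only nearest-neighbour resampling.
    ``suitability``
        values in [0, 1] (or nodata).
    ``wind``
        mean wind speed in m/s, non-negative.
    ``climate``
        a physical climate feature (mm, degC, index); unconstrained.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata: float = -9999.0
    semantics: Semantics = "climate"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        """Check the value-range invariants implied by ``semantics``."""
        data = self.data_values()
        if data.size == 0:
            return
        if self.semantics == "suitability":
            if data.min() < 0 or data.max() > 1:
                raise ValueError(
                    "suitability raster has values outside [0, 1]: "
                    f"range [{data.min():g}, {data.max():g}]"
                )
        elif self.semantics == "wind":
            if data.min() < 0:
                raise ValueError("wind raster has negative values")

    # -- helpers ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def spec(self) -> GridSpec:
        x0, y0 = self.origin
        nrows, ncols = self.values.shape
        return GridSpec(
            self.cell_size,
            (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0),
        )

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask, True where a cell is nodata (NaN counts as nodata)."""
        vals = self.values
        mask = vals == self.nodata
        if np.issubdtype(vals.dtype, np.floating):
            mask |= np.isnan(vals)
        return mask

    def data_values(self) -> np.ndarray:
        """1-D array of the non-nodata cell values."""
        return self.values[~self.nodata_mask()]

    def with_values(self, values: np.ndarray, semantics: Semantics | None = None,
                    nodata: float | None = None) -> "GridRaster":
        """Same grid geometry, new cell values (and optionally semantics)."""
        return GridRaster(
            np.asarray(values),
            self.cell_size,
            self.origin,
            nodata=self.nodata if nodata is None else nodata,
            semantics=semantics or self.semantics,
            meta=dict(self.meta),
        )

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) indices under the package convention.

        Cells are half-open: ``[x_left, x_right)`` horizontally and
        ``(y_bottom, y_top]`` vertically.  Indices may fall outside the
        raster; callers decide how to treat those.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        # ceil for the half-open (bottom, top] interval on y
        row = np.ceil((y0 - y) / self.cell_size).astype(int) - 1
        # the top edge of the raster belongs to row 0
        row = np.where(np.asarray(y) == y0, 0, row)
        return row, col

    def aligned_with(self, other: "GridRaster", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, abs_tol=tol)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=tol)
            and math.isclose(self.origin[1], other.origin[1], abs_tol=tol)
        )


def require_aligned(*rasters: GridRaster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.aligned_with(r):
            raise GridAlignmentError(
                "rasters are not on the same grid: "
                f"{first.shape}@{first.origin}/{first.cell_size} vs "
                f"{r.shape}@{r.origin}/{r.cell_size}"
            )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_ASC_EXT = {".asc", ".agr", ".txt"}
_TIF_EXT = {".tif", ".tiff"}


def _read_ascii(path: str) -> GridRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    idx = 0
    while idx < len(lines):
        parts = lines[idx].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            idx += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"{path}: missing required header '{key}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if cell <= 0:
        raise RasterFormatError(f"{path}: non-positive cellsize")
    nodata = header.get("nodata_value", -9999.0)
    try:
        flat = np.array(" ".join(lines[idx:]).split(), dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric cell data ({exc})") from exc
    if flat.size != nrows * ncols:
        raise RasterFormatError(
            f"{path}: header promises {nrows}x{ncols}={nrows * ncols} cells, "
            f"file contains {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    if "xllcenter" in header:
        xll = header["xllcenter"] - cell / 2
    else:
        xll = header.get("xllcorner", 0.0)
    if "yllcenter" in header:
        yll = header["yllcenter"] - cell / 2
    else:
        yll = header.get("yllcorner", 0.0)
    origin = (xll, yll + nrows * cell)
    return GridRaster(values, cell, origin, nodata=nodata)


def _write_ascii(r: GridRaster, path: str) -> None:
    nrows, ncols = r.shape
    x0, y0 = r.origin
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {y0 - nrows * r.cell_size:.6f}\n")
        fh.write(f"cellsize {r.cell_size:.6f}\n")
        fh.write(f"NODATA_value {r.nodata:g}\n")
        for row in r.values:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band, via tifffile + the standard geo tags)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _read_tiff(path: str) -> GridRaster:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            tags = {tag.code: tag.value for tag in page.tags.values()}
    except (tifffile.TiffFileError, OSError) as exc:
        raise RasterFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    if values.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single-band raster")
    scale = tags.get(_TAG_PIXEL_SCALE)
    tie = tags.get(_TAG_TIEPOINT)
    if scale is None or tie is None:
        raise RasterFormatError(f"{path}: missing georeferencing tags")
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise RasterFormatError(f"{path}: non-uniform cell size {sx} x {sy}")
    # tiepoint maps raster point (i, j, k) to model point (x, y, z)
    px, py = float(tie[0]), float(tie[1])
    mx, my = float(tie[3]), float(tie[4])
    origin = (mx - px * sx, my + py * sy)
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
    return GridRaster(np.asarray(values, dtype=float), sx, origin, nodata=nodata)


def _write_tiff(r: GridRaster, path: str) -> None:
    import tifffile

    c = float(r.cell_size)
    x0, y0 = (float(v) for v in r.origin)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (c, c, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{r.nodata:g}"),
    ]
    tifffile.imwrite(path, np.asarray(r.values, dtype=np.float64),
                     extratags=extratags)


def read_raster(path: str, semantics: Semantics | None = None) -> GridRaster:
    """Read a grid file (ESRI ASCII or GeoTIFF) into a :class:`GridRaster`.

    ``semantics`` is assigned by the caller; it defaults to ``climate``
    (the unconstrained physical-unit kind).  The nodata sentinel is taken
    from the file.
    """
    if not os.path.exists(path):
        raise RasterFormatError(f"no such file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in _ASC_EXT:
        r = _read_ascii(path)
    elif ext in _TIF_EXT:
        r = _read_tiff(path)
    else:
        raise RasterFormatError(f"unsupported raster format: {ext!r}")
    if semantics is not None:
        r = replace(r, semantics=semantics)
        r.validate()
    return r


def write_raster(r: GridRaster, path: str) -> None:
    """Write a :class:`GridRaster` as ESRI ASCII or GeoTIFF (by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext in _ASC_EXT:
        _write_ascii(r, path)
    elif ext in _TIF_EXT:
        _write_tiff(r, path)
    else:
        raise RasterFormatError(f"unsupported raster format: {ext!r}")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_grid(r: GridRaster, target: GridSpec,
                     method: Literal["nearest", "mean"] = "nearest") -> GridRaster:
    """Resample a raster onto a target grid.

    ``nearest`` assigns each target cell the value of the source cell
    containing the target cell's center, so it never invents values and
    is the only method allowed for categorical rasters.  ``mean``
    averages the non-nodata source cells whose centers fall inside each
    target cell (aggregation to a coarser grid); where the target is
    finer than the source it degrades gracefully to the containing-cell
    value.  Nodata propagates in both cases.
    """
    if method not in ("nearest", "mean"):
        raise ValueError(f"unknown resampling method: {method!r}")
    if method == "mean" and r.semantics in CATEGORICAL:
        raise SemanticsError("mean-resampling a categorical raster is undefined")

    xs, ys = target.cell_centers()
    if method == "nearest":
        rows, cols = r.index_of(
            np.repeat(xs[None, :], target.nrows, axis=0),
            np.repeat(ys[:, None], target.ncols, axis=1),
        )
        rows = np.clip(rows, 0, r.shape[0] - 1)
        cols = np.clip(cols, 0, r.shape[1] - 1)
        out = r.values[rows, cols]
        return GridRaster(out, target.cell_size, target.origin,
                          nodata=r.nodata, semantics=r.semantics,
                          meta=dict(r.meta))

    # mean: bin source cell centers into target cells
    src_xs, src_ys = r.spec.cell_centers()
    cx = np.repeat(src_xs[None, :], r.shape[0], axis=0).ravel()
    cy = np.repeat(src_ys[:, None], r.shape[1], axis=1).ravel()
    tx0, ty0 = target.origin
    tcol = np.floor((cx - tx0) / target.cell_size).astype(int)
    trow = np.floor((ty0 - cy) / target.cell_size).astype(int)
    inside = (
        (tcol >= 0) & (tcol < target.ncols) & (trow >= 0) & (trow < target.nrows)
    )
    vals = r.values.ravel()
    valid = inside & ~r.nodata_mask().ravel()
    sums = np.zeros((target.nrows, target.ncols))
    counts = np.zeros((target.nrows, target.ncols))
    np.add.at(sums, (trow[valid], tcol[valid]), vals[valid])
    np.add.at(counts, (trow[valid], tcol[valid]), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), r.nodata)
    # target cells that received no source center: fall back to nearest
    if np.any(counts == 0):
        nearest = resample_to_grid(r, target, "nearest").values
        out = np.where(counts == 0, nearest, out)
    return GridRaster(out, target.cell_size, target.origin,
                      nodata=r.nodata, semantics=r.semantics, meta=dict(r.meta))
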