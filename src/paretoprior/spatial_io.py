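"""Raster I/O, rank maps, percentile classification, and zonal summaries.

Two single-band raster formats are supported, chosen by file extension:

* ``.asc`` — ESRI ASCII grid, the plain-text GIS interchange format
  (header of ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value followed
  by rows from north to south);
* ``.tif``/``.tiff`` — single-band TIFF written with :mod:`tifffile`, with
  georeference carried in an ESRI world-file sidecar (``.tfw``).

All grids in a run must align exactly (shape, origin, cell size).  Rank
rasters are integers with nodata 0, since ranks start at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .criteria import DecisionMatrix
from .ranking import UNRANKED, RankAssignment
from .stack import AttributeStack

__all__ = [
    "RankGrid",
    "read_raster",
    "write_raster",
    "read_stack",
    "ranks_to_grid",
    "write_rank_grid",
    "read_rank_grid",
    "percentile_threshold",
    "zonal_summary",
    "median_rank_profile",
]

_FLOAT_NODATA = -9999.0


@dataclass
class RankGrid:
    """Per-cell positive integer Pareto rank; 0 = nodata (cell not ranked)."""

    grid: np.ndarray
    cell_size: float = 50.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: int = UNRANKED

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int32)

    @property
    def ranked_mask(self) -> np.ndarray:
        return self.grid != self.nodata

    def ranked_values(self) -> np.ndarray:
        return self.grid[self.ranked_mask]


# ---------------------------------------------------------------------------
# raster files

def write_raster(path, grid, cell_size=50.0, origin=(0.0, 0.0), nodata=_FLOAT_NODATA):
    """Write a single-band raster (.asc text or .tif + .tfw world file)."""
    path = Path(path)
    grid = np.asarray(grid)
    if path.suffix.lower() == ".asc":
        _write_asc(path, grid, cell_size, origin, nodata)
    elif path.suffix.lower() in (".tif", ".tiff"):
        out = grid.astype(np.float64) if grid.dtype.kind == "f" else grid.astype(np.int32)
        if out.dtype.kind == "f":
            out = np.where(np.isnan(out), nodata, out)
        tifffile.imwrite(path, out, metadata={"nodata": float(nodata)})
        _write_world_file(path.with_suffix(".tfw"), cell_size, origin)
    else:
        raise ValueError(f"unsupported raster extension {path.suffix!r} (use .asc or .tif)")


def read_raster(path):
    """Read a raster; returns (grid, cell_size, origin, nodata).

    Float grids come back with nodata replaced by NaN; integer grids keep
    the nodata value in place.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".asc":
        return _read_asc(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            grid = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        nodata = float(meta.get("nodata", _FLOAT_NODATA))
        cell_size, origin = _read_world_file(path.with_suffix(".tfw"))
        if grid.dtype.kind == "f":
            grid = np.where(grid == nodata, np.nan, grid)
        return grid, cell_size, origin, nodata
    raise ValueError(f"unsupported raster extension {path.suffix!r} (use .asc or .tif)")


def _write_asc(path, grid, cell_size, origin, nodata):
    nrows, ncols = grid.shape
    x0, y_top = origin
    is_int = grid.dtype.kind in "iub"
    out = grid.astype(float).copy()
    if not is_int:
        out[np.isnan(out)] = nodata
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y_top - nrows * cell_size}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {int(nodata) if is_int else nodata}\n"
    )
    fmt = "%d" if is_int else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def _read_asc(path):
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _FLOAT_NODATA)
    origin = (header["xllcorner"], header["yllcorner"] + header["nrows"] * cell)
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, cell, origin, nodata


def _write_world_file(path, cell_size, origin):
    x0, y_top = origin
    lines = [cell_size, 0.0, 0.0, -cell_size, x0 + cell_size / 2, y_top - cell_size / 2]
    Path(path).write_text("\n".join(f"{v:.10g}" for v in lines) + "\n")


def _read_world_file(path):
    path = Path(path)
    if not path.exists():
        return 50.0, (0.0, 0.0)
    a, _, _, e, c, f = (float(s) for s in path.read_text().split())
    cell = a
    return cell, (c - cell / 2, f - e / 2)  # e = -cell, so f - e/2 = f + cell/2


# ---------------------------------------------------------------------------
# stacks

def read_stack(layer_files: dict, mask_file, zones_file=None, conserved_file=None) -> AttributeStack:
    """Load aligned layer rasters plus mask/zones/conserved into a stack.

    ``layer_files`` maps layer name to path.  Every grid must match the
    mask's shape, cell size, and origin; nodata cells become NaN.
    """
    mask, cell, origin, _ = read_raster(mask_file)
    mask = np.nan_to_num(np.asarray(mask, dtype=float)) != 0
    layers = {}
    for name, f in layer_files.items():
        grid, c, o, _ = read_raster(f)
        _check_aligned(name, grid, c, o, mask.shape, cell, origin)
        layers[name] = np.asarray(grid, dtype=float)
    zones = conserved = None
    if zones_file is not None:
        zones, c, o, _ = read_raster(zones_file)
        _check_aligned("zones", zones, c, o, mask.shape, cell, origin)
        zones = np.nan_to_num(np.asarray(zones, dtype=float)).astype(int)
    if conserved_file is not None:
        conserved, c, o, _ = read_raster(conserved_file)
        _check_aligned("conserved", conserved, c, o, mask.shape, cell, origin)
        conserved = np.nan_to_num(np.asarray(conserved, dtype=float)) != 0
    return AttributeStack(layers, mask, cell, zones, conserved, origin)


def _check_aligned(name, grid, cell, origin, shape, ref_cell, ref_origin):
    if grid.shape != shape:
        raise ValueError(f"layer {name!r} shape {grid.shape} != mask shape {shape}")
    if not np.isclose(cell, ref_cell) or not np.allclose(origin, ref_origin):
        raise ValueError(f"layer {name!r} georeference does not match the mask")


# ---------------------------------------------------------------------------
# rank maps and summaries

def ranks_to_grid(X: DecisionMatrix, ranks: RankAssignment, stack: AttributeStack) -> RankGrid:
    """Scatter per-alternative ranks back onto the stack's grid.

    Alternative ids are row-major cell indices.  Invalid or out-of-mask
    cells get nodata (0).
    """
    if not np.array_equal(X.ids, ranks.ids):
        raise ValueError("decision matrix and rank assignment cover different ids")
    ids = np.asarray(ranks.ids, dtype=int)
    if ids.size == 0 or ids.min() < 0 or ids.max() >= stack.n_cells:
        raise ValueError("alternative ids do not map onto the stack grid")
    flat = np.full(stack.n_cells, UNRANKED, dtype=np.int32)
    flat[ids] = ranks.rank
    return RankGrid(flat.reshape(stack.grid_shape), stack.cell_size, stack.origin)


def write_rank_grid(path, rg: RankGrid) -> None:
    write_raster(path, rg.grid.astype(np.int32), rg.cell_size, rg.origin, nodata=rg.nodata)


def read_rank_grid(path) -> RankGrid:
    grid, cell, origin, nodata = read_raster(path)
    grid = np.nan_to_num(np.asarray(grid, dtype=float), nan=nodata)
    return RankGrid(grid.astype(np.int32), cell, origin, int(nodata))


def percentile_threshold(ranks, q: float = 0.25) -> int:
    """Smallest rank t with at least a fraction q of ranked cells at rank <= t.

    Nearest-rank rule on the empirical CDF; chosen over interpolating
    estimators because ranks are small integers with heavy ties and an
    interpolated threshold could be a value no cell attains.
    """
    ranks = np.asarray(ranks)
    ranks = ranks[ranks != UNRANKED]
    if ranks.size == 0:
        raise ValueError("no ranked cells")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    s = np.sort(ranks)
    return int(s[int(np.ceil(q * s.size)) - 1])


def zonal_summary(rank_grid: RankGrid, zones, conserved, q: float = 0.25) -> pd.DataFrame:
    """Percent of ranked cells at or below the rank-percentile threshold,
    per (zone, conservation status) stratum.

    The threshold is computed once over ALL ranked cells of this rank grid
    and then applied within each stratum, so strata percentages are
    comparable.  Strata with no ranked cells are omitted.
    """
    zones = np.asarray(zones)
    conserved = np.asarray(conserved, dtype=bool)
    if zones.shape != rank_grid.grid.shape or conserved.shape != rank_grid.grid.shape:
        raise ValueError("zones/conserved not aligned with rank grid")
    ranked = rank_grid.ranked_mask
    if not ranked.any():
        raise ValueError("no ranked cells to summarize")
    t = percentile_threshold(rank_grid.grid[ranked], q)
    rows = []
    for zone in np.unique(zones[ranked]):
        for status in (False, True):
            sel = ranked & (zones == zone) & (conserved == status)
            n = int(sel.sum())
            if n == 0:
                continue
            n_below = int((rank_grid.grid[sel] <= t).sum())
            rows.append(
                {
                    "zone": zone,
                    "conserved": status,
                    "n_cells": n,
                    "n_at_or_below": n_below,
                    "percent": 100.0 * n_below / n,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["rank_threshold"] = t
    out.attrs["q"] = q
    return out


def median_rank_profile(rank_grid: RankGrid, axis: str = "row") -> np.ndarray:
    """Median rank of ranked cells along each grid row (northing profile)
    or column (easting profile); lines with no ranked cells are NaN."""
    if axis not in ("row", "column"):
        raise ValueError("axis must be 'row' or 'column'")
    g = np.where(rank_grid.ranked_mask, rank_grid.grid, np.nan).astype(float)
    if g.size == 0:
        raise ValueError("empty grid")
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(g, axis=1 if axis == "row" else 0)
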