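"""Aligned raster attribute stacks.

An :class:`AttributeStack` bundles the per-cell attribute layers for a study
area on a single common grid, together with the analysis mask, an optional
categorical zone layer (e.g. climate zones used for summarization) and an
optional binary conservation-status layer.  Missing cells are NaN; all
layers share shape, origin and cell size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AttributeStack"]


@dataclass
class AttributeStack:
    """Named, grid-aligned attribute layers with mask and ancillary layers.

    Parameters
    ----------
    layers : dict of str -> ndarray
        Per-cell real-valued grids (NaN = missing), all of one shape.
    mask : ndarray of bool
        True where a cell is inside the analysis area.
    cell_size : float
        Cell edge length in meters (> 0).
    zones : ndarray of int, optional
        Categorical zone label per cell (summarization stratum).
    conserved : ndarray of bool, optional
        Conservation status per cell.
    origin : (float, float)
        World coordinates (x, y) of the upper-left corner of cell (0, 0).
    """

    layers: dict[str, np.ndarray]
    mask: np.ndarray
    cell_size: float = 50.0
    zones: np.ndarray | None = None
    conserved: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    grid_shape: tuple[int, int] = field(init=False)

    def __post_init__(self):
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.grid_shape = self.mask.shape
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}
        for name, grid in self.layers.items():
            if grid.shape != self.grid_shape:
                raise ValueError(
                    f"layer {name!r} shape {grid.shape} != grid shape {self.grid_shape}"
                )
        for attr in ("zones", "conserved"):
            grid = getattr(self, attr)
            if grid is not None:
                grid = np.asarray(grid)
                if grid.shape != self.grid_shape:
                    raise ValueError(f"{attr} shape {grid.shape} != grid shape {self.grid_shape}")
                setattr(self, attr, grid)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.grid_shape))

    def cell_ids(self) -> np.ndarray:
        """Row-major cell index k = i * n_cols + j for every grid cell."""
        return np.arange(self.n_cells)

    def masked_values(self, name: str) -> np.ndarray:
        """Flat layer values with out-of-mask cells set to NaN."""
        if name not in self.layers:
            raise KeyError(f"unknown layer {name!r}; have {sorted(self.layers)}")
        vals = self.layers[name].astype(float).ravel().copy()
        vals[~self.mask.ravel()] = np.nan
        return vals

    def add_layer(self, name: str, grid: np.ndarray) -> None:
        grid = np.asarray(grid, dtype=float)
        if grid.shape != self.grid_shape:
            raise ValueError(f"layer {name!r} shape {grid.shape} != grid shape {self.grid_shape}")
        self.layers[name] = grid
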