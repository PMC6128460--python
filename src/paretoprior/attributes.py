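"""Derivation of threat and biodiversity attribute layers from raster primitives.

Inputs are already-rasterized binary or continuous grids on the common
analysis grid; vector-to-raster conversion happens upstream.  Implemented
derivations:

* fire counts from stacked historical fire-perimeter rasters,
* circular focal densities (road density; urban + weighted-agriculture
  development density) in a metric radius around each cell center,
* road-free / non-urban patch areas by connected-component labeling,
* taxon richness as the sum of per-species habitat-suitability surfaces,
  optionally thresholded to binary presence first.

Externally modeled layers (ignition probability, fire return interval
departure, genetic diversity/divergence) are consumed as provided.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "count_overlapping_fires",
    "circular_footprint",
    "focal_density",
    "development_density",
    "patch_area",
    "stack_sdm_richness",
    "derive_standard_attributes",
]


def _check_binary(grid: np.ndarray, what: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if not np.isin(grid[~np.isnan(grid)], (0.0, 1.0)).all():
        raise ValueError(f"{what} grid must be binary (0/1)")
    return grid


def count_overlapping_fires(perimeter_layers) -> np.ndarray:
    """Per-cell number of fire perimeters covering the cell.

    Each layer is a binary indicator of one historical fire's footprint;
    stacking them counts how often a cell burned over the record.
    """
    layers = [_check_binary(g, "fire perimeter") for g in perimeter_layers]
    if not layers:
        raise ValueError("need at least one perimeter layer")
    shape = layers[0].shape
    for g in layers[1:]:
        if g.shape != shape:
            raise ValueError("perimeter layers are not aligned")
    return np.sum(layers, axis=0)


def circular_footprint(radius: float, cell_size: float) -> np.ndarray:
    """Boolean kernel of cells whose centers lie within ``radius`` meters.

    Membership uses center-to-center distance <= radius, so the focal cell
    is always included.
    """
    if radius < cell_size:
        raise ValueError("radius must be at least one cell")
    r_cells = int(radius // cell_size)
    di, dj = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    return (di**2 + dj**2) * cell_size**2 <= radius**2


def focal_density(indicator, radius: float, cell_size: float = 50.0) -> np.ndarray:
    """Proportion of cells within a metric radius that carry the indicator.

    The denominator counts only in-grid cells, so densities at the grid
    border are proportions of the truncated window, not of the full disk.
    Used for road density with a 500 m radius at 50 m resolution.
    """
    indicator = _check_binary(indicator, "indicator")
    kernel = circular_footprint(radius, cell_size).astype(float)
    num = ndimage.correlate(np.nan_to_num(indicator), kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(indicator, dtype=float), kernel, mode="constant", cval=0.0)
    return num / den


def development_density(
    urban,
    agriculture,
    radius: float = 500.0,
    cell_size: float = 50.0,
    ag_weight: float = 0.3,
) -> np.ndarray:
    """Weighted urban + agriculture density in a circular window.

    Per cell: ``(n_urban + ag_weight * n_agriculture) / n_total`` over the
    same center-in-radius window as :func:`focal_density`.  Agriculture
    counts at reduced weight (default 0.3) because it degrades habitat less
    than urban development.  A cell flagged both urban and agricultural is
    rejected.
    """
    urban = _check_binary(urban, "urban")
    agriculture = _check_binary(agriculture, "agriculture")
    if urban.shape != agriculture.shape:
        raise ValueError("urban and agriculture grids are not aligned")
    if ag_weight < 0:
        raise ValueError("ag_weight must be non-negative")
    overlap = (urban == 1) & (agriculture == 1)
    if overlap.any():
        raise ValueError(f"{overlap.sum()} cells are both urban and agriculture")
    kernel = circular_footprint(radius, cell_size).astype(float)
    weighted = np.nan_to_num(urban) + ag_weight * np.nan_to_num(agriculture)
    num = ndimage.correlate(weighted, kernel, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(urban, dtype=float), kernel, mode="constant", cval=0.0)
    return num / den


def patch_area(
    blocking,
    cell_size: float = 50.0,
    mask: np.ndarray | None = None,
    connectivity: int = 4,
) -> np.ndarray:
    """Area (hectares) of the contiguous open patch containing each cell.

    Open cells are non-blocking (not road, not urban) in-mask cells; they
    are grouped into connected components and every cell receives its
    component's total area.  Blocking and out-of-mask cells are NaN.

    4-connectivity is the default so that patches cannot leak diagonally
    across a one-cell-wide rasterized road.
    """
    blocking = _check_binary(blocking, "blocking")
    open_cells = blocking != 1
    if mask is not None:
        open_cells &= np.asarray(mask, dtype=bool)
    if not open_cells.any():
        raise ValueError("all cells are blocking; no patches to delineate")
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(open_cells, structure=structure)
    cell_ha = cell_size**2 / 10_000.0
    sizes = np.bincount(labels.ravel(), minlength=n + 1).astype(float) * cell_ha
    out = np.full(blocking.shape, np.nan)
    out[open_cells] = sizes[labels[open_cells]]
    return out


def stack_sdm_richness(suitability_layers, thresholds=None) -> np.ndarray:
    """Taxon richness index from per-species habitat-suitability surfaces.

    Continuous mode (``thresholds=None``) sums the [0, 1] suitabilities —
    an expected-richness index.  Thresholded mode converts each surface to
    binary predicted presence (suitability >= its threshold) before
    summing, as done for taxa whose models are calibrated with per-species
    presence thresholds.  NaN in any layer propagates to the sum.
    """
    layers = [np.asarray(g, dtype=float) for g in suitability_layers]
    if not layers:
        raise ValueError("need at least one suitability layer")
    shape = layers[0].shape
    for g in layers:
        if g.shape != shape:
            raise ValueError("suitability layers are not aligned")
        finite = g[~np.isnan(g)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("suitability values must lie in [0, 1]")
    if thresholds is None:
        return np.sum(layers, axis=0)
    thresholds = list(thresholds)
    if len(thresholds) != len(layers):
        raise ValueError(f"expected {len(layers)} thresholds, got {len(thresholds)}")
    out = np.zeros(shape, dtype=float)
    for g, t in zip(layers, thresholds):
        binary = (g >= t).astype(float)
        binary[np.isnan(g)] = np.nan
        out = out + binary
    return out


def derive_standard_attributes(
    stack,
    radius: float = 500.0,
    ag_weight: float = 0.3,
    plant_threshold: float = 0.5,
    connectivity: int = 4,
):
    """Compute the twelve standard attributes from a primitive-layer stack.

    Expects primitive layers named ``fire_*`` (binary perimeters), ``roads``,
    ``urban``, ``agriculture`` (binary), per-species suitabilities named
    ``sdm_plant_*``, ``sdm_herp_*``, ``sdm_bird_*``, ``sdm_mamm_*``, and the
    forwarded model outputs ``ign_prob``, ``frid``, ``divers``, ``diverg``.
    Adds attribute layers (``nfires``, ``road``, ``dev``, ``patch``,
    ``plant``, ``herp``, ``bird``, ``mamm`` plus the four forwarded ones) to
    the stack in place and returns it.

    Plant models are thresholded to binary presence before summation
    (one shared threshold by default); other taxa are summed continuously.
    """
    layers = stack.layers
    fire_names = sorted(n for n in layers if n.startswith("fire_"))
    if not fire_names:
        raise ValueError("no fire perimeter layers (fire_*) in stack")
    stack.add_layer("nfires", count_overlapping_fires([layers[n] for n in fire_names]))
    stack.add_layer("road", focal_density(layers["roads"], radius, stack.cell_size))
    stack.add_layer(
        "dev",
        development_density(
            layers["urban"], layers["agriculture"], radius, stack.cell_size, ag_weight
        ),
    )
    blocking = ((layers["roads"] == 1) | (layers["urban"] == 1)).astype(float)
    stack.add_layer(
        "patch", patch_area(blocking, stack.cell_size, stack.mask, connectivity)
    )
    for taxon in ("plant", "herp", "bird", "mamm"):
        names = sorted(n for n in layers if n.startswith(f"sdm_{taxon}_"))
        if not names:
            raise ValueError(f"no suitability layers (sdm_{taxon}_*) in stack")
        thresholds = [plant_threshold] * len(names) if taxon == "plant" else None
        stack.add_layer(taxon, stack_sdm_richness([layers[n] for n in names], thresholds))
    for name in ("ign_prob", "frid", "divers", "diverg"):
        if name not in layers:
            raise ValueError(f"forwarded layer {name!r} missing from stack")
    return stack
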