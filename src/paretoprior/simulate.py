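"""Synthetic criteria, synthetic landscapes, and rank-range experiments.

Two generators support testing and method exploration:

* :func:`simulate_criteria` draws alternatives from an equicorrelated
  multivariate Gaussian (one shared pairwise correlation ``rho``) and
  min-max rescales each column to [0, 1].  This is the simplest structure
  in which the influence of inter-criteria correlation on Pareto ranking
  can be dialed: as ``rho`` rises from -1 toward 1, vectors are
  increasingly likely to dominate one another, so the number of fronts
  (the maximum rank) grows; strongly negative correlation collapses almost
  everything onto the first front.

* :func:`synthetic_landscape` emulates a fire-prone, fragmented coastal
  landscape on a raster grid: binary fire perimeters, a road network,
  urban/agriculture development concentrated toward the west, per-species
  habitat-suitability surfaces, and externally modeled continuous layers
  (ignition probability, fire return interval departure, genetic
  diversity/divergence), plus west-to-east climate-zone bands and a
  conserved-land indicator.  It drives the full derive-rank-summarize
  pipeline end to end.

:func:`rank_range_experiment` measures the maximum assigned rank across
replicates over a (K, M, rho) grid.  All randomness flows from one seed;
replicate r uses seed + r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .criteria import value_fn_f
from .ranking import pareto_rank_array
from .stack import AttributeStack

__all__ = [
    "SimulationConfig",
    "simulate_criteria",
    "rank_range_experiment",
    "synthetic_stack",
    "synthetic_landscape",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One (K, M, rho) condition for the rank-range experiment."""

    n_units: int
    n_criteria: int
    rho: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError("n_units must be at least 2")
        if self.n_criteria < 1:
            raise ValueError("n_criteria must be at least 1")
        if self.n_criteria > 1:
            lo = -1.0 / (self.n_criteria - 1)
            if not (lo < self.rho <= 1.0):
                raise ValueError(
                    f"rho={self.rho} infeasible for M={self.n_criteria}; "
                    f"equicorrelation requires rho in ({lo:.4f}, 1]"
                )


def _equicorrelated_normal(rng, K: int, M: int, rho: float) -> np.ndarray:
    if M == 1:
        return rng.standard_normal((K, 1))
    if rho == 1.0:
        z = rng.standard_normal((K, 1))
        return np.repeat(z, M, axis=1)
    C = np.full((M, M), rho)
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C)
    return rng.standard_normal((K, M)) @ L.T


def simulate_criteria(cfg: SimulationConfig) -> np.ndarray:
    """K x M criteria matrix in [0, 1] with pairwise correlation ~ rho."""
    rng = np.random.default_rng(cfg.seed)
    Z = _equicorrelated_normal(rng, cfg.n_units, cfg.n_criteria, cfg.rho)
    return np.column_stack([value_fn_f(Z[:, j]) for j in range(Z.shape[1])])


def rank_range_experiment(
    n_units,
    n_criteria,
    rhos,
    n_replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Max Pareto rank per replicate over a factorial (K, M, rho) grid.

    Returns a tidy table with one row per (K, M, rho, replicate) holding
    ``max_rank``; summarize with :func:`summarize_rank_range`.
    """
    n_units = np.atleast_1d(n_units)
    n_criteria = np.atleast_1d(n_criteria)
    rhos = np.atleast_1d(rhos)
    rows = []
    for K in n_units:
        for M in n_criteria:
            for rho in rhos:
                if M > 1 and not (-1.0 / (M - 1) < rho <= 1.0):
                    continue
                for r in range(n_replicates):
                    cfg = SimulationConfig(int(K), int(M), float(rho), seed=seed + r)
                    ranks = pareto_rank_array(simulate_criteria(cfg))
                    rows.append(
                        {
                            "K": int(K),
                            "M": int(M),
                            "rho": float(rho),
                            "replicate": r,
                            "max_rank": int(ranks.max()),
                        }
                    )
    return pd.DataFrame(rows)


def summarize_rank_range(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of max_rank per (K, M, rho) condition."""
    return (
        results.groupby(["K", "M", "rho"])["max_rank"]
        .agg(mean_max_rank="mean", sd_max_rank="std")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# synthetic rasters

def _smooth_field(rng, shape, sigma=4.0):
    """Standardized Gaussian random field (smoothed white noise)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / f.std()


def synthetic_stack(
    rows: int,
    cols: int,
    n_layers: int,
    rho: float = 0.0,
    missing_fraction: float = 0.0,
    n_zones: int = 4,
    seed: int = 0,
    mask_hole_fraction: float = 0.02,
    smooth_sigma: float = 3.0,
) -> AttributeStack:
    """Aligned correlated continuous layers with mask holes, zone bands,
    and a conserved indicator.

    Layers are per-cell equicorrelated Gaussian draws smoothed into random
    fields (identical smoothing preserves the inter-layer correlation).
    ``missing_fraction`` of in-mask cells get one layer's value knocked out
    (NaN).  Zones are contiguous west-to-east column bands; conserved
    status is a thresholded random field (blobs).  Deterministic per seed.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    K = rows * cols
    Z = _equicorrelated_normal(rng, K, n_layers, rho)
    layers = {}
    for j in range(n_layers):
        g = ndimage.gaussian_filter(Z[:, j].reshape(rows, cols), smooth_sigma)
        layers[f"layer_{j:02d}"] = (g - g.mean()) / g.std()

    mask = np.ones((rows, cols), dtype=bool)
    n_holes = int(round(mask_hole_fraction * K))
    if n_holes:
        holes = rng.choice(K, size=n_holes, replace=False)
        mask.ravel()[holes] = False

    if missing_fraction:
        in_mask_idx = np.flatnonzero(mask.ravel())
        n_miss = int(round(missing_fraction * in_mask_idx.size))
        cells = rng.choice(in_mask_idx, size=n_miss, replace=False)
        which = rng.integers(0, n_layers, size=n_miss)
        names = list(layers)
        for c, j in zip(cells, which):
            layers[names[j]].ravel()[c] = np.nan

    zone_edges = np.linspace(0, cols, n_zones + 1).astype(int)
    zones = np.zeros((rows, cols), dtype=int)
    for z in range(n_zones):
        zones[:, zone_edges[z] : zone_edges[z + 1]] = z + 1
    conserved = _smooth_field(rng, (rows, cols), sigma=6.0) > 0
    return AttributeStack(layers, mask, 50.0, zones, conserved, (0.0, 0.0))


def synthetic_landscape(
    rows: int = 100,
    cols: int = 100,
    n_fires: int = 6,
    n_species: dict | None = None,
    missing_fraction: float = 0.1,
    n_zones: int = 4,
    seed: int = 0,
) -> AttributeStack:
    """Primitive-layer stack emulating a fire-prone fragmented landscape.

    Generates binary fire perimeters (random burn blobs, more frequent in
    the interior), a rectilinear road network densest in the west, urban
    and (disjoint) agriculture footprints declining eastward, per-species
    suitability surfaces in [0, 1], and the four externally modeled
    continuous layers.  ``missing_fraction`` of in-mask cells get a NaN in
    one of the forwarded continuous layers, emulating gaps in external
    model coverage.  Feed to
    :func:`paretoprior.attributes.derive_standard_attributes`.
    """
    if n_species is None:
        n_species = {"plant": 6, "herp": 4, "bird": 3, "mamm": 4}
    rng = np.random.default_rng(seed)
    shape = (rows, cols)
    west_east = np.linspace(1.0, -1.0, cols)[None, :] * np.ones((rows, 1))

    layers: dict[str, np.ndarray] = {}
    # fire perimeters: smooth blobs biased toward the interior
    interior = -np.abs(np.linspace(-1, 1, cols))[None, :] * np.ones((rows, 1))
    for i in range(n_fires):
        f = _smooth_field(rng, shape, sigma=5.0) + 0.8 * interior
        layers[f"fire_{i:02d}"] = (f > np.quantile(f, 0.8)).astype(float)

    # rectilinear road network, denser in the west
    roads = np.zeros(shape)
    spacing = max(4, rows // 12)
    for r in range(spacing // 2, rows, spacing):
        roads[r, :] = 1.0
    col_positions = np.unique(rng.integers(0, cols, size=max(3, cols // 8)))
    for c in col_positions:
        keep_p = 1.0 - 0.6 * (c / cols)  # western roads more complete
        seg = rng.random(rows) < keep_p
        roads[seg, c] = 1.0
    layers["roads"] = roads

    urban_field = _smooth_field(rng, shape, sigma=6.0) + 1.2 * west_east
    urban = urban_field > np.quantile(urban_field, 0.85)
    ag_field = _smooth_field(rng, shape, sigma=6.0) + 0.6 * west_east
    agriculture = (ag_field > np.quantile(ag_field, 0.88)) & ~urban
    layers["urban"] = urban.astype(float)
    layers["agriculture"] = agriculture.astype(float)

    def _suitability():
        return 1.0 / (1.0 + np.exp(-_smooth_field(rng, shape, sigma=5.0)))

    for taxon, n in n_species.items():
        for s in range(n):
            layers[f"sdm_{taxon}_{s:02d}"] = _suitability()

    layers["ign_prob"] = _suitability()
    layers["frid"] = 20.0 * _smooth_field(rng, shape, sigma=5.0)  # years, +/- departure
    layers["divers"] = _suitability()
    layers["diverg"] = _suitability()

    mask = ~urban  # urban excluded from the analysis area
    # small random survey gaps
    holes = rng.random(shape) < 0.01
    mask &= ~holes

    if missing_fraction:
        in_mask_idx = np.flatnonzero(mask.ravel())
        n_miss = int(round(missing_fraction * in_mask_idx.size))
        cells = rng.choice(in_mask_idx, size=n_miss, replace=False)
        forwarded = ["ign_prob", "frid", "divers", "diverg"]
        which = rng.integers(0, len(forwarded), size=n_miss)
        for c, j in zip(cells, which):
            layers[forwarded[j]].ravel()[c] = np.nan

    zone_edges = np.linspace(0, cols, n_zones + 1).astype(int)
    zones = np.zeros(shape, dtype=int)
    for z in range(n_zones):
        zones[:, zone_edges[z] : zone_edges[z + 1]] = z + 1
    conserved = _smooth_field(rng, shape, sigma=8.0) > 0
    return AttributeStack(layers, mask, 50.0, zones, conserved, (0.0, 0.0))
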