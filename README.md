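# paretoprior

Multi-criteria Pareto ranking for prioritizing raster grid cells for
conservation monitoring and management.

## The problem

Conservation planners must decide where to spend limited monitoring and
management effort across a landscape in which threats (wildfire, habitat
fragmentation) and assets (species richness, genetic diversity) overlap in
complicated spatial patterns. Treating every grid cell as an alternative
described by a vector of criteria turns this into a multi-criteria decision
analysis — but the usual single-synthesizing-criterion methods (additive
multi-attribute value scores, AHP) require stakeholders to agree on
subjective criteria weights before anything can be ranked.

`paretoprior` ranks cells **without weights**, using Pareto dominance. With
all criteria expressed so that *lower = higher priority*, a criteria vector
**x**ₖ *weakly dominates* **x**ₗ when

```
x_{k,m} ≤ x_{l,m}  for all m,   and   x_{k,m} < x_{l,m}  for at least one m.
```

The non-dominated set (the Pareto front) of all cells receives rank 1; the
front of the remaining cells rank 2; and so on until every cell is ranked
(`r(x_k)`). Dominance implies strict rank order, identical vectors share a
rank, and — because only within-criterion comparisons are made — the ranks
are invariant to any strictly increasing per-criterion transform, including
positive weights: weighting has no effect, which is the method's point.

Attributes enter as minimization criteria through one of two linear min-max
value functions applied per column **a**ₘ:

```
f(a) = (a − min a) / (max a − min a)      lower attribute  = higher priority
g(a) = (max a − a) / (max a − min a)      higher attribute = higher priority
```

The package ships the standard twelve-attribute registry — fire counts,
ignition probability, fire return interval departure (FRID); road density,
development density, road-free patch area; plant/herpetofauna/bird/mammal
richness from stacked species distribution models; genetic diversity and
divergence — grouped into fire (F′), fragmentation (H′), species (S′) and
genetic (G′) criteria blocks, the six standard decision matrices
([F′|S′], [H′|S′], [F′|G′], [H′|G′], [F′|S′|G′], [H′|S′|G′]), and the three
composite rank-of-ranks pairings such as r[r(F′|S′) | r(H′|S′)] that widen
the rank range when many criteria compress the fronts.

## Worked example

```python
import numpy as np
from paretoprior import MinMaxCriteria, ParetoRanker

# five cells x three attributes: fire count, ignition probability, FRID
attrs = np.array([
    [3, 0.62, -12.0],
    [1, 0.10,   4.0],
    [4, 0.55,  -8.0],
    [0, 0.05,  10.0],
    [3, 0.60, -12.0],
])
crit = MinMaxCriteria(
    ["higher_is_priority", "higher_is_priority", "lower_is_priority"]
).fit_transform(attrs)
print(np.round(crit, 3))
print(ParetoRanker().fit_predict(crit))
```

```
[[0.25  0.    0.   ]
 [0.75  0.912 0.727]
 [0.    0.123 0.182]
 [1.    1.    1.   ]
 [0.25  0.035 0.   ]]
[1 3 1 4 2]
```

Cells 1 and 3 trade off (most fires vs. highest ignition probability and
most negative FRID) and share the first front; cell 4 is dominated by
everything and ranks last. Transforming attributes to criteria changed no
comparison — ranking the raw attributes with per-column direction flips
gives the same result.

On a full raster stack (here a synthetic fire-prone landscape):

```python
from paretoprior import (derive_standard_attributes, rank_preset,
                         synthetic_landscape, zonal_summary)

stack = derive_standard_attributes(synthetic_landscape(rows=100, cols=100, seed=11))
dm, ranks, rg = rank_preset(stack, "FS")          # fire + species criteria
print("ranked cells:", int(ranks.ranked_mask.sum()), "max rank:", ranks.max_rank)
summary = zonal_summary(rg, stack.zones, stack.conserved, q=0.25)
print(summary.head(4).to_string(index=False))
```

```
ranked cells: 7982 max rank: 15
 zone  conserved  n_cells  n_at_or_below   percent
    1      False      655            143 21.832061
    1       True     1227            339 27.628362
    2      False      948            258 27.215190
    2       True      681             80 11.747430
```

The summary gives, per climate zone and conservation status, the percent of
cells ranked at or below the 25th-percentile rank across all ranked cells —
the cells flagged for increased monitoring and management. With seven
criteria only 15 fronts are needed for ~8,000 cells: more criteria (or
negatively correlated ones) compress the rank range, which is why the
composite rank-of-ranks presets exist.

## Command line

```bash
paretoprior derive    --config run.yaml          # Table-style attribute layers
paretoprior rank      --config run.yaml --preset FS
paretoprior composite --config run.yaml --composite FS+HS
paretoprior summarize --config run.yaml --rank-raster out/ranks_FS.asc
paretoprior simulate  -k 1000 -m 2 -r -0.9 -r 0 -r 0.9 --replicates 20
```

Rasters are ESRI ASCII grids (`.asc`) or single-band TIFF (`.tif` with a
`.tfw` world file); ranks are written as integer rasters with nodata 0 plus
a two-column `id,rank` table.

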