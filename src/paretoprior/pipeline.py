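"""High-level pipeline: stack -> decision matrix -> ranks -> rank grid."""

from __future__ import annotations

import numpy as np

from .criteria import DecisionMatrix, build_decision_matrix, pareto_rank, composite_pareto_rank
from .presets import MATRIX_PRESETS, COMPOSITE_PRESETS, specs_for
from .ranking import RankAssignment
from .spatial_io import RankGrid, ranks_to_grid
from .stack import AttributeStack

__all__ = ["rank_preset", "rank_composite_preset"]


def rank_preset(
    stack: AttributeStack, preset: str, overrides: dict | None = None
) -> tuple[DecisionMatrix, RankAssignment, RankGrid]:
    """Build the named preset decision matrix from a stack and rank it."""
    if preset not in MATRIX_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(MATRIX_PRESETS)}")
    specs = specs_for(MATRIX_PRESETS[preset], overrides)
    dm = build_decision_matrix(stack, specs)
    ranks = pareto_rank(dm)
    return dm, ranks, ranks_to_grid(dm, ranks, stack)


def rank_composite_preset(
    stack: AttributeStack,
    composite: str,
    component_ranks: dict[str, RankAssignment] | None = None,
    overrides: dict | None = None,
) -> tuple[RankAssignment, RankGrid]:
    """Composite rank-of-ranks for a named pairing of matrix presets.

    Reuses ``component_ranks`` when the component rankings were already
    computed; otherwise computes them from the stack.
    """
    if composite not in COMPOSITE_PRESETS:
        raise KeyError(f"unknown composite {composite!r}; have {sorted(COMPOSITE_PRESETS)}")
    parts = []
    ids = None
    for name in COMPOSITE_PRESETS[composite]:
        if component_ranks and name in component_ranks:
            ra = component_ranks[name]
        else:
            _, ra, _ = rank_preset(stack, name, overrides)
        parts.append(ra)
        ids = ra.ids if ids is None else ids
    comp = composite_pareto_rank(parts)
    # scatter onto the grid via a throwaway matrix of the component ranks
    dm = DecisionMatrix(
        comp.ids,
        list(COMPOSITE_PRESETS[composite]),
        np.column_stack([p.rank.astype(float) for p in parts]),
        valid=comp.ranked_mask,
    )
    return comp, ranks_to_grid(dm, comp, stack)
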