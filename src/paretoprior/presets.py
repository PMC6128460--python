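"""Default criteria registry and named decision-matrix presets.

The twelve standard attributes are three fire-threat layers (fire count,
ignition probability, fire return interval departure), three fragmentation
layers (road density, development density, road-free patch area), four
taxon richness indices from stacked species distribution models, and two
genetic layers (mean diversity, mean divergence).

Preference directions: more fires, higher ignition probability, denser
roads/development, richer or more genetically diverse cells are HIGHER
priority (order-reversing map g); more negative fire-interval departure and
smaller patches are higher priority, so those two use the order-preserving
map f.  Users can override any direction in a config file.
"""

from __future__ import annotations

from .criteria import ValueFunctionSpec

__all__ = ["DEFAULT_DIRECTIONS", "ATTRIBUTE_GROUPS", "MATRIX_PRESETS", "COMPOSITE_PRESETS", "specs_for"]

DEFAULT_DIRECTIONS: dict[str, str] = {
    "nfires": "higher_is_priority",
    "ign_prob": "higher_is_priority",
    "frid": "lower_is_priority",
    "road": "higher_is_priority",
    "dev": "higher_is_priority",
    "patch": "lower_is_priority",
    "plant": "higher_is_priority",
    "herp": "higher_is_priority",
    "bird": "higher_is_priority",
    "mamm": "higher_is_priority",
    "divers": "higher_is_priority",
    "diverg": "higher_is_priority",
}

ATTRIBUTE_GROUPS: dict[str, list[str]] = {
    "F": ["nfires", "ign_prob", "frid"],
    "H": ["road", "dev", "patch"],
    "S": ["plant", "herp", "bird", "mamm"],
    "G": ["divers", "diverg"],
}

# the six standard decision matrices: threat block (fire or fragmentation)
# concatenated with one or both biodiversity blocks
MATRIX_PRESETS: dict[str, list[str]] = {
    "FS": ATTRIBUTE_GROUPS["F"] + ATTRIBUTE_GROUPS["S"],
    "HS": ATTRIBUTE_GROUPS["H"] + ATTRIBUTE_GROUPS["S"],
    "FG": ATTRIBUTE_GROUPS["F"] + ATTRIBUTE_GROUPS["G"],
    "HG": ATTRIBUTE_GROUPS["H"] + ATTRIBUTE_GROUPS["G"],
    "FSG": ATTRIBUTE_GROUPS["F"] + ATTRIBUTE_GROUPS["S"] + ATTRIBUTE_GROUPS["G"],
    "HSG": ATTRIBUTE_GROUPS["H"] + ATTRIBUTE_GROUPS["S"] + ATTRIBUTE_GROUPS["G"],
}

# composite rank-of-ranks pairings: fire-based vs fragmentation-based
# rankings over the same biodiversity block
COMPOSITE_PRESETS: dict[str, tuple[str, str]] = {
    "FS+HS": ("FS", "HS"),
    "FG+HG": ("FG", "HG"),
    "FSG+HSG": ("FSG", "HSG"),
}


def specs_for(names: list[str], overrides: dict[str, str] | None = None) -> list[ValueFunctionSpec]:
    """Build value-function specs for attribute names using the registry.

    Unknown attributes must appear in ``overrides`` with an explicit
    direction.
    """
    directions = dict(DEFAULT_DIRECTIONS)
    if overrides:
        directions.update(overrides)
    specs = []
    for name in names:
        if name not in directions:
            raise KeyError(
                f"no preference direction registered for attribute {name!r}; "
                "provide one in the criteria config"
            )
        specs.append(ValueFunctionSpec(name, directions[name]))
    return specs
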