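"""Built-in beverage presets, shipped as YAML config files.

The four canonical dietary fluids (salty soup, sucrose soft drink, HFCS soft
drink, WHO oral rehydration solution) plus pure water and a lactulose
solution.  Presets carry their quoted overall osmolarity as a declared value
and a composition whose ideal arithmetic matches it.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .solutes import Beverage, beverage_from_dict

__all__ = ["PRESET_NAMES", "preset_beverage", "preset_path", "table_presets"]

PRESET_NAMES = (
    "salty_soup",
    "sucrose_softdrink",
    "hfcs_softdrink",
    "who_ors",
    "water",
    "lactulose_solution",
)

#: The four beverages of the canonical trapping comparison, in display order.
TABLE_PRESETS = PRESET_NAMES[:4]


def preset_beverage(name: str) -> Beverage:
    """Load a built-in preset by name (see :data:`PRESET_NAMES`)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    ref = resources.files("osmotrap").joinpath("presets", f"{name}.yaml")
    with ref.open() as fh:
        return beverage_from_dict(yaml.safe_load(fh))


def preset_path(name: str):
    """Filesystem path of a preset's YAML definition (for copying/templating)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    return resources.files("osmotrap").joinpath("presets", f"{name}.yaml")


def table_presets() -> list[Beverage]:
    """The four canonical beverages, in display order."""
    return [preset_beverage(name) for name in TABLE_PRESETS]
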