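"""Solutes, beverages, and ideal-solution osmolarity arithmetic.

Osmolarity here is the ideal-solution value: every dissolved formula unit
contributes ``particles_per_formula`` osmotically active particles, with no
osmotic (activity) coefficients.  That is the arithmetic used for dietary
fluids throughout this package: a solute at concentration ``c`` g/L with molar
mass ``M`` g/mol contributes ``c / M * particles * 1000`` mosm/L.

Ethanol is the one species whose effective osmolarity is not reproduced by
this arithmetic (literature values for weak ethanol solutions are far above
the ideal number); ethanol-containing beverages are therefore representable
only through a declared (measured) osmolarity override.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "ABSORPTION_CLASSES",
    "Solute",
    "Beverage",
    "REGISTRY",
    "get_solute",
    "component_osmolarity",
    "beverage_osmolarity",
    "hfcs_composition",
    "dilute",
    "beverage_from_dict",
    "load_beverage",
    "osmolarity_report",
]

#: Closed set of absorption behaviours a solute can have in the small bowel.
ABSORPTION_CLASSES = frozenset(
    {
        "sodium_coupled_fast",   # glucose/galactose via SGLT1, water follows < 2 h
        "facilitated_slow",      # fructose via GLUT5, up to 4 h (longer if impaired)
        "disaccharide_sucrose",  # hydrolysed to equimolar glucose + fructose
        "electrolyte",           # NaCl etc., absorbed with the fast pool
        "nonabsorbed_osmotic",   # lactulose: persists, passed on to the colon
        "ethanol_declared",      # representable only via declared osmolarity
    }
)


@dataclass(frozen=True)
class Solute:
    """An osmotically active species.

    Parameters
    ----------
    name : str
        Identifier used in beverage definitions (case-insensitive lookup).
    molar_mass : float
        g/mol, must be positive.
    particles_per_formula : float
        Ideal dissociation count (2 for NaCl, 1 for sugars).
    absorption_class : str
        One of :data:`ABSORPTION_CLASSES`.
    """

    name: str
    molar_mass: float
    particles_per_formula: float
    absorption_class: str

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")
        if self.particles_per_formula < 1:
            raise ValueError(
                f"particles_per_formula must be >= 1, got {self.particles_per_formula}"
            )
        if self.absorption_class not in ABSORPTION_CLASSES:
            raise ValueError(
                f"unknown absorption_class {self.absorption_class!r}; "
                f"expected one of {sorted(ABSORPTION_CLASSES)}"
            )


# Built-in registry. Molar masses: monosaccharides 180.16, sucrose/lactulose
# 342.3, NaCl 58.44 (dissociating into two particles).
_BUILTINS = [
    Solute("glucose", 180.16, 1, "sodium_coupled_fast"),
    Solute("galactose", 180.16, 1, "sodium_coupled_fast"),
    Solute("fructose", 180.16, 1, "facilitated_slow"),
    Solute("sucrose", 342.3, 1, "disaccharide_sucrose"),
    Solute("nacl", 58.44, 2, "electrolyte"),
    Solute("lactulose", 342.3, 1, "nonabsorbed_osmotic"),
]

REGISTRY: dict[str, Solute] = {s.name: s for s in _BUILTINS}
REGISTRY["salt"] = REGISTRY["nacl"]


def get_solute(name: str) -> Solute:
    """Look up a built-in solute by name (case-insensitive)."""
    try:
        return REGISTRY[name.strip().lower()]
    except KeyError:
        raise KeyError(
            f"unknown solute {name!r}; known: {sorted(REGISTRY)}"
        ) from None


def component_osmolarity(solute: Solute, concentration: float) -> float:
    """Ideal osmolarity (mosm/L) contributed by one solute at ``concentration`` g/L."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return concentration / solute.molar_mass * solute.particles_per_formula * 1000.0


@dataclass(frozen=True)
class Beverage:
    """A labelled volume of fluid with a solute composition.

    ``declared_osmolarity`` (mosm/L), when given, takes precedence over the
    value computed from the composition — used for measured values (ethanol
    drinks) and for presets quoted with a round overall osmolarity.
    """

    label: str
    volume: float  # L
    components: tuple[tuple[Solute, float], ...] = ()  # (solute, g/L)
    declared_osmolarity: float | None = None

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        object.__setattr__(self, "components", tuple(self.components))
        for solute, conc in self.components:
            if conc < 0:
                raise ValueError(
                    f"{self.label}: concentration of {solute.name} must be >= 0"
                )
        if self.declared_osmolarity is not None and self.declared_osmolarity < 0:
            raise ValueError("declared_osmolarity must be >= 0")

    @property
    def osmolarity(self) -> float:
        return beverage_osmolarity(self)

    def component_osmolarities(self) -> list[tuple[Solute, float]]:
        """Per-component ideal osmolarities (mosm/L), independent of any declared total."""
        return [(s, component_osmolarity(s, c)) for s, c in self.components]


def beverage_osmolarity(beverage: Beverage) -> float:
    """Overall osmolarity (mosm/L): declared value if present, else the component sum."""
    if beverage.declared_osmolarity is not None:
        return beverage.declared_osmolarity
    return sum(component_osmolarity(s, c) for s, c in beverage.components)


def hfcs_composition(
    total_sugar: float, fructose_mass_fraction: float = 0.55
) -> list[tuple[Solute, float]]:
    """Split a total HFCS sugar load (g/L) into fructose and glucose components.

    Soft-drink HFCS is typically 55% fructose / 45% glucose by mass; because the
    two monosaccharides share a molar mass, osmolar shares equal mass shares.
    """
    if total_sugar < 0:
        raise ValueError(f"total_sugar must be >= 0, got {total_sugar}")
    if not 0.0 <= fructose_mass_fraction <= 1.0:
        raise ValueError(
            f"fructose_mass_fraction must be in [0, 1], got {fructose_mass_fraction}"
        )
    return [
        (REGISTRY["fructose"], total_sugar * fructose_mass_fraction),
        (REGISTRY["glucose"], total_sugar * (1.0 - fructose_mass_fraction)),
    ]


def dilute(beverage: Beverage, factor: float, label: str | None = None) -> Beverage:
    """Dilute a beverage ``factor``-fold with water (volume × factor, concentrations / factor)."""
    if factor < 1:
        raise ValueError(f"dilution factor must be >= 1, got {factor}")
    declared = (
        None
        if beverage.declared_osmolarity is None
        else beverage.declared_osmolarity / factor
    )
    return Beverage(
        label=label or f"{beverage.label} (1:{factor:g} diluted)",
        volume=beverage.volume * factor,
        components=tuple((s, c / factor) for s, c in beverage.components),
        declared_osmolarity=declared,
    )


# ---------------------------------------------------------------------------
# Config I/O (YAML key-value files) and tabular reports


def beverage_from_dict(data: dict) -> Beverage:
    """Build a Beverage from a parsed config mapping.

    Schema::

        label: HFCS soft drink
        volume_l: 0.5
        declared_osmolarity_mosm_l: 800   # optional
        components:
          - {solute: glucose, concentration_g_per_l: 64.86}
          - {solute: fructose, concentration_g_per_l: 79.27}
    """
    try:
        label = str(data["label"])
        volume = float(data["volume_l"])
    except KeyError as exc:
        raise ValueError(f"beverage config missing required key: {exc}") from None
    comps = []
    for entry in data.get("components") or []:
        comps.append(
            (get_solute(str(entry["solute"])), float(entry["concentration_g_per_l"]))
        )
    declared = data.get("declared_osmolarity_mosm_l")
    return Beverage(
        label=label,
        volume=volume,
        components=tuple(comps),
        declared_osmolarity=None if declared is None else float(declared),
    )


def beverage_to_dict(beverage: Beverage) -> dict:
    data: dict = {
        "label": beverage.label,
        "volume_l": beverage.volume,
        "components": [
            {"solute": s.name, "concentration_g_per_l": c}
            for s, c in beverage.components
        ],
    }
    if beverage.declared_osmolarity is not None:
        data["declared_osmolarity_mosm_l"] = beverage.declared_osmolarity
    return data


def load_beverage(path: str | Path) -> Beverage:
    """Read a beverage definition from a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return beverage_from_dict(data)


def save_beverage(beverage: Beverage, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(beverage_to_dict(beverage), fh, sort_keys=False)


def osmolarity_report(beverages: Iterable[Beverage]) -> pd.DataFrame:
    """Tabulate overall osmolarity and per-component breakdown for a set of beverages."""
    rows = []
    for bev in beverages:
        breakdown = "; ".join(
            f"{s.name} {osm:.0f}" for s, osm in bev.component_osmolarities()
        )
        rows.append(
            {
                "label": bev.label,
                "volume_L": bev.volume,
                "osmolarity_mosm_per_L": round(beverage_osmolarity(bev)),
                "components_mosm_per_L": breakdown,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "volume_L", "osmolarity_mosm_per_L", "components_mosm_per_L"],
    )
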