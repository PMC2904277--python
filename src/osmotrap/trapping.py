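"""Static model of osmotic fluid trapping in the small bowel.

A hyperosmolar drink of volume ``V`` (L) at osmolarity ``O`` (mosm/L) is
diluted to isotonicity (reference ``O_iso`` = 300 mosm/L) by water drawn from
the circulation.  The initially trapped volume is

    V_d = max(0, V * O / O_iso - V)

and the total isotonic volume presented for absorption is ``V_a = V + V_d``.
Dilution is treated as instantaneous at ingestion, so the circulatory deficit
steps to ``-V_d`` at t = 0 and recovers as the luminal water is reabsorbed.

Absorption is partitioned by osmolar share of the solutes:

* sodium-coupled sugars (glucose, galactose via SGLT1) and electrolytes carry
  their water share back into the circulation at a constant rate over the
  first two hours;
* fructose (GLUT5, facilitated diffusion along the entire small bowel) holds
  its water share in the lumen while it transits; that share returns at a
  constant rate between two hours and the fructose completion time (default
  4 h, longer for impaired absorbers).  The delayed onset reflects that the
  fructose-associated water remains sequestered until fructose itself is
  absorbed distally — and makes the fraction absorbed at 2 h equal exactly
  the fast osmolar share (45% for the 360/440 HFCS drink);
* sucrose hydrolyses to equimolar glucose + fructose, so its share splits
  50/50 between the fast and slow pools;
* non-absorbed solutes (lactulose) never return their water to the body: the
  residual volume is passed on to the colon at the slow completion time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .solutes import Beverage

__all__ = [
    "ISOTONIC_REFERENCE",
    "FAST_COMPLETION_H",
    "SLOW_COMPLETION_H",
    "ClassPartition",
    "TrappingResult",
    "AbsorptionState",
    "trapped_volume",
    "total_absorbable_volume",
    "partition_by_osmotic_share",
    "analyze_beverage",
    "absorption_timecourse",
    "circulatory_balance",
    "truncate2",
]

ISOTONIC_REFERENCE = 300.0  # mosm/L, plasma-isotonic reference used throughout
FAST_COMPLETION_H = 2.0     # sodium-coupled sugars and electrolytes
SLOW_COMPLETION_H = 4.0     # fructose in normal absorbers

_FAST_CLASSES = ("sodium_coupled_fast", "electrolyte")


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals — the display convention for volumes."""
    return math.trunc(x * 100.0) / 100.0


def trapped_volume(V: float, O: float, O_iso: float = ISOTONIC_REFERENCE) -> float:
    """Initially trapped volume V_d = max(0, V*O/O_iso - V), in litres.

    Hypotonic and isotonic inputs clamp to zero: they need no dilution water.
    """
    if not V > 0:
        raise ValueError(f"ingested volume must be > 0, got {V}")
    if O < 0:
        raise ValueError(f"osmolarity must be >= 0, got {O}")
    if not O_iso > 0:
        raise ValueError(f"isotonic reference must be > 0, got {O_iso}")
    return max(0.0, V * O / O_iso - V)


def total_absorbable_volume(V: float, V_d: float) -> float:
    """Total isotonic volume for absorption, V_a = V + V_d (litres)."""
    if not V > 0:
        raise ValueError(f"ingested volume must be > 0, got {V}")
    if V_d < 0:
        raise ValueError(f"trapped volume must be >= 0, got {V_d}")
    return V + V_d


class ClassPartition(NamedTuple):
    """One absorption pool: class name, water volume (L), completion time (h).

    ``completion_time`` is ``inf`` for the non-absorbed pool; ``onset`` is the
    time its constant-rate absorption starts (0 for fast pools, the fast
    completion time for the slow fructose pool).
    """

    absorption_class: str
    volume: float
    completion_time: float
    onset: float = 0.0

    def absorbed_at(self, t: float) -> float:
        """Volume of this pool returned to the circulation by time t (h)."""
        if not math.isfinite(self.completion_time):
            return 0.0
        if t <= self.onset:
            return 0.0
        if t >= self.completion_time:
            return self.volume
        return self.volume * (t - self.onset) / (self.completion_time - self.onset)


def _partitions_for(
    beverage: Beverage, V_a: float, slow_completion_h: float
) -> list[ClassPartition]:
    comps = beverage.component_osmolarities()
    total = sum(osm for _, osm in comps)
    if total <= 0:
        raise ValueError(
            f"{beverage.label}: zero-osmolarity beverage has no absorption partition"
        )
    slow_onset = min(FAST_COMPLETION_H, slow_completion_h)
    fast = slow = nonabs = 0.0
    for solute, osm in comps:
        share = V_a * osm / total
        cls = solute.absorption_class
        if cls in _FAST_CLASSES:
            fast += share
        elif cls == "facilitated_slow":
            slow += share
        elif cls == "disaccharide_sucrose":
            # instantaneous hydrolysis into equimolar glucose + fructose
            fast += share / 2.0
            slow += share / 2.0
        elif cls == "nonabsorbed_osmotic":
            nonabs += share
        else:  # ethanol_declared — not absorbable in this static model
            raise ValueError(
                f"{beverage.label}: cannot partition absorption for class {cls!r}"
            )
    parts = []
    if fast > 0:
        parts.append(ClassPartition("sodium_coupled_fast", fast, FAST_COMPLETION_H))
    if slow > 0:
        parts.append(
            ClassPartition("facilitated_slow", slow, slow_completion_h, slow_onset)
        )
    if nonabs > 0:
        parts.append(
            ClassPartition("nonabsorbed_osmotic", nonabs, math.inf, slow_completion_h)
        )
    return parts


def partition_by_osmotic_share(
    beverage: Beverage, V_a: float, slow_completion_h: float = SLOW_COMPLETION_H
) -> list[tuple[str, float]]:
    """Partition V_a across absorption classes by osmolar share.

    Returns (class, volume) pairs; sucrose's share is split 50/50 into the
    fast and slow pools, electrolytes join the fast pool, and non-absorbed
    solutes get a separate pool flagged with infinite completion time.
    """
    return [
        (p.absorption_class, p.volume)
        for p in _partitions_for(beverage, V_a, slow_completion_h)
    ]


@dataclass(frozen=True)
class TrappingResult:
    """Output of the static trapping model for one ingestion."""

    label: str
    V: float            # ingested volume, L
    O: float            # beverage osmolarity, mosm/L
    V_d: float          # initially trapped volume, L
    V_a: float          # total volume for absorption, L
    partitions: tuple[ClassPartition, ...]
    sodium_mmol: float = 0.0  # sodium carried by the beverage itself

    @property
    def fraction_fast(self) -> float:
        """Share of V_a absorbed with the fast (sodium-coupled) pool."""
        fast = sum(p.volume for p in self.partitions if p.onset == 0.0
                   and math.isfinite(p.completion_time))
        return fast / self.V_a

    @property
    def completion_h(self) -> float:
        """Time at which the small bowel is cleared (absorption or colonic handoff)."""
        times = [
            p.completion_time if math.isfinite(p.completion_time) else p.onset
            for p in self.partitions
        ]
        return max(times, default=0.0)

    def volume_of(self, absorption_class: str) -> float:
        return sum(
            p.volume for p in self.partitions if p.absorption_class == absorption_class
        )


def analyze_beverage(
    beverage: Beverage,
    O_iso: float = ISOTONIC_REFERENCE,
    slow_completion_h: float = SLOW_COMPLETION_H,
) -> TrappingResult:
    """Run the full static trapping model for one beverage at its own volume."""
    O = beverage.osmolarity
    V = beverage.volume
    V_d = trapped_volume(V, O, O_iso)
    V_a = total_absorbable_volume(V, V_d)
    try:
        parts = _partitions_for(beverage, V_a, slow_completion_h)
    except ValueError:
        if O > 0:
            raise
        # Pure water: nothing to partition, the whole volume joins the fast pool.
        parts = [ClassPartition("sodium_coupled_fast", V_a, FAST_COMPLETION_H)]
    sodium = sum(
        conc * beverage.volume / s.molar_mass * 1000.0
        for s, conc in beverage.components
        if s.absorption_class == "electrolyte"
    )
    return TrappingResult(
        label=beverage.label,
        V=V,
        O=O,
        V_d=V_d,
        V_a=V_a,
        partitions=tuple(parts),
        sodium_mmol=sodium,
    )


class AbsorptionState(NamedTuple):
    """Water bookkeeping at one time point: absorbed into the body, still in
    the small-bowel lumen, and handed on to the colon (non-absorbed solutes)."""

    absorbed: float
    luminal: float
    to_colon: float = 0.0


def absorption_timecourse(result: TrappingResult, t: float) -> AbsorptionState:
    """Absorbed and luminal volumes (L) at time ``t`` hours after ingestion.

    Each pool absorbs at a constant rate over its [onset, completion] window;
    ``absorbed + luminal + to_colon == V_a`` at every t, and the small bowel
    is clear of a fully absorbable drink at the slow completion time.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    absorbed = 0.0
    to_colon = 0.0
    for p in result.partitions:
        if math.isfinite(p.completion_time):
            absorbed += p.absorbed_at(t)
        elif t >= p.onset:  # non-absorbed pool leaves for the colon at its onset
            to_colon += p.volume
    luminal = result.V_a - absorbed - to_colon
    return AbsorptionState(absorbed=absorbed, luminal=luminal, to_colon=to_colon)


def circulatory_balance(result: TrappingResult, t: float) -> float:
    """Net water moved into the body since the start of ingestion (L).

    Equals ``absorbed(t) - V_d``: starts at the peak deficit ``-V_d`` (dilution
    is instantaneous) and ends at ``+V`` for a fully absorbable drink.  Water
    diverted to the colon never returns, so a lactulose load leaves a lasting
    deficit.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return absorption_timecourse(result, t).absorbed - result.V_d
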