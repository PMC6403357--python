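"""Species generation from random life-history trade-off allocations.

Each coral species receives a fixed budget of 100 resource units (RUs) that
is split among three traits — growth performance, heat tolerance and
competitiveness — following the classic CSR-triangle view of life-history
strategies. The RU shares are mapped linearly onto per-morphotype trait
ranges, so a species that puts everything into one trait sits at the
corresponding corner of the trait triangle. Species come in massive/branching
pairs that share one allocation but differ in absolute trait values and in
three-dimensional structure (surface factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

TOTAL_RU = 100

MASSIVE = "massive"
BRANCHING = "branching"

STRATEGY_FAST_GROWING = "fast_growing"
STRATEGY_HEAT_TOLERANT = "heat_tolerant"
STRATEGY_COMPETITIVE = "competitive"
STRATEGY_MIXED = "mixed"


class ResourceAllocation(NamedTuple):
    """Integer split of the 100-RU budget across the three traits."""

    ru_growth: int
    ru_heat: int
    ru_comp: int

    def validate(self) -> "ResourceAllocation":
        if min(self) < 0:
            raise ValueError(f"negative resource allocation: {self}")
        if sum(self) != TOTAL_RU:
            raise ValueError(f"allocation must sum to {TOTAL_RU}, got {sum(self)}")
        return self


@dataclass(frozen=True)
class MorphotypeRanges:
    """[min, max] trait ranges for one growth form.

    growth is radial extension in metres per month; the competition index and
    bleaching resistance are dimensionless in [0, 1].
    """

    growth: tuple[float, float]
    competition: tuple[float, float]
    bleach_resistance: tuple[float, float]
    surface_factor: float

    def __post_init__(self) -> None:
        for name in ("growth", "competition", "bleach_resistance"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has min > max: ({lo}, {hi})")
        if self.surface_factor < 1.0:
            raise ValueError("surface_factor must be >= 1")


@dataclass(frozen=True)
class TraitRanges:
    """Per-morphotype trait parameter table.

    Defaults are calibration knobs: massive corals extend 0.4–1.7 mm/month
    and branching corals 1.7–8.3 mm/month radially; the competition-index
    ranges encode the morphotype asymmetry in standing contests for space —
    a compact massive skeleton holds ground against a branching colony
    occupying the same space, so the massive CI range (0.5–1) sits above the
    branching range (0–0.5) while the growth/heat/competition trade-off
    still operates within each morphotype. Bleaching resistance tops out at
    0.8 (no species is fully immune). Surface factors of 1 (massive
    hemisphere) and 3 (branching) emulate reef rugosity measurements.
    """

    massive: MorphotypeRanges = MorphotypeRanges(
        growth=(0.0004, 0.0017),
        competition=(0.5, 1.0),
        bleach_resistance=(0.0, 0.8),
        surface_factor=1.0,
    )
    branching: MorphotypeRanges = MorphotypeRanges(
        growth=(0.0017, 0.0083),
        competition=(0.0, 0.5),
        bleach_resistance=(0.0, 0.8),
        surface_factor=3.0,
    )

    def __post_init__(self) -> None:
        if self.branching.surface_factor <= self.massive.surface_factor:
            raise ValueError("branching surface factor must exceed massive")
        if self.branching.growth[1] < self.massive.growth[1]:
            raise ValueError("branching growth range must reach beyond massive")

    def for_morphotype(self, morphotype: str) -> MorphotypeRanges:
        if morphotype == MASSIVE:
            return self.massive
        if morphotype == BRANCHING:
            return self.branching
        raise ValueError(f"unknown morphotype: {morphotype!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "TraitRanges":
        def mk(sub: dict) -> MorphotypeRanges:
            return MorphotypeRanges(
                growth=tuple(sub["growth"]),
                competition=tuple(sub["competition"]),
                bleach_resistance=tuple(sub["bleach_resistance"]),
                surface_factor=float(sub["surface_factor"]),
            )

        return cls(massive=mk(d[MASSIVE]), branching=mk(d[BRANCHING]))

    def to_dict(self) -> dict:
        def unmk(m: MorphotypeRanges) -> dict:
            return {
                "growth": list(m.growth),
                "competition": list(m.competition),
                "bleach_resistance": list(m.bleach_resistance),
                "surface_factor": m.surface_factor,
            }

        return {MASSIVE: unmk(self.massive), BRANCHING: unmk(self.branching)}


@dataclass(frozen=True)
class Species:
    id: str
    morphotype: str
    allocation: ResourceAllocation
    growth_rate: float  # radial extension, m/month
    bleach_resistance: float
    competition_index: float
    surface_factor: float


class SpeciesPair(NamedTuple):
    massive: Species
    branching: Species


def allocate_resource_units(rng: np.random.Generator) -> ResourceAllocation:
    """Draw one allocation uniformly over the integer compositions of 100.

    Uses the stars-and-bars bijection: two distinct bar positions among the
    102 slots of 100 stars + 2 bars define the three parts, so every
    composition (including the corners of the simplex) is equally likely.
    """
    p, q = np.sort(rng.choice(TOTAL_RU + 2, size=2, replace=False))
    return ResourceAllocation(int(p), int(q - p - 1), int(TOTAL_RU + 1 - q)).validate()


def _linear_map(ru: int, lo: float, hi: float) -> float:
    return lo + (ru / TOTAL_RU) * (hi - lo)


def make_species(
    allocation: ResourceAllocation,
    morphotype: str,
    ranges: TraitRanges,
    species_id: str,
) -> Species:
    """Map an RU allocation to operational trait values for one morphotype."""
    allocation = ResourceAllocation(*allocation).validate()
    m = ranges.for_morphotype(morphotype)
    return Species(
        id=species_id,
        morphotype=morphotype,
        allocation=allocation,
        growth_rate=_linear_map(allocation.ru_growth, *m.growth),
        bleach_resistance=_linear_map(allocation.ru_heat, *m.bleach_resistance),
        competition_index=_linear_map(allocation.ru_comp, *m.competition),
        surface_factor=m.surface_factor,
    )


def make_species_pair(
    allocation: ResourceAllocation,
    ranges: TraitRanges | None = None,
    pair_id: str = "sp",
) -> SpeciesPair:
    """Build the massive/branching pair sharing one trait allocation."""
    ranges = ranges or TraitRanges()
    return SpeciesPair(
        massive=make_species(allocation, MASSIVE, ranges, f"{pair_id}_ma"),
        branching=make_species(allocation, BRANCHING, ranges, f"{pair_id}_br"),
    )


def make_species_set(
    rng: np.random.Generator,
    n_pairs: int = 10,
    ranges: TraitRanges | None = None,
    set_id: str = "set0",
) -> list[Species]:
    """Generate one community species array: n_pairs shared allocations,
    each realised as a massive and a branching species (2*n_pairs total)."""
    out: list[Species] = []
    for k in range(n_pairs):
        alloc = allocate_resource_units(rng)
        pair = make_species_pair(alloc, ranges, pair_id=f"{set_id}_p{k}")
        out.extend(pair)
    return out


def classify_strategy(
    allocation: ResourceAllocation, threshold: int = 50
) -> str:
    """Assign the CSR-style strategy group by the dominant trait.

    A species is labelled by a trait holding at least `threshold` RUs;
    otherwise it is 'mixed'. At most one trait can reach 50 of 100 unless two
    tie at exactly 50, in which case the order growth > heat > competition
    breaks the tie deterministically.
    """
    alloc = ResourceAllocation(*allocation).validate()
    if alloc.ru_growth >= threshold:
        return STRATEGY_FAST_GROWING
    if alloc.ru_heat >= threshold:
        return STRATEGY_HEAT_TOLERANT
    if alloc.ru_comp >= threshold:
        return STRATEGY_COMPETITIVE
    return STRATEGY_MIXED


# Trait-triangle vertices (unit side): growth at origin, competition on the
# x-axis, heat tolerance at the apex.
_VERTEX_GROWTH = np.array([0.0, 0.0])
_VERTEX_COMP = np.array([1.0, 0.0])
_VERTEX_HEAT = np.array([0.5, math.sqrt(3.0) / 2.0])


def ternary_coordinates(allocation: Sequence[float]) -> tuple[float, float]:
    """Barycentric → Cartesian map of an allocation into the trait triangle.

    Accepts any non-negative triple (ru_growth, ru_heat, ru_comp); the triple
    is normalised, so both RU counts and fractions work.
    """
    g, h, c = (float(v) for v in allocation)
    if min(g, h, c) < 0:
        raise ValueError("allocation components must be non-negative")
    total = g + h + c
    if total <= 0:
        raise ValueError("allocation must have a positive sum")
    w = np.array([g, h, c]) / total
    xy = w[0] * _VERTEX_GROWTH + w[1] * _VERTEX_HEAT + w[2] * _VERTEX_COMP
    return float(xy[0]), float(xy[1])


def species_table(species: Iterable[Species]) -> pd.DataFrame:
    """Tabulate a species array (one row per species) for CSV export."""
    rows = []
    for sp in species:
        x, y = ternary_coordinates(
            (sp.allocation.ru_growth, sp.allocation.ru_heat, sp.allocation.ru_comp)
        )
        rows.append(
            {
                "id": sp.id,
                "morphotype": sp.morphotype,
                "ru_growth": sp.allocation.ru_growth,
                "ru_heat": sp.allocation.ru_heat,
                "ru_comp": sp.allocation.ru_comp,
                "strategy": classify_strategy(sp.allocation),
                "growth_rate_m_per_month": sp.growth_rate,
                "bleach_resistance": sp.bleach_resistance,
                "competition_index": sp.competition_index,
                "surface_factor": sp.surface_factor,
                "ternary_x": x,
                "ternary_y": y,
            }
        )
    return pd.DataFrame(rows)
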