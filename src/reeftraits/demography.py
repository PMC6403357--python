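"""Monthly demographic processes: bleaching mortality, mechanical
disturbance, reproduction (larvae and fragmentation) and recruit survival.

Disturbance events are circular kill footprints — storms or similar impacts
that remove every organism whose centre lies inside the footprint and so
open space for settlement. Reproduction couples fecundity to a colony's
three-dimensional surface area, which makes branching corals (high surface
factor) both more fecund and able to reproduce asexually by fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reefscape import (
    ALGA,
    BIRTH_FRAGMENT,
    BIRTH_INITIAL,
    BIRTH_LARVA,
    RECRUIT_AGE_LIMIT,
    STATE_ALIVE,
    STATE_BLEACHED,
    STATE_DEAD,
    Arena,
    surface_area,
)
from .thermal import BleachParams


@dataclass(frozen=True)
class DisturbanceEvent:
    """Circular mechanical kill footprint applied in a given month."""

    month: int
    center: tuple[float, float]
    diameter: float
    size_class: str  # "small" (2–4 m) or "large" (5–10 m) at full arena scale
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.bounds or ((2.0, 4.0) if self.size_class == "small" else (5.0, 10.0))
        if not lo <= self.diameter <= hi:
            raise ValueError(
                f"{self.size_class} event diameter {self.diameter} outside [{lo},{hi}]"
            )


@dataclass(frozen=True)
class DisturbanceSchedule:
    """Mechanical disturbance regime: when enabled, one small (2–4 m) event
    every 6 months and one large (5–10 m) event every 12 months."""

    enabled: bool = True
    small_period: int = 6
    large_period: int = 12
    small_diameter: tuple[float, float] = (2.0, 4.0)
    large_diameter: tuple[float, float] = (5.0, 10.0)


@dataclass(frozen=True)
class ReproductionParams:
    """Reproduction defaults: larval recruits per m² of colony surface per
    month; monthly fragmentation probability per unit surface factor for
    branching colonies above the minimum fragmenting radius; fragment
    dispersal radius and the initial radius of settlers."""

    larval_rate_per_m2_surface: float = 0.01
    frag_rate_per_sf: float = 0.005
    min_frag_radius: float = 0.1
    frag_dispersal: float = 2.0
    recruit_radius: float = 0.01


def schedule_disturbances(
    schedule: DisturbanceSchedule,
    n_months: int,
    side: float,
    rng: np.random.Generator,
) -> list[DisturbanceEvent]:
    """Draw the full event list for a run: periodic timing, uniform random
    centres, diameters uniform within the size-class bounds."""
    if not schedule.enabled:
        return []
    events: list[DisturbanceEvent] = []
    for period, dia, cls in (
        (schedule.small_period, schedule.small_diameter, "small"),
        (schedule.large_period, schedule.large_diameter, "large"),
    ):
        for month in range(period - 1, n_months, period):
            events.append(
                DisturbanceEvent(
                    month=month,
                    center=(rng.uniform(0, side), rng.uniform(0, side)),
                    diameter=rng.uniform(*dia),
                    size_class=cls,
                    bounds=dia,
                )
            )
    events.sort(key=lambda e: (e.month, e.size_class))
    return events


def apply_disturbance(arena: Arena, event: DisturbanceEvent) -> np.ndarray:
    """Kill every coral and alga whose centre lies inside the event circle
    (periodic wrap respected). Returns the removed global indices."""
    cx, cy = event.center
    dx = np.abs(arena.x - cx)
    dy = np.abs(arena.y - cy)
    dx = np.minimum(dx, arena.side - dx)
    dy = np.minimum(dy, arena.side - dy)
    inside = (np.hypot(dx, dy) < event.diameter / 2.0) & (arena.state != STATE_DEAD)
    removed = np.flatnonzero(inside)
    arena.state[removed] = STATE_DEAD
    arena.compact()
    return removed


def apply_bleaching(
    arena: Arena,
    bp_by_species: np.ndarray,
    params: BleachParams,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Apply the monthly bleaching check.

    Each living coral bleaches with its species' effective probability;
    bleached colonies die in the same month with morphotype-specific
    mortality scaled by (1 − bleach_resistance), and survivors pause growth
    for the recovery lag before returning to the living state. Returns
    (number bleached, number died).
    """
    # tick down colonies already recovering
    recovering = arena.state == STATE_BLEACHED
    arena.bleach_t[recovering] -= 1
    arena.state[recovering & (arena.bleach_t <= 0)] = STATE_ALIVE

    if not np.any(bp_by_species > 0):
        return 0, 0
    alive = (arena.sp >= 0) & (arena.state == STATE_ALIVE)
    idx = np.flatnonzero(alive)
    if idx.size == 0:
        return 0, 0
    sp = arena.sp[idx]
    bleach = rng.random(idx.size) < bp_by_species[sp]
    bid = idx[bleach]
    if bid.size == 0:
        return 0, 0
    morph_mort = np.where(
        arena.is_branching[arena.sp[bid]],
        params.mortality_branching,
        params.mortality_massive,
    )
    p_die = morph_mort * (1.0 - arena.resistance[arena.sp[bid]])
    dies = rng.random(bid.size) < p_die
    arena.state[bid[dies]] = STATE_DEAD
    survivors = bid[~dies]
    arena.state[survivors] = STATE_BLEACHED
    arena.bleach_t[survivors] = params.recovery_lag_months
    n_bleached, n_dead = int(bid.size), int(dies.sum())
    arena.compact()
    return n_bleached, n_dead


def effective_bleaching_probabilities(
    arena: Arena, hr: float | None, params: BleachParams
) -> np.ndarray:
    """Vector of per-species effective bleaching probabilities for a month
    with heating rate `hr` (zeros when no heat stress)."""
    bp = np.zeros(arena.n_species)
    if hr is None or hr <= params.hr_min:
        return bp
    frac = min(1.0, (hr - params.hr_min) / (params.hr_max - params.hr_min))
    bp_min = np.where(arena.is_branching, params.bp_min_branching, params.bp_min_massive)
    susc = np.where(
        arena.is_branching, params.susceptibility_branching, params.susceptibility_massive
    )
    bp_actual = bp_min + frac * (1.0 - bp_min)
    return bp_actual * (1.0 - arena.resistance) * susc


def reproduce(
    arena: Arena, params: ReproductionParams, rng: np.random.Generator
) -> int:
    """Monthly reproduction; returns the number of recruits that settled.

    Larval recruitment: each species produces Poisson-many settlers with
    mean proportional to its total living surface area, dropped uniformly at
    random; settlers landing on occupied coral space fail. Fragmentation:
    branching colonies above the minimum radius shed a fragment with
    probability frag_rate_per_sf × surface_factor, which settles within the
    dispersal radius of the parent under the same space rule.
    """
    living = (arena.sp >= 0) & (arena.state == STATE_ALIVE)
    if not np.any(living):
        return 0
    surf = np.zeros(arena.n_species)
    np.add.at(
        surf,
        arena.sp[living],
        surface_area(arena.r[living], arena.sf[arena.sp[living]]),
    )

    cand_x: list[float] = []
    cand_y: list[float] = []
    cand_sp: list[int] = []
    cand_birth: list[int] = []

    n_larvae = rng.poisson(params.larval_rate_per_m2_surface * surf)
    for s in np.flatnonzero(n_larvae):
        for _ in range(int(n_larvae[s])):
            cand_x.append(rng.uniform(0, arena.side))
            cand_y.append(rng.uniform(0, arena.side))
            cand_sp.append(int(s))
            cand_birth.append(BIRTH_LARVA)

    frag_ok = (
        living
        & arena.is_branching[arena.sp]
        & (arena.r >= params.min_frag_radius)
    )
    fidx = np.flatnonzero(frag_ok)
    if fidx.size:
        p = params.frag_rate_per_sf * arena.sf[arena.sp[fidx]]
        frag = rng.random(fidx.size) < p
        for k in fidx[frag]:
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0, params.frag_dispersal)
            cand_x.append(arena.x[k] + dist * np.cos(ang))
            cand_y.append(arena.y[k] + dist * np.sin(ang))
            cand_sp.append(int(arena.sp[k]))
            cand_birth.append(BIRTH_FRAGMENT)

    if not cand_x:
        return 0
    px = np.mod(np.asarray(cand_x), arena.side)
    py = np.mod(np.asarray(cand_y), arena.side)
    free = arena.points_free_of_coral(px, py)
    settled = 0
    for xx, yy, s, b in zip(
        px[free], py[free], np.asarray(cand_sp)[free], np.asarray(cand_birth)[free]
    ):
        arena.add(xx, yy, params.recruit_radius, int(s), age=0, birth=int(b))
        settled += 1
    return settled


def recruit_survival(arena: Arena) -> np.ndarray:
    """Displace young recruits by algal contact: any coral recruit aged at
    most 4 months in contact with an algal thallus dies; older colonies are
    immune and count as ordinary colonies. Returns removed indices."""
    recruits = (
        (arena.sp >= 0)
        & (arena.state != STATE_DEAD)
        & (arena.birth != BIRTH_INITIAL)
        & (arena.age <= RECRUIT_AGE_LIMIT)
    )
    if not np.any(recruits) or not np.any(arena.alga_mask()):
        return np.empty(0, int)
    gi, gj, _ = arena.contact_pairs(arena.state != STATE_DEAD)
    doomed = np.zeros(arena.n, dtype=bool)
    if gi.size:
        for a, b in ((gi, gj), (gj, gi)):
            sel = recruits[a] & (arena.sp[b] == ALGA)
            doomed[a[sel]] = True
    removed = np.flatnonzero(doomed)
    arena.state[removed] = STATE_DEAD
    arena.compact()
    return removed


def events_frame(events: Sequence[DisturbanceEvent], kills: Sequence[int]) -> pd.DataFrame:
    """Event-log export: month, class, centre, diameter, kill count."""
    return pd.DataFrame(
        {
            "month": [e.month for e in events],
            "type": [e.size_class for e in events],
            "x": [e.center[0] for e in events],
            "y": [e.center[1] for e in events],
            "diameter": [e.diameter for e in events],
            "n_killed": list(kills),
        }
    )
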