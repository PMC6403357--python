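"""Continuous spatial arena: circular colonies, neighbour competition,
overgrowth and cover accounting.

Colonies and algal thalli are circles on a periodic square arena (default
50 × 50 m). Coral colonies grow radially each month; where two colonies are
in contact, growth over the contacted arc is reduced according to the
difference in competition index (CI): the inferior colony loses the arc
fraction of its increment scaled by ΔCI, the superior colony keeps growing
over the inferior at a rate scaled by ΔCI, and a CI tie produces a standoff
in which both partners are fully inhibited on the shared arc. Colonies may
overlap (planar cover is double-counted, so total cover can exceed 100%),
but a branching colony that is overgrown too far by superior neighbours is
displaced; massive colonies are never displaced by overlap alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .traits import BRANCHING, MASSIVE, Species

log = logging.getLogger(__name__)

STATE_ALIVE = 0
STATE_BLEACHED = 1
STATE_DEAD = 2

BIRTH_INITIAL = 0
BIRTH_LARVA = 1
BIRTH_FRAGMENT = 2

ALGA = -1  # species index for algal thalli

RECRUIT_AGE_LIMIT = 4  # months; algae can displace coral recruits up to this age


@dataclass(frozen=True)
class AlgaeParams:
    """Macroalgae dynamics: recruitment onto free space (thalli per m² per
    year), radial growth of uncontacted thalli (m/month, the fastest radial
    rate in the system), and shrinkage per contacting adult coral (m/month)."""

    recruitment_per_m2_yr: float = 0.2
    growth: float = 0.010
    shrink_per_contact: float = 0.002
    init_radius: float = 0.02


def planar_area(radius: float | np.ndarray) -> float | np.ndarray:
    """Projected (planar) area of a circular colony, m²."""
    return np.pi * np.square(radius)


def surface_area(radius, surface_factor):
    """Three-dimensional surface area: hemisphere (2πr²) times the
    morphotype surface factor."""
    return 2.0 * np.pi * np.square(radius) * np.asarray(surface_factor)


def circle_overlap_area(d, r1, r2):
    """Lens area of two circles at centre distance d (vectorised)."""
    d = np.asarray(d, dtype=float)
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), d.shape).copy()
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), d.shape).copy()
    out = np.zeros_like(d)
    rmin = np.minimum(r1, r2)
    contained = d <= np.abs(r1 - r2)
    out[contained] = np.pi * rmin[contained] ** 2
    partial = (~contained) & (d < r1 + r2)
    if np.any(partial):
        dd, a, b = d[partial], r1[partial], r2[partial]
        alpha = np.arccos(np.clip((dd**2 + a**2 - b**2) / (2 * dd * a), -1, 1))
        beta = np.arccos(np.clip((dd**2 + b**2 - a**2) / (2 * dd * b), -1, 1))
        out[partial] = (
            a**2 * (alpha - np.sin(2 * alpha) / 2)
            + b**2 * (beta - np.sin(2 * beta) / 2)
        )
    return out


def contact_arc_fraction(d, r_focal, r_neigh):
    """Fraction of the focal circle's circumference lying inside the
    neighbour (vectorised). 1 when the focal circle is engulfed, 0 when the
    neighbour is strictly inside the focal circle or out of contact."""
    d = np.asarray(d, dtype=float)
    r_focal = np.broadcast_to(np.asarray(r_focal, dtype=float), d.shape)
    r_neigh = np.broadcast_to(np.asarray(r_neigh, dtype=float), d.shape)
    out = np.zeros_like(d)
    engulfed = d <= r_neigh - r_focal
    out[engulfed] = 1.0
    chord = (~engulfed) & (d > np.abs(r_focal - r_neigh)) & (d < r_focal + r_neigh)
    if np.any(chord):
        dd, rf, rn = d[chord], r_focal[chord], r_neigh[chord]
        alpha = np.arccos(np.clip((dd**2 + rf**2 - rn**2) / (2 * dd * rf), -1, 1))
        out[chord] = alpha / np.pi
    return out


class Arena:
    """Structure-of-arrays container for all individuals on the reef.

    Corals carry a species index into the run's species array; algal thalli
    use the sentinel index ALGA. Dead individuals are removed lazily by
    `compact`, which every mutating step calls as needed.
    """

    def __init__(self, species: Sequence[Species], side: float = 50.0):
        self.side = float(side)
        self.species = list(species)
        n = len(self.species)
        self.growth = np.array([s.growth_rate for s in self.species])
        self.ci = np.array([s.competition_index for s in self.species])
        self.resistance = np.array([s.bleach_resistance for s in self.species])
        self.sf = np.array([s.surface_factor for s in self.species])
        self.is_branching = np.array(
            [s.morphotype == BRANCHING for s in self.species], dtype=bool
        )
        self.n_species = n

        self.x = np.empty(0)
        self.y = np.empty(0)
        self.r = np.empty(0)
        self.sp = np.empty(0, dtype=np.int32)
        self.age = np.empty(0, dtype=np.int32)
        self.state = np.empty(0, dtype=np.int8)
        self.birth = np.empty(0, dtype=np.int8)
        self.bleach_t = np.empty(0, dtype=np.int16)

    # -- bookkeeping ----------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def area(self) -> float:
        return self.side**2

    @property
    def max_radius(self) -> float:
        """Largest admissible colony radius; keeps periodic neighbour
        queries well defined on small arenas."""
        return self.side / 4.0

    def add(self, x, y, r, sp, age=0, state=STATE_ALIVE, birth=BIRTH_INITIAL):
        x, y, r = np.atleast_1d(x), np.atleast_1d(y), np.atleast_1d(r)
        k = x.size
        self.x = np.concatenate([self.x, np.mod(x, self.side)])
        self.y = np.concatenate([self.y, np.mod(y, self.side)])
        self.r = np.concatenate([self.r, r])
        self.sp = np.concatenate([self.sp, np.full(k, sp, dtype=np.int32)])
        self.age = np.concatenate([self.age, np.full(k, age, dtype=np.int32)])
        self.state = np.concatenate([self.state, np.full(k, state, dtype=np.int8)])
        self.birth = np.concatenate([self.birth, np.full(k, birth, dtype=np.int8)])
        self.bleach_t = np.concatenate([self.bleach_t, np.zeros(k, dtype=np.int16)])

    def compact(self) -> None:
        keep = self.state != STATE_DEAD
        if keep.all():
            return
        for name in ("x", "y", "r", "sp", "age", "state", "birth", "bleach_t"):
            setattr(self, name, getattr(self, name)[keep])

    def coral_mask(self) -> np.ndarray:
        return (self.sp >= 0) & (self.state != STATE_DEAD)

    def alga_mask(self) -> np.ndarray:
        return (self.sp == ALGA) & (self.state != STATE_DEAD)

    # -- geometry -------------------------------------------------------

    def periodic_distance(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        dx = np.abs(self.x[i] - self.x[j])
        dy = np.abs(self.y[i] - self.y[j])
        dx = np.minimum(dx, self.side - dx)
        dy = np.minimum(dy, self.side - dy)
        return np.hypot(dx, dy)

    def _tree(self, idx: np.ndarray) -> cKDTree:
        pts = np.column_stack([self.x[idx], self.y[idx]])
        return cKDTree(pts, boxsize=self.side)

    def contact_pairs(
        self, mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All strictly contacting pairs (d < r_i + r_j) among entities in
        `mask` (default: every non-dead entity), with periodic wrap-around.
        Returns (i, j, d) as global indices."""
        if mask is None:
            mask = self.state != STATE_DEAD
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            return (np.empty(0, int), np.empty(0, int), np.empty(0))
        tree = self._tree(idx)
        rmax = float(self.r[idx].max())
        search = min(2.0 * rmax, 0.499 * self.side)
        pairs = tree.query_pairs(r=search, output_type="ndarray")
        if pairs.size == 0:
            return (np.empty(0, int), np.empty(0, int), np.empty(0))
        gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
        d = self.periodic_distance(gi, gj)
        touch = d < self.r[gi] + self.r[gj]
        return gi[touch], gj[touch], d[touch]

    def points_free_of_coral(self, px: np.ndarray, py: np.ndarray) -> np.ndarray:
        """Boolean mask of query points not covered by any living coral."""
        cidx = np.flatnonzero(self.coral_mask())
        free = np.ones(px.size, dtype=bool)
        if cidx.size == 0 or px.size == 0:
            return free
        tree = self._tree(cidx)
        rmax = float(self.r[cidx].max())
        search = min(rmax, 0.499 * self.side)
        hits = tree.query_ball_point(np.column_stack([px, py]), r=search)
        for k, hh in enumerate(hits):
            if not hh:
                continue
            h = cidx[np.asarray(hh, dtype=int)]
            dx = np.abs(self.x[h] - px[k])
            dy = np.abs(self.y[h] - py[k])
            dx = np.minimum(dx, self.side - dx)
            dy = np.minimum(dy, self.side - dy)
            if np.any(np.hypot(dx, dy) < self.r[h]):
                free[k] = False
        return free

    def snapshot(self) -> pd.DataFrame:
        """Arena export: one row per non-dead individual."""
        keep = self.state != STATE_DEAD
        morph = np.where(self.sp >= 0, "", "alga")
        names = np.array([s.id for s in self.species] + ["alga"])
        morphs = np.array(
            [s.morphotype for s in self.species] + ["alga"]
        )
        return pd.DataFrame(
            {
                "id": np.flatnonzero(keep),
                "species": names[self.sp[keep]],
                "morphotype": morphs[self.sp[keep]],
                "x": self.x[keep],
                "y": self.y[keep],
                "radius": self.r[keep],
                "age": self.age[keep],
                "state": self.state[keep],
            }
        )


def find_contacts(arena: Arena, index: int) -> list[tuple[int, float]]:
    """Neighbours of one entity with their overlap depth (r_i + r_j − d),
    strictly positive, respecting periodic wrap-around."""
    mask = arena.state != STATE_DEAD
    if not mask[index]:
        return []
    others = np.flatnonzero(mask)
    others = others[others != index]
    if others.size == 0:
        return []
    d = arena.periodic_distance(np.full(others.size, index), others)
    depth = arena.r[index] + arena.r[others] - d
    sel = depth > 0
    return [(int(j), float(o)) for j, o in zip(others[sel], depth[sel])]


def initialize_community(
    species: Sequence[Species],
    total_cover_pct: float,
    rng: np.random.Generator,
    side: float = 50.0,
    radius_range: tuple[float, float] = (0.05, 0.5),
    quota_tol: float = 0.02,
    max_attempts: int = 200,
) -> Arena:
    """Randomly place randomly sized colonies so every species holds an
    equal share of the requested total planar cover.

    Massive species are placed first; branching colonies are rejected from
    positions whose centre falls inside an existing massive colony, so where
    the morphotypes would initially coincide the massive colony retains the
    space. Per-species cover lands within ±5% of its quota (placement stops
    within `quota_tol` relative).
    """
    arena = Arena(species, side=side)
    if not species:
        return arena
    quota = (total_cover_pct / 100.0) * arena.area / len(species)
    r_lo, r_hi = radius_range

    order = sorted(range(len(species)), key=lambda i: species[i].morphotype != MASSIVE)
    massive_done = False
    massive_tree = None
    massive_idx = None
    for si in order:
        sp = species[si]
        if sp.morphotype == BRANCHING and not massive_done:
            massive_idx = np.flatnonzero(arena.coral_mask())
            massive_tree = arena._tree(massive_idx) if massive_idx.size else None
            massive_done = True
        placed = 0.0
        while quota - placed > quota_tol * quota:
            r = rng.uniform(r_lo, r_hi)
            if planar_area(r) > quota - placed:
                r = float(np.sqrt((quota - placed) / np.pi))
                if r < 0.005:
                    break
            ok = False
            for _ in range(max_attempts):
                px, py = rng.uniform(0, side, 2)
                if sp.morphotype == BRANCHING and massive_tree is not None:
                    rmax = float(arena.r[massive_idx].max())
                    hits = massive_tree.query_ball_point(
                        [px, py], r=min(rmax, 0.499 * side)
                    )
                    if hits:
                        h = massive_idx[np.asarray(hits, dtype=int)]
                        dx = np.minimum(
                            np.abs(arena.x[h] - px), side - np.abs(arena.x[h] - px)
                        )
                        dy = np.minimum(
                            np.abs(arena.y[h] - py), side - np.abs(arena.y[h] - py)
                        )
                        if np.any(np.hypot(dx, dy) < arena.r[h]):
                            continue
                ok = True
                break
            if not ok:
                log.warning(
                    "species %s: placement quota unreachable after %d attempts "
                    "(placed %.1f of %.1f m2)",
                    sp.id,
                    max_attempts,
                    placed,
                    quota,
                )
                break
            arena.add(px, py, r, si, age=60, birth=BIRTH_INITIAL)
            placed += planar_area(r)
    return arena


def growth_step(arena: Arena, dt: float = 1.0) -> None:
    """One month of radial growth with arc-weighted neighbour inhibition.

    Only living corals grow (bleached colonies pause but still obstruct).
    For each contact, the focal colony's increment is reduced by
    arc_fraction × penalty, where penalty = ΔCI if the focal colony is
    inferior, 1 − ΔCI if it is superior, and 1 for a CI tie (standoff).
    """
    coral = arena.coral_mask()
    gi, gj, d = arena.contact_pairs(coral)
    penalty_sum = np.zeros(arena.n)
    if gi.size:
        for a, b in ((gi, gj), (gj, gi)):
            arc = contact_arc_fraction(d, arena.r[a], arena.r[b])
            ci_a = arena.ci[arena.sp[a]]
            ci_b = arena.ci[arena.sp[b]]
            dci = ci_b - ci_a
            pen = np.where(dci > 0, dci, np.where(dci < 0, 1.0 + dci, 1.0))
            np.add.at(penalty_sum, a, arc * pen)
    grow = coral & (arena.state == STATE_ALIVE)
    eff = np.clip(1.0 - penalty_sum[grow], 0.0, 1.0)
    arena.r[grow] = np.minimum(
        arena.r[grow] + arena.growth[arena.sp[grow]] * dt * eff, arena.max_radius
    )
    arena.age[arena.state != STATE_DEAD] += 1


def resolve_overgrowth(arena: Arena, threshold: float = 0.75) -> np.ndarray:
    """Displace branching colonies whose planar area is overlapped beyond
    `threshold` by superior neighbours; massive colonies are never displaced
    by overlap alone. Returns removed global indices."""
    coral = arena.coral_mask()
    gi, gj, d = arena.contact_pairs(coral)
    if gi.size == 0:
        return np.empty(0, int)
    overlapped = np.zeros(arena.n)
    for a, b in ((gi, gj), (gj, gi)):
        focal_branching = arena.is_branching[arena.sp[a]]
        ci_a = arena.ci[arena.sp[a]]
        ci_b = arena.ci[arena.sp[b]]
        neigh_massive = ~arena.is_branching[arena.sp[b]]
        superior = (ci_b > ci_a) | ((ci_b == ci_a) & neigh_massive & focal_branching)
        sel = focal_branching & superior
        if np.any(sel):
            lens = circle_overlap_area(d[sel], arena.r[a[sel]], arena.r[b[sel]])
            np.add.at(overlapped, a[sel], lens)
    frac = overlapped / planar_area(arena.r)
    doomed = coral & arena.is_branching[arena.sp] & (frac > threshold)
    removed = np.flatnonzero(doomed)
    arena.state[removed] = STATE_DEAD
    arena.compact()
    return removed


def algae_step(arena: Arena, params: AlgaeParams, rng: np.random.Generator) -> None:
    """Monthly macroalgae dynamics: recruit onto coral-free space, grow when
    uncontacted, shrink per contacting adult coral and disappear at zero
    radius. (Displacement of young coral recruits by algal contact is applied
    in the demographic recruit-survival step.)"""
    n_attempts = rng.poisson(params.recruitment_per_m2_yr * arena.area / 12.0)
    if n_attempts:
        px = rng.uniform(0, arena.side, n_attempts)
        py = rng.uniform(0, arena.side, n_attempts)
        free = arena.points_free_of_coral(px, py)
        for xx, yy in zip(px[free], py[free]):
            arena.add(xx, yy, params.init_radius, ALGA, age=0, birth=BIRTH_LARVA)

    algae = arena.alga_mask()
    if not np.any(algae):
        return
    gi, gj, _ = arena.contact_pairs(arena.state != STATE_DEAD)
    contacts = np.zeros(arena.n)
    if gi.size:
        adult = lambda k: (arena.sp[k] >= 0) & (arena.age[k] > RECRUIT_AGE_LIMIT)
        for a, b in ((gi, gj), (gj, gi)):
            sel = (arena.sp[a] == ALGA) & adult(b)
            np.add.at(contacts, a[sel], 1.0)
    contacted = algae & (contacts > 0)
    arena.r[contacted] -= params.shrink_per_contact * contacts[contacted]
    growing = algae & (contacts == 0)
    arena.r[growing] = np.minimum(arena.r[growing] + params.growth, arena.max_radius)
    arena.state[algae & (arena.r <= 0)] = STATE_DEAD
    arena.compact()


def cover_report(arena: Arena) -> pd.DataFrame:
    """Planar percentage cover per species (overlaps double-counted, so the
    total may exceed 100%), with morphotype attached."""
    cover = np.zeros(arena.n_species)
    coral = arena.coral_mask()
    if np.any(coral):
        np.add.at(cover, arena.sp[coral], planar_area(arena.r[coral]))
    cover = cover / arena.area * 100.0
    return pd.DataFrame(
        {
            "species": [s.id for s in arena.species],
            "morphotype": [s.morphotype for s in arena.species],
            "cover_pct": cover,
        }
    )


def morphotype_cover(arena: Arena) -> dict[str, float]:
    rep = cover_report(arena)
    return {
        MASSIVE: float(rep.loc[rep.morphotype == MASSIVE, "cover_pct"].sum()),
        BRANCHING: float(rep.loc[rep.morphotype == BRANCHING, "cover_pct"].sum()),
    }
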