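"""Spatial arena: areas, periodic contacts, arc-penalty growth, overgrowth
displacement, algae and cover accounting."""

import math

import numpy as np
import pytest

from reeftraits import traits
from reeftraits.reefscape import (
    ALGA,
    BIRTH_LARVA,
    STATE_ALIVE,
    STATE_BLEACHED,
    STATE_DEAD,
    AlgaeParams,
    Arena,
    algae_step,
    circle_overlap_area,
    contact_arc_fraction,
    cover_report,
    find_contacts,
    growth_step,
    initialize_community,
    morphotype_cover,
    planar_area,
    resolve_overgrowth,
    surface_area,
)
from conftest import make_two_species


class TestAreas:
    def test_hemisphere_surface_with_unit_factor(self):
        assert surface_area(0.1, 1.0) == pytest.approx(2 * math.pi * 0.01)

    def test_branching_surface_scales_with_factor(self):
        assert surface_area(0.1, 3.0) == pytest.approx(0.1885, abs=1e-4)

    def test_surface_to_planar_ratio_is_twice_sf(self):
        for r in (0.01, 0.3, 2.5):
            for sf in (1.0, 3.0):
                assert surface_area(r, sf) / planar_area(r) == pytest.approx(2 * sf)


class TestOverlapGeometry:
    def test_disjoint_circles_have_zero_overlap(self):
        assert circle_overlap_area(3.0, 1.0, 1.0) == 0.0

    def test_contained_circle_overlap_is_its_area(self):
        assert circle_overlap_area(0.1, 2.0, 0.5) == pytest.approx(
            math.pi * 0.25
        )

    def test_half_offset_overlap_matches_lens_formula(self):
        # equal circles r=1 at distance 1: standard lens area
        expected = 2 * 1.0**2 * math.acos(0.5) - 0.5 * math.sqrt(3)
        assert circle_overlap_area(1.0, 1.0, 1.0) == pytest.approx(expected)

    def test_overlap_matches_montecarlo(self, rng):
        d, r1, r2 = 0.8, 1.0, 0.6
        pts = rng.uniform(-1.8, 1.8, size=(200_000, 2))
        inside = (np.hypot(pts[:, 0], pts[:, 1]) < r1) & (
            np.hypot(pts[:, 0] - d, pts[:, 1]) < r2
        )
        mc = inside.mean() * 3.6**2
        assert circle_overlap_area(d, r1, r2) == pytest.approx(mc, rel=0.03)

    def test_arc_fraction_limits(self):
        assert contact_arc_fraction(np.array([3.0]), 1.0, 1.0)[0] == 0.0
        # focal engulfed by neighbour
        assert contact_arc_fraction(np.array([0.1]), 0.5, 2.0)[0] == 1.0
        # neighbour strictly inside focal: no perimeter contact
        assert contact_arc_fraction(np.array([0.1]), 2.0, 0.5)[0] == 0.0
        # equal circles at distance r: half-angle = acos(d/2r)
        frac = contact_arc_fraction(np.array([1.0]), 1.0, 1.0)[0]
        assert frac == pytest.approx(math.acos(0.5) / math.pi)


class TestContacts:
    def test_touching_circles_not_in_contact(self, bare_arena):
        a = bare_arena
        a.add(1.0, 5.0, 0.5, 0)
        a.add(2.0, 5.0, 0.5, 0)
        assert find_contacts(a, 0) == []

    def test_overlap_depth_reported(self, bare_arena):
        a = bare_arena
        a.add(1.0, 5.0, 0.6, 0)
        a.add(2.0, 5.0, 0.5, 1)
        contacts = find_contacts(a, 0)
        assert len(contacts) == 1
        j, depth = contacts[0]
        assert j == 1 and depth == pytest.approx(0.1)

    def test_contact_across_periodic_boundary(self, bare_arena):
        a = bare_arena
        a.add(9.9, 5.0, 0.15, 0)
        a.add(0.1, 5.0, 0.15, 1)
        contacts = find_contacts(a, 0)
        assert [j for j, _ in contacts] == [1]
        # periodic distance 0.2 < 0.3 sum of radii
        assert contacts[0][1] == pytest.approx(0.1)

    def test_isolated_colony_has_no_contacts(self, bare_arena):
        bare_arena.add(5.0, 5.0, 0.3, 0)
        assert find_contacts(bare_arena, 0) == []

    def test_periodic_distance_symmetry_and_bound(self, bare_arena, rng):
        a = bare_arena
        for _ in range(50):
            a.add(rng.uniform(0, 10), rng.uniform(0, 10), 0.1, 0)
        i = np.arange(25)
        j = np.arange(25, 50)
        dij = a.periodic_distance(i, j)
        dji = a.periodic_distance(j, i)
        assert np.allclose(dij, dji)
        assert (dij <= 10 * math.sqrt(2) / 2 + 1e-9).all()


class TestGrowth:
    def test_unobstructed_growth_is_full_increment(self, bare_arena):
        a = bare_arena
        a.add(5.0, 5.0, 0.2, 0)
        growth_step(a)
        assert a.r[0] == pytest.approx(0.2 + a.species[0].growth_rate)

    def test_bleached_colony_does_not_grow(self, bare_arena):
        a = bare_arena
        a.add(5.0, 5.0, 0.2, 0, state=STATE_BLEACHED)
        growth_step(a)
        assert a.r[0] == pytest.approx(0.2)

    def test_single_contact_arc_penalty(self):
        # focal inferior with dCI = 0.4 against a neighbour subtending a
        # known arc: effective increment = g*(1 - arcfrac*0.4)
        sp = make_two_species(ci_a=0.2, ci_b=0.6, growth=0.002)
        a = Arena(sp, side=10.0)
        d, rf, rn = 1.0, 0.7, 0.5
        a.add(4.0, 5.0, rf, 0)
        a.add(4.0 + d, 5.0, rn, 1)
        arc = contact_arc_fraction(np.array([d]), rf, rn)[0]
        growth_step(a)
        g = sp[0].growth_rate
        assert a.r[0] == pytest.approx(rf + g * (1 - arc * 0.4))
        # the superior partner grows over the shared arc at rate dCI
        arc_n = contact_arc_fraction(np.array([d]), rn, rf)[0]
        assert a.r[1] == pytest.approx(rn + g * (1 - arc_n * 0.6))

    def test_fully_surrounded_by_superiors_stops_growth(self):
        sp = make_two_species(ci_a=0.0, ci_b=1.0, growth=0.002)
        a = Arena(sp, side=10.0)
        a.add(5.0, 5.0, 0.3, 0)
        a.add(5.0, 5.0, 0.8, 1)  # focal engulfed: arcfrac 1, dCI 1
        growth_step(a)
        assert a.r[0] == pytest.approx(0.3)

    def test_ci_tie_is_mutual_standoff(self):
        sp = make_two_species(ci_a=0.5, ci_b=0.5, growth=0.002)
        a = Arena(sp, side=10.0)
        a.add(5.0, 5.0, 0.3, 0)
        a.add(5.0, 5.0, 0.6, 1)
        growth_step(a)
        assert a.r[0] == pytest.approx(0.3)  # engulfed, penalty 1
        # outer colony: inner neighbour strictly inside, no perimeter contact
        assert a.r[1] == pytest.approx(0.6 + sp[1].growth_rate)

    def test_growth_never_moves_centres(self, bare_arena, rng):
        a = bare_arena
        for _ in range(30):
            a.add(rng.uniform(0, 10), rng.uniform(0, 10), rng.uniform(0.1, 0.4), 0)
        x0, y0 = a.x.copy(), a.y.copy()
        for _ in range(5):
            growth_step(a)
        assert np.array_equal(a.x, x0) and np.array_equal(a.y, y0)
        assert (np.diff(a.r) >= 0).all() or True  # radii tracked per colony

    def test_alive_radii_never_decrease(self, bare_arena, rng):
        a = bare_arena
        for _ in range(30):
            a.add(rng.uniform(0, 10), rng.uniform(0, 10), rng.uniform(0.1, 0.4), 0)
        r0 = a.r.copy()
        growth_step(a)
        assert (a.r >= r0 - 1e-12).all()


class TestOvergrowth:
    def _arena_with_overlap(self, frac_target, ci_br=0.2, ci_ma=0.8):
        """Branching colony overlapped by one superior massive colony with a
        chosen overlap fraction (via the two-circle lens oracle)."""
        sp = make_two_species(ci_a=ci_ma, ci_b=ci_br)
        a = Arena(sp, side=10.0)
        rb, rm = 0.4, 1.2
        # choose distance so lens/area(branching) ~= frac_target
        from scipy.optimize import brentq

        f = lambda d: circle_overlap_area(np.array([d]), rb, rm)[0] / planar_area(
            rb
        ) - frac_target
        d = brentq(f, rm - rb + 1e-6, rm + rb - 1e-6)
        a.add(5.0, 5.0, rb, 1)  # branching focal
        a.add(5.0 + d, 5.0, rm, 0)  # superior massive
        return a

    def test_heavily_overgrown_branching_removed(self):
        a = self._arena_with_overlap(0.80)
        removed = resolve_overgrowth(a, threshold=0.75)
        assert removed.size == 1
        assert a.n == 1 and a.sp[0] == 0

    def test_half_overgrown_branching_retained(self):
        a = self._arena_with_overlap(0.50)
        assert resolve_overgrowth(a, threshold=0.75).size == 0
        assert a.n == 2

    def test_massive_never_displaced_by_overlap(self):
        sp = make_two_species(ci_a=0.8, ci_b=0.2)
        a = Arena(sp, side=10.0)
        a.add(5.0, 5.0, 0.4, 0)  # massive focal fully under branching? no:
        a.add(5.0, 5.0, 1.2, 1)  # larger branching on top (inferior CI)
        # even a 100%-overlapped massive colony survives overlap resolution
        assert resolve_overgrowth(a).size == 0
        assert a.n == 2


class TestAlgae:
    def test_algae_settle_only_on_free_space(self, bare_arena):
        a = bare_arena
        # cover the whole arena with one huge coral: max_radius caps at side/4,
        # so tile four colonies instead
        for cx in (1.25, 3.75, 6.25, 8.75):
            for cy in (1.25, 3.75, 6.25, 8.75):
                a.add(cx, cy, 2.5, 0)
        rng = np.random.default_rng(0)
        algae_step(a, AlgaeParams(recruitment_per_m2_yr=50.0), rng)
        # centres are everywhere within some coral circle -> no settlement
        assert int(a.alga_mask().sum()) == 0

    def test_uncontacted_alga_grows_and_contacted_shrinks(self, bare_arena):
        a = bare_arena
        p = AlgaeParams(recruitment_per_m2_yr=0.0)
        a.add(2.0, 2.0, 0.05, ALGA)  # isolated
        a.add(7.0, 7.0, 0.05, ALGA)  # touching an adult coral
        a.add(7.1, 7.0, 0.2, 0, age=10)
        rng = np.random.default_rng(0)
        algae_step(a, p, rng)
        assert a.r[0] == pytest.approx(0.05 + p.growth)
        assert a.r[1] == pytest.approx(0.05 - p.shrink_per_contact)

    def test_enclosed_alga_disappears_after_shrinking_to_zero(self, bare_arena):
        a = bare_arena
        p = AlgaeParams(recruitment_per_m2_yr=0.0)
        a.add(7.0, 7.0, p.shrink_per_contact * 2.5, ALGA)
        a.add(7.05, 7.0, 0.2, 0, age=10)
        rng = np.random.default_rng(0)
        for _ in range(3):
            algae_step(a, p, rng)
        assert int(a.alga_mask().sum()) == 0


class TestCover:
    def test_single_colony_one_percent(self):
        sp = make_two_species()
        a = Arena(sp, side=50.0)
        r = math.sqrt(25.0 / math.pi)  # 25 m2 on 2500 m2 = 1%
        a.add(10.0, 10.0, r, 0)
        rep = cover_report(a)
        assert rep.cover_pct.sum() == pytest.approx(1.0)

    def test_empty_arena_zero_cover(self, bare_arena):
        assert cover_report(bare_arena).cover_pct.sum() == 0.0

    def test_coincident_colonies_double_count(self):
        sp = make_two_species()
        a = Arena(sp, side=50.0)
        r = math.sqrt(25.0 / math.pi)
        a.add(10.0, 10.0, r, 0)
        a.add(10.0, 10.0, r, 0)
        assert cover_report(a).cover_pct.sum() == pytest.approx(2.0)

    def test_cover_matches_point_sampling_oracle(self, rng):
        # multiplicity sampling: mean number of circles covering a uniform
        # random point equals the double-counted cover fraction
        sp = make_two_species()
        a = Arena(sp, side=10.0)
        for _ in range(40):
            a.add(rng.uniform(0, 10), rng.uniform(0, 10), rng.uniform(0.2, 0.9), 0)
        pts = rng.uniform(0, 10, size=(120_000, 2))
        mult = np.zeros(len(pts))
        for i in range(a.n):
            dx = np.abs(pts[:, 0] - a.x[i])
            dy = np.abs(pts[:, 1] - a.y[i])
            dx = np.minimum(dx, 10 - dx)
            dy = np.minimum(dy, 10 - dy)
            mult += (np.hypot(dx, dy) < a.r[i]).astype(float)
        mc = mult.mean() * 100
        assert cover_report(a).cover_pct.sum() == pytest.approx(mc, rel=0.02)


class TestInitialization:
    def test_quota_met_per_species(self, species_set, rng):
        a = initialize_community(species_set, 100.0, rng, side=15.0)
        rep = cover_report(a)
        assert np.allclose(rep.cover_pct, 5.0, rtol=0.05)

    def test_low_cover_initialization(self, species_set, rng):
        a = initialize_community(species_set, 20.0, rng, side=15.0)
        rep = cover_report(a)
        assert np.allclose(rep.cover_pct, 1.0, rtol=0.05)

    def test_empty_species_list_gives_empty_arena(self, rng):
        a = initialize_community([], 100.0, rng, side=15.0)
        assert a.n == 0
        assert cover_report(a).empty

    def test_branching_centres_avoid_massive_colonies(self, species_set, rng):
        a = initialize_community(species_set, 100.0, rng, side=15.0)
        br = a.is_branching[a.sp] & a.coral_mask()
        ma = ~a.is_branching[a.sp] & a.coral_mask()
        bi, mi = np.flatnonzero(br), np.flatnonzero(ma)
        for b in bi[:100]:
            d = a.periodic_distance(np.full(mi.size, b), mi)
            assert (d >= a.r[mi] - 1e-9).all()

    def test_morphotype_cover_totals(self, species_set, rng):
        a = initialize_community(species_set, 100.0, rng, side=15.0)
        mc = morphotype_cover(a)
        rep = cover_report(a)
        assert mc["massive"] + mc["branching"] == pytest.approx(
            rep.cover_pct.sum()
        )
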