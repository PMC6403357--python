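# Methods

## Overview

`reeftraits` simulates a benthic coral community as interacting circular
individuals on a continuous, periodic square arena. Massive and branching
coral species defined by a three-way life-history trade-off compete for
space, reproduce, and suffer mortality from heat-driven bleaching and from
mechanical disturbance. The package's purpose is comparative: holding the
trait-generation process fixed, it asks which trait combinations persist
under different climates and how fast a community's thermal baseline must
move for the community to survive warming.

## Trait model

Each species allocates exactly 100 integer resource units among growth,
heat tolerance and competitiveness. Allocations are drawn uniformly over
the integer 3-simplex (stars-and-bars), so corners (pure strategies) are
reachable and each component has mean 100/3. A species' operational traits
are linear maps of its RU shares onto per-morphotype ranges:

| trait | massive | branching | units |
|---|---|---|---|
| radial extension | 0.4–1.7 | 1.7–8.3 | mm·month⁻¹ |
| competition index (CI) | 0.5–1.0 | 0.0–0.5 | – |
| bleaching resistance | 0.0–0.8 | 0.0–0.8 | – |
| surface factor | 1.0 | 3.0 | – |

Extension rates bracket typical massive and branching coral growth.
Bleaching resistance is capped at 0.8: no coral is immune. The surface
factor multiplies the hemispherical surface `2πr²` and drives fecundity,
fragmentation and the morphotype growth-rate difference; 3 for branching
corals approximates reef rugosity measurements. The CI ranges are disjoint
by design: in standing space contests a compact massive skeleton retains
ground against branching neighbours, while the trade-off still
differentiates species within a morphotype. All ranges are configuration
values (`TraitRanges`), not hard-coded behaviour; they are stand-in
calibrations and the single most influential free choice in the model.

Species are generated in massive/branching pairs sharing one allocation
(20 species = 10 pairs per community array). Strategy labels (fast-growing
/ heat-tolerant / competitive / mixed) use a dominant-trait rule at 50 RU,
which partitions the simplex totally and deterministically.

## Space, growth and competition

Colonies are circles with fixed centres on a periodic arena (default
50 × 50 m; any side is allowed and smaller arenas are the supported
desk scale). Neighbour search uses a periodic k-d tree; two individuals are
in contact when their centre distance is strictly less than the sum of
radii.

A living colony's monthly radial increment `g` is reduced by each contact:
the colony loses `arcfrac × penalty` of its increment per contact, where
`arcfrac` is the fraction of its circumference inside the neighbour.
For the lower-CI partner the penalty is ΔCI; the higher-CI partner keeps
growing over the neighbour at rate ΔCI (penalty 1 − ΔCI); an exact CI tie
is a standoff (penalty 1 for both). Negative totals clamp to zero growth.
Radii are capped at a quarter of the arena side — a numerical guard that
keeps periodic geometry well defined on small arenas and is not binding at
full scale.

Overlap is allowed and cover is double-counted (total cover may exceed
100%). The asymmetric brake on overgrowth: a branching colony whose own
area is overlapped more than 75% (configurable) by superior neighbours is
displaced and dies; massive colonies are never displaced by overlap alone.
A consequence of the arc-penalty growth rule worth stating plainly: because
an inferior colony is only fractionally inhibited (ΔCI < 1 on most
contacts), mutual overlap deepens over decades and the undisturbed
community equilibrates at a double-counted cover well above 100% (≈190% on
a 12 m arena after 90 years). Quantities expressed "relative to initial
cover" inherit this inflation.

At initialisation, randomly sized colonies (radii uniform in 0.05–0.5 m)
are placed uniformly at random until each species meets its planar-cover
quota (total cover / number of species, within ±5%). Massive species are
placed first and branching centres are rejected from massive-occupied
points, implementing the rule that massive corals retain initially
contested space.

## Macroalgae

Algal thalli are circles that recruit onto coral-free points (0.2
thalli·m⁻²·yr⁻¹), grow at 10 mm·month⁻¹ (the fastest radial rate in the
system) while uncontacted, shrink by 2 mm·month⁻¹ per contacting adult
coral, and disappear at zero radius. Their single demographic effect is to
kill coral recruits aged ≤ 4 months on contact. Algae affect all coral
species equally; their parameters shape recruitment intensity, not the
trait comparisons.

## Thermal environment and bleaching

The synthetic climatology emulates a tropical western-Indian-Ocean SST
record: a sinusoid (mean 27 °C, amplitude 1.5 °C, peak in mid-March) plus
AR(1) daily weather with month-scale persistence (marginal sd 0.35 °C,
autocorrelation 0.97 ≈ 33-day e-folding — SST anomalies persist for weeks,
which is what lets degree-heating sums accumulate) and a per-year offset
(sd 0.3 °C) for interannual variability. Twelve such normal years form the
pool that is concatenated in random order; a single extreme-year template
adds a smooth anomaly whose March mean is exactly +2 °C — at ~4σ of the
combined interannual spread it plays the role of the one extreme year in a
~14-year record. Warming is a staircase of 0.5 °C increments evenly spaced
to reach the scenario total within the final decade; increments apply to
extreme years too, preserving the pool's variability. Years are 365 days;
no leap days.

LMST is the mean over the trailing B years (12-month blocks, updated
monthly) of each block's three warmest month means. Each run prepends B
years of spin-up climatology so LMST and the 120-day DHD window are defined
from the first scenario month. The monthly bleaching check, on the last day
of each month, computes DHD and — if DHD > 40 strictly — HR, then the
per-species bleaching probability: linear ramp from `bp_min` (0.2 massive /
0.25 branching) at `HR_min = 1` to 1 at `HR_max = 3.5`, times
`1 − resistance` (the morphotype susceptibility modifier exists but
defaults to 1, since `bp_min` and mortality already carry the morphotype
asymmetry). Bleached colonies die the same month with probability
`mortality × (1 − resistance)` (0.6 massive / 0.8 branching); survivors
stop growing for a 3-month recovery lag.

`HR_min` is the calibration anchor. With the defaults, one extreme-template
year produces ~6 consecutive stress months (HR ≈ 1.0–1.45) and a
cumulative community bleaching mortality near 50%, matching the severity
reported for the 1998 western-Indian-Ocean event; the control climatology
(no extremes, no warming) stays below HR_min everywhere, so the baseline
scenario is bleaching-free. `calibrate_bleaching` exposes this fit: it
bisects `HR_min` to hit a target expected community mortality at a given
event HR. Two regime consequences follow from this calibration rather than
from any tuning: fast-adapting communities (B=10) never cross HR_min under
gradual warming alone (bleaching is prevented almost entirely), while
slow-adapting communities (B=50) accumulate chronic stress whose HR grows
with the warming lag.

The adaptation-rate mapping `rate = (ΔT/(H/10)) × (10/B)` °C·decade⁻¹
expresses the warming a community tracks when its baseline integrates the
last B years; with H = 90 it reproduces the characteristic rates for
(ΔT, B) = (1, 50) → 0.022, (4, 50) → 0.089, (2, 10) → 0.22 and
(4, 10) → 0.44.

## Demography

Mechanical disturbance, when enabled, applies one small (2–4 m diameter)
kill footprint every 6 months and one large (5–10 m) every 12; every
individual whose centre lies inside the circle dies. On reduced arenas the
footprint diameters scale with the arena side so the disturbed-area
fraction is preserved. Reproduction has two channels: larval settlement
with per-species Poisson counts proportional to total living surface area
(0.01 recruits·m⁻² surface·month⁻¹), placed uniformly and failing on
coral-occupied points; and fragmentation of branching colonies above 0.1 m
radius (probability 0.005 × sf per month) settling within 2 m of the
parent. Recruits start at 1 cm radius, are vulnerable to algae through age
4 months, and then count as ordinary colonies. There is no background
senescence mortality.

The monthly step order is: growth/competition → overgrowth displacement →
algae → bleaching check → scheduled disturbance → reproduction → recruit
survival, with cover snapshots annually. A per-month ledger records every
birth and death by cause; population counts balance exactly.

## Randomness and reproducibility

One root seed spawns named independent streams (traits, climate,
placement, demography), so subsystems are reproducible in isolation;
(seed, config) determines every output bit. Ensemble runs spawn one stream
per species set and one per replicate.

## Ensembles and reported metrics

The full design is 10 independent 20-species arrays × 20 replicates
(200 species). Survivor counts and the pooled Shannon index are reported on
that 200-species scale; when an ensemble simulates k < 10 sets, survivor
counts are multiplied by 10/k and the pooled Shannon index is shifted by
ln(10/k) — exact for exchangeable, equally covered sets and the natural
scaled-down estimator. The massive:branching dominance ratio divides the
run-averaged massive cover by the run-averaged branching cover (stable when
branching cover approaches zero in single runs). Evenness is Pielou's
J = H/ln S.

## Problem sizes used for the shipped analyses

The shipped acceptance analysis (`scripts/acceptance.py`) and the
end-to-end tests run at a desk scale chosen as the package's own reduced
configuration: a 12 m arena (≈350 initial colonies at 100% cover), 3
species sets × 2 replicates per scenario cell, and 2 × 2 for the seven-cell
adaptation grid, 90 simulated years everywhere. Smaller arenas make species
extinction easier (fewer colonies per species) and make single disturbance
footprints relatively coarser; directional results are preserved, absolute
survivor counts are biased low relative to full scale.

## Known limitations

- The trait ranges, bleaching ramp (`bp_min`, linear form) and
  algae/recruitment constants are stand-in calibrations; the comparative
  results (which strategies win under which regime) are robust to moderate
  changes, absolute covers and survivor counts are not.
- The arc-penalty growth rule lets double-counted cover exceed 100%
  substantially in crowded, undisturbed communities (see above);
  relative-cover outputs should be read against that baseline, not against
  a union-area notion of cover.
- Because bleaching probability and bleached mortality are both discounted
  by `1 − resistance`, extreme heat (HR ≥ 3.5) bleaches every colony but
  does not kill fully resistant species outright.
- No acidification, no inter-reef connectivity, no within-run trait
  evolution, no polyp-level physiology; substrate is homogeneous.
- The synthetic climatology reproduces seasonal shape, persistence and
  interannual spread but not observed skewness, multi-year ENSO phasing or
  trends in the real record it stands in for.
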