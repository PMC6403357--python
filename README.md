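# reeftraits

A spatially explicit, individual-based simulator of coral reef communities
under thermal stress, mechanical disturbance and gradual ocean warming. It is
aimed at reef ecologists and modellers who want to explore which life-history
trait combinations let coral species persist under climate-change scenarios,
and what community-level adaptation rate would be required to keep reefs
alive through the end of the century.

## The model in brief

**Species and trade-offs.** Every coral species receives 100 resource units
(RU) split randomly among three traits — growth rate *g*, heat tolerance
(bleaching resistance *r*) and competitiveness (competition index *CI*) — so
each species is a point on the Grime-style trait triangle. Species come in
massive/branching pairs sharing one allocation; absolute trait values are a
linear map of the RU shares onto per-morphotype ranges. Branching corals grow
faster, fragment, and carry a higher surface factor *sf* (surface area
`2πr²·sf`), but bleach and break more easily; massive corals hold space.

**Space.** Colonies are circles on a periodic 50 × 50 m arena. Each month a
colony extends its radius by *g*, reduced on every contacted arc according to
the CI difference with the neighbour (inferior partner loses `arcfrac·ΔCI`
of its increment; a CI tie is a standoff). Colonies may overlap — planar
cover is double-counted and can exceed 100% — but a branching colony
overlapped beyond 75% of its area by superior neighbours is displaced.
Macroalgae occupy free space, displace coral recruits up to 4 months old,
and are slowly pushed back by adult corals.

**Bleaching.** The long-term mean summer temperature (LMST) is the mean of
each year's three warmest month means over a rolling base period of *B*
years, updated monthly. Degree heating days `DHD = Σ max(T_d − LMST, 0)`
accumulate over a trailing 120-day window; when DHD exceeds 40 °C·days the
heating rate `HR = DHD / #{days above LMST}` sets the monthly bleaching
probability, ramping linearly from `bp_min` at `HR_min` to 1 at
`HR_max = 3.5` (all corals bleach), scaled by `1 − r`. Bleached colonies die
with morphotype-specific mortality or pause growth while recovering.
Because a shorter base period lets LMST track warming faster, *B* acts as
the community's adaptation speed: the adaptation rate equivalent to warming
ΔT over a horizon H is `(ΔT / (H/10)) · (10 / B)` °C per decade.

**Scenarios.** Scenario 1: constant climate, with/without mechanical
disturbance (2–4 m kill footprints every 6 months, 5–10 m every 12).
Scenario 2: extreme thermal (El Niño-like) years — a +2 °C March anomaly —
recurring every τ ∈ {2,4,6,8,10} years. Scenario 3: gradual warming in
0.5 °C steps to 0.5–4 °C by year 90, with fast (B=10) to slow (B=50)
adaptation, with or without 8-yearly extreme years. Ensembles combine
several independent 20-species arrays with replicates.

## Worked example

```python
import numpy as np
from reeftraits import ScenarioConfig, run_scenario

cfg = ScenarioConfig(scenario="S3", tau=None, delta_t_total=2.0, b_years=50,
                     initial_cover_pct=100.0, side=12.0, n_years=90)
res = run_scenario(cfg, seed=1)
print(round(res.total_cover().iloc[-1], 1))   # total cover (%) at year 90
print(int((res.annual_cover.iloc[-1] > 0).sum()))  # surviving species of 20
print(int(res.ledger.bleach_deaths.sum()))    # colonies killed by bleaching
```

prints

```
69.3
11
641
```

on a 12 m desk-scale arena: under +2 °C with slow adaptation the community
ends with 69.3% cover (down from 100%), 11 of 20 species still present, and
641 colonies lost to bleaching over the 90 years. The same run with
`b_years=10` produces no bleaching deaths at all — the rolling baseline
tracks the warming — which is the adaptation-potential contrast the
simulator is built to expose.

The same experiment from a shell:

```sh
reeftraits run --scenario S3 --delta-t 2 --b-years 50 --side 12 --seed 1 -v
reeftraits ensemble --scenario S2 --side 12 --sets 3 --replicates 2
reeftraits grid --scenario S3 --delta-t-list 1,2,4 --b-list 10,50 --side 12
```

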