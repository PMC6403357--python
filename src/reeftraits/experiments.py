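"""Scenario definitions, the monthly simulation loop, ensembles and
community metrics.

Three experiment families are supported. Scenario 1 is the bleaching-free
baseline (constant climate, with or without mechanical disturbance, initial
cover 20% or 100%). Scenario 2 adds extreme thermal (El Niño-like) years
recurring every τ years. Scenario 3 adds gradual warming in 0.5 °C steps to
0.5–4 °C above current conditions by the end of the 90-year run, and varies
the LMST base period B (10–50 years) to contrast fast- and slow-adapting
communities. Each ensemble draws several independent 20-species arrays
(massive/branching pairs sharing allocations) and replicates each array.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import demography, reefscape, thermal, traits

log = logging.getLogger(__name__)

FULL_SIDE = 50.0
SPECIES_PER_SET = 20
FULL_N_SETS = 10
FULL_SPECIES = FULL_N_SETS * SPECIES_PER_SET  # 200


@dataclass
class ScenarioConfig:
    """Complete definition of one experiment.

    tau is the extreme-thermal-event interval in years (None = never);
    delta_t_total the additional warming reached by the end of the run (°C);
    b_years the LMST base period. `side` sets the arena edge in metres —
    values below 50 m are the reduced desk scale, and disturbance footprints
    are shrunk by the same linear factor so the regime stays comparable.
    """

    scenario: str = "S1"
    initial_cover_pct: float = 100.0
    disturbance_enabled: bool = False
    tau: float | None = None
    delta_t_total: float = 0.0
    b_years: int = 50
    n_species_sets: int = 10
    n_replicates: int = 20
    n_years: int = 90
    seed: int = 0
    side: float = FULL_SIDE
    trait_ranges: traits.TraitRanges = field(default_factory=traits.TraitRanges)
    climate: thermal.ClimateParams = field(default_factory=thermal.ClimateParams)
    bleach: thermal.BleachParams = field(default_factory=thermal.BleachParams)
    algae: reefscape.AlgaeParams = field(default_factory=reefscape.AlgaeParams)
    reproduction: demography.ReproductionParams = field(
        default_factory=demography.ReproductionParams
    )
    overgrowth_threshold: float = 0.75

    def validate(self) -> "ScenarioConfig":
        tau = None if self.tau in (None, math.inf) else float(self.tau)
        if self.scenario == "S1":
            if tau is not None or self.delta_t_total != 0:
                raise ValueError("S1 allows no extreme events and no warming")
        elif self.scenario == "S2":
            if tau is not None and tau not in (2, 4, 6, 8, 10):
                raise ValueError("S2 requires tau in {2,4,6,8,10} or none")
            if self.initial_cover_pct != 100:
                raise ValueError("S2 runs start from 100% cover")
            if self.delta_t_total != 0:
                raise ValueError("S2 has no gradual warming")
        elif self.scenario == "S3":
            steps = round(self.delta_t_total / 0.5)
            if not (0 < self.delta_t_total <= 4.0) or not math.isclose(
                steps * 0.5, self.delta_t_total
            ):
                raise ValueError("S3 warming must be one of 0.5,1.0,...,4.0 °C")
            if tau is not None and tau != 8:
                raise ValueError("S3 extreme events recur every 8 years or never")
        else:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 10 <= self.b_years <= 50:
            raise ValueError("LMST base period must lie in [10, 50] years")
        return self

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "scenario",
                "initial_cover_pct",
                "disturbance_enabled",
                "tau",
                "delta_t_total",
                "b_years",
                "n_species_sets",
                "n_replicates",
                "n_years",
                "seed",
                "side",
                "overgrowth_threshold",
            )
        }
        d["trait_ranges"] = self.trait_ranges.to_dict()
        for key, obj in (
            ("climate", self.climate),
            ("bleach", self.bleach),
            ("algae", self.algae),
            ("reproduction", self.reproduction),
        ):
            d[key] = {k: v for k, v in obj.__dict__.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "trait_ranges" in d:
            d["trait_ranges"] = traits.TraitRanges.from_dict(d["trait_ranges"])
        for key, klass in (
            ("climate", thermal.ClimateParams),
            ("bleach", thermal.BleachParams),
            ("algae", reefscape.AlgaeParams),
            ("reproduction", demography.ReproductionParams),
        ):
            if key in d:
                d[key] = klass(**d[key])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    """Outputs of a single simulation run."""

    config: ScenarioConfig
    species: list[traits.Species]
    annual_cover: pd.DataFrame  # year × species cover (%), wide
    ledger: pd.DataFrame  # monthly demographic event counts
    events: pd.DataFrame  # disturbance log
    arena: reefscape.Arena
    initial_cover_pct: float

    def total_cover(self) -> pd.Series:
        return self.annual_cover.sum(axis=1)

    def morphotype_cover(self) -> pd.DataFrame:
        morph = {s.id: s.morphotype for s in self.species}
        g = self.annual_cover.T.groupby(
            self.annual_cover.columns.map(morph)
        ).sum()
        return g.T


def _streams(seed) -> dict[str, np.random.Generator]:
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = ("traits", "climate", "placement", "demography")
    return {
        n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))
    }


def run_scenario(
    config: ScenarioConfig,
    species: Sequence[traits.Species] | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> RunResult:
    """Run one replicate: monthly loop of thermal update → growth →
    overgrowth → algae → bleaching check → scheduled disturbance →
    reproduction → recruit survival, with annual cover snapshots.

    Fully reproducible: (seed, config) determine every output. `species`
    may be supplied to reuse one species array across replicates; otherwise
    it is drawn from the run's own trait stream.
    """
    config.validate()
    rngs = _streams(config.seed if seed is None else seed)
    if species is None:
        species = traits.make_species_set(rngs["traits"], ranges=config.trait_ranges)
    species = list(species)

    arena = reefscape.initialize_community(
        species, config.initial_cover_pct, rngs["placement"], side=config.side
    )
    initial = float(reefscape.cover_report(arena)["cover_pct"].sum())
    sp_ids = [s.id for s in species]

    if config.n_years == 0:
        cov0 = reefscape.cover_report(arena).set_index("species")["cover_pct"]
        annual = pd.DataFrame([cov0.reindex(sp_ids)], index=[0])
        annual.index.name = "year"
        empty = pd.DataFrame()
        return RunResult(config, species, annual, empty, empty, arena, initial)

    # climate and thermal trajectory
    pool, extreme = thermal.make_year_pool(config.climate, rngs["climate"])
    spinup = thermal.build_scenario_series(
        pool, config.b_years, None, 0.0, rngs["climate"]
    )
    scenario_series = thermal.build_scenario_series(
        pool, config.n_years, config.tau, config.delta_t_total, rngs["climate"], extreme
    )
    full = np.concatenate([spinup.daily_temps, scenario_series.daily_temps])
    traj = thermal.compute_thermal_trajectory(
        full, config.b_years, config.b_years, config.bleach
    )

    scale = config.side / FULL_SIDE
    schedule = demography.DisturbanceSchedule(
        enabled=config.disturbance_enabled,
        small_diameter=(2.0 * scale, 4.0 * scale),
        large_diameter=(5.0 * scale, 10.0 * scale),
    )
    events = demography.schedule_disturbances(
        schedule, 12 * config.n_years, config.side, rngs["demography"]
    )
    events_by_month: dict[int, list[demography.DisturbanceEvent]] = {}
    for ev in events:
        events_by_month.setdefault(ev.month, []).append(ev)
    event_kills: list[int] = []

    annual_rows = []
    ledger_rows = []
    for m in range(12 * config.n_years):
        n_before = int(arena.coral_mask().sum())
        reefscape.growth_step(arena)
        n_overgrown = reefscape.resolve_overgrowth(
            arena, config.overgrowth_threshold
        ).size
        reefscape.algae_step(arena, config.algae, rngs["demography"])
        bp = demography.effective_bleaching_probabilities(
            arena, traj.hr_or_none(m), config.bleach
        )
        n_bleached, n_bleach_dead = demography.apply_bleaching(
            arena, bp, config.bleach, rngs["demography"]
        )
        n_dist = 0  # coral deaths only; the event log counts algae too
        for ev in events_by_month.get(m, ()):
            corals_before = int(arena.coral_mask().sum())
            removed = demography.apply_disturbance(arena, ev)
            event_kills.append(int(removed.size))
            n_dist += corals_before - int(arena.coral_mask().sum())
        n_recruits = demography.reproduce(arena, config.reproduction, rngs["demography"])
        n_algal_kill = demography.recruit_survival(arena).size
        ledger_rows.append(
            {
                "month": m,
                "corals_start": n_before,
                "recruits": n_recruits,
                "overgrowth_deaths": n_overgrown,
                "bleached": n_bleached,
                "bleach_deaths": n_bleach_dead,
                "disturbance_deaths": n_dist,
                "algal_deaths": n_algal_kill,
                "corals_end": int(arena.coral_mask().sum()),
                "lmst": traj.lmst[m],
                "dhd": traj.dhd[m],
            }
        )
        if (m + 1) % 12 == 0:
            cov = reefscape.cover_report(arena).set_index("species")["cover_pct"]
            annual_rows.append(cov.reindex(sp_ids))
            year = (m + 1) // 12
            if year % 10 == 0:
                log.info(
                    "year %d: %d corals, total cover %.1f%%",
                    year,
                    int(arena.coral_mask().sum()),
                    float(cov.sum()),
                )

    annual = pd.DataFrame(annual_rows, index=np.arange(1, config.n_years + 1))
    annual.index.name = "year"
    ev_frame = demography.events_frame(
        [e for mm in sorted(events_by_month) for e in events_by_month[mm]],
        event_kills,
    )
    ledger = pd.DataFrame(ledger_rows)
    return RunResult(config, species, annual, ledger, ev_frame, arena, initial)


# -- community metrics ----------------------------------------------------


def shannon_index(cover_by_species: Sequence[float]) -> float:
    """Shannon diversity H = −Σ p_i ln p_i over positive cover shares."""
    c = np.asarray(cover_by_species, dtype=float)
    if np.any(c < 0):
        raise ValueError("covers must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("at least one species must have positive cover")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def evenness(h: float, n_species: int) -> float:
    """Pielou's J = H / ln S over the S surviving species (NaN for S < 2)."""
    if n_species < 2:
        return float("nan")
    return h / math.log(n_species)


@dataclass
class EnsembleSummary:
    """Aggregated outputs of an ensemble (species sets × replicates).

    Headline community metrics are reported on the scale of the full design
    (10 species sets = 200 species): when fewer sets are simulated, survivor
    counts are scaled by 10/n_sets and the pooled Shannon index is shifted by
    ln(10/n_sets), which is exact for exchangeable, equally covered sets.
    """

    config: ScenarioConfig
    species_stats: pd.DataFrame  # per (set, species): mean/sd cover, survival
    yearly_total: pd.DataFrame  # mean relative total cover (%) per year
    survivors_of_200: float
    shannon: float
    evenness: float
    relative_cover_pct: float
    massive_cover_pct: float
    branching_cover_pct: float
    massive_branching_ratio: float
    n_runs: int


def run_ensemble(
    config: ScenarioConfig, return_runs: bool = False
) -> EnsembleSummary | tuple[EnsembleSummary, list[RunResult]]:
    """Run the full ensemble: n_species_sets independent species arrays ×
    n_replicates runs each, aggregated into community metrics at year 90."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    set_seeds = root.spawn(config.n_species_sets)
    runs: list[RunResult] = []
    rows = []
    rel_by_year = []
    # per replicate-index pooled final covers, for survivor and H statistics
    pooled_final: dict[int, list[np.ndarray]] = {
        j: [] for j in range(config.n_replicates)
    }
    pooled_morph: dict[int, list[tuple[float, float]]] = {
        j: [] for j in range(config.n_replicates)
    }
    rel_final = []
    for s, sseed in enumerate(set_seeds):
        sp_rng = np.random.default_rng(sseed)
        species = traits.make_species_set(
            sp_rng, ranges=config.trait_ranges, set_id=f"set{s}"
        )
        rep_seeds = sseed.spawn(config.n_replicates)
        final_covers = []
        for j, rseed in enumerate(rep_seeds):
            res = run_scenario(config, species=species, seed=rseed)
            final = res.annual_cover.iloc[-1].to_numpy()
            final_covers.append(final)
            pooled_final[j].append(final)
            morph = res.morphotype_cover().iloc[-1]
            pooled_morph[j].append(
                (float(morph.get("massive", 0.0)), float(morph.get("branching", 0.0)))
            )
            rel_final.append(res.total_cover().iloc[-1] / res.initial_cover_pct * 100)
            rel_by_year.append(res.total_cover() / res.initial_cover_pct * 100)
            if return_runs:
                runs.append(res)
        fc = np.stack(final_covers)
        for k, sp in enumerate(species):
            rows.append(
                {
                    "set": s,
                    "species": sp.id,
                    "morphotype": sp.morphotype,
                    "ru_growth": sp.allocation.ru_growth,
                    "ru_heat": sp.allocation.ru_heat,
                    "ru_comp": sp.allocation.ru_comp,
                    "mean_cover": fc[:, k].mean(),
                    "sd_cover": fc[:, k].std(ddof=0),
                    "survival_fraction": float((fc[:, k] > 0).mean()),
                }
            )

    scale = FULL_N_SETS / config.n_species_sets
    surv, hs = [], []
    ratios_m, ratios_b = [], []
    for j in range(config.n_replicates):
        covers = np.concatenate(pooled_final[j])
        surv.append(int((covers > 0).sum()) * scale)
        if np.any(covers > 0):
            hs.append(shannon_index(covers) + math.log(scale))
        ma = sum(m for m, _ in pooled_morph[j])
        br = sum(b for _, b in pooled_morph[j])
        ratios_m.append(ma)
        ratios_b.append(br)

    survivors = float(np.mean(surv))
    h = float(np.mean(hs)) if hs else 0.0
    j_even = evenness(h, max(2, int(round(survivors)))) if survivors >= 2 else float("nan")
    mean_ma = float(np.mean(ratios_m))
    mean_br = float(np.mean(ratios_b))
    ratio = mean_ma / mean_br if mean_br > 0 else float("inf")
    yearly = pd.concat(rel_by_year, axis=1).mean(axis=1).to_frame("relative_cover_pct")

    summary = EnsembleSummary(
        config=config,
        species_stats=pd.DataFrame(rows),
        yearly_total=yearly,
        survivors_of_200=survivors,
        shannon=h,
        evenness=j_even,
        relative_cover_pct=float(np.mean(rel_final)),
        massive_cover_pct=mean_ma,
        branching_cover_pct=mean_br,
        massive_branching_ratio=ratio,
        n_runs=config.n_species_sets * config.n_replicates,
    )
    return (summary, runs) if return_runs else summary


def trait_occupancy(summary: EnsembleSummary) -> pd.DataFrame:
    """Trait-triangle occupancy: mean ± SD cover per (allocation, morphotype)
    with planar ternary coordinates for plotting."""
    df = summary.species_stats
    g = (
        df.groupby(["ru_growth", "ru_heat", "ru_comp", "morphotype"], as_index=False)
        .agg(mean_cover=("mean_cover", "mean"), sd_cover=("sd_cover", "mean"))
    )
    xy = [
        traits.ternary_coordinates((r.ru_growth, r.ru_heat, r.ru_comp))
        for r in g.itertuples()
    ]
    g["ternary_x"] = [p[0] for p in xy]
    g["ternary_y"] = [p[1] for p in xy]
    return g


def adaptation_grid(
    delta_t_list: Sequence[float],
    b_list: Sequence[int],
    tau: float | None,
    base_config: ScenarioConfig,
) -> pd.DataFrame:
    """Relative year-90 cover across the warming × adaptation grid, with the
    required adaptation rate (°C/decade) attached per cell."""
    rows = []
    for dt in delta_t_list:
        for b in b_list:
            cfg = replace(
                base_config,
                scenario="S3",
                delta_t_total=float(dt),
                b_years=int(b),
                tau=tau,
            )
            summ = run_ensemble(cfg)
            rows.append(
                {
                    "delta_t_total": dt,
                    "b_years": b,
                    "tau": tau if tau is not None else math.inf,
                    "relative_cover_pct": summ.relative_cover_pct,
                    "survivors_of_200": summ.survivors_of_200,
                    "adaptation_rate_c_per_decade": thermal.required_adaptation_rate(
                        dt, base_config.n_years, b
                    ),
                }
            )
            log.info(
                "grid cell dT=%.1f B=%d: %.1f%% cover", dt, b, rows[-1]["relative_cover_pct"]
            )
    return pd.DataFrame(rows)


def summary_manifest(summary: EnsembleSummary) -> dict:
    """JSON-serialisable run manifest."""
    return {
        "config": summary.config.to_dict(),
        "n_runs": summary.n_runs,
        "survivors_of_200": summary.survivors_of_200,
        "shannon": summary.shannon,
        "evenness": summary.evenness,
        "relative_cover_pct": summary.relative_cover_pct,
        "massive_branching_ratio": summary.massive_branching_ratio,
    }
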