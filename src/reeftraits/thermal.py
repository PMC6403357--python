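"""Thermal environment: synthetic climatologies, rolling LMST, DHD/HR and
bleaching probabilities.

The bleaching model follows the degree-heating-days convention: the long-term
mean summer temperature (LMST) is the mean, over a rolling base period of B
years, of each year's three warmest calendar-month means, updated monthly.
Degree heating days (DHD) accumulate the positive daily exceedances of LMST
over a trailing 120-day window; if more than 40 DHD accrue, the heating rate
HR = DHD / (days above LMST) drives the monthly bleaching probability, with
HR_max = 3.5 the rate at which bleaching probability saturates. A shorter
base period B makes LMST track warming faster and thereby mimics a faster
community adaptation rate.

The synthetic climatology emulates a tropical Indian-Ocean seasonal cycle
(warmest months February–April) with AR(1) daily weather and interannual
year-to-year offsets; the "extreme year" template carries a smooth anomaly
that lifts the March mean by ~2 °C, the signature of an El Niño bleaching
year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])  # len 13
MARCH = 2


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic daily SST generator.

    mean_sst/amplitude/peak_day define the seasonal sinusoid (°C, days);
    noise_sd and ar1 the daily AR(1) weather (marginal sd in °C);
    interannual_sd the sd of per-year mean offsets (°C); extreme_anomaly the
    March-mean excess of the extreme-year template (°C) spread as a Gaussian
    bump of width extreme_width_days; n_pool_years the number of distinct
    normal years available for concatenation.
    """

    mean_sst: float = 27.0
    amplitude: float = 1.5
    peak_day: int = 74  # mid-March
    noise_sd: float = 0.35
    ar1: float = 0.97
    interannual_sd: float = 0.3
    extreme_anomaly: float = 2.0
    extreme_width_days: float = 45.0
    n_pool_years: int = 12

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("seasonal amplitude must be non-negative")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")


@dataclass(frozen=True)
class BleachParams:
    """Bleaching-response parameters.

    hr_min/hr_max bracket the linear ramp of bleaching probability from
    bp_min to 1; bp_min and the susceptibility modifier are per morphotype
    (massive corals are slightly more heat tolerant); mortality is the
    probability that a bleached colony dies in the event month; surviving
    bleached colonies stop growing for recovery_lag_months.
    """

    hr_max: float = 3.5
    hr_min: float = 1.0
    bp_min_massive: float = 0.2
    bp_min_branching: float = 0.25
    susceptibility_massive: float = 1.0
    susceptibility_branching: float = 1.0
    mortality_massive: float = 0.6
    mortality_branching: float = 0.8
    recovery_lag_months: int = 3
    dhd_threshold: float = 40.0
    window_days: int = 120

    def __post_init__(self) -> None:
        if not 0 < self.hr_min < self.hr_max:
            raise ValueError("require 0 < hr_min < hr_max")
        for bp in (self.bp_min_massive, self.bp_min_branching):
            if not 0 < bp < 1:
                raise ValueError("bp_min must lie in (0, 1)")

    def bp_min(self, morphotype: str) -> float:
        return self.bp_min_massive if morphotype == "massive" else self.bp_min_branching

    def susceptibility(self, morphotype: str) -> float:
        return (
            self.susceptibility_massive
            if morphotype == "massive"
            else self.susceptibility_branching
        )

    def mortality(self, morphotype: str) -> float:
        return (
            self.mortality_massive if morphotype == "massive" else self.mortality_branching
        )


@dataclass
class Climatology:
    """A contiguous daily SST series in °C (365-day years, no leap days)."""

    daily_temps: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.daily_temps = np.asarray(self.daily_temps, dtype=float)
        if self.daily_temps.ndim != 1 or self.daily_temps.size == 0:
            raise ValueError("daily_temps must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.daily_temps)):
            raise ValueError("daily_temps must be finite")

    @property
    def n_days(self) -> int:
        return int(self.daily_temps.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": np.arange(self.n_days), "temp_c": self.daily_temps}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Climatology":
        df = pd.read_csv(path)
        if "temp_c" not in df.columns:
            raise ValueError("climatology CSV needs a temp_c column")
        return cls(df["temp_c"].to_numpy(dtype=float), provenance="user")


def _seasonal_cycle(params: ClimateParams) -> np.ndarray:
    t = np.arange(DAYS_PER_YEAR)
    return params.mean_sst + params.amplitude * np.cos(
        2.0 * np.pi * (t - params.peak_day) / DAYS_PER_YEAR
    )


def _extreme_profile(params: ClimateParams) -> np.ndarray:
    """Smooth anomaly whose March mean equals exactly extreme_anomaly °C."""
    t = np.arange(DAYS_PER_YEAR)
    bump = np.exp(-0.5 * ((t - params.peak_day) / params.extreme_width_days) ** 2)
    march = slice(MONTH_STARTS[MARCH], MONTH_STARTS[MARCH + 1])
    return bump * (params.extreme_anomaly / bump[march].mean())


def synthesize_base_year(
    params: ClimateParams, rng: np.random.Generator, extreme: bool = False
) -> np.ndarray:
    """Generate one 365-day year: sinusoid + AR(1) weather + year offset.

    The extreme variant adds the Gaussian March anomaly on top of the same
    seasonal cycle, so with all noise switched off the extreme-year March
    mean sits exactly extreme_anomaly above the normal-year March mean.
    """
    year = _seasonal_cycle(params).copy()
    if params.noise_sd > 0:
        innov_sd = params.noise_sd * math.sqrt(1.0 - params.ar1**2)
        eps = rng.normal(0.0, innov_sd, DAYS_PER_YEAR)
        noise = np.empty(DAYS_PER_YEAR)
        noise[0] = rng.normal(0.0, params.noise_sd)
        for i in range(1, DAYS_PER_YEAR):
            noise[i] = params.ar1 * noise[i - 1] + eps[i]
        year += noise
    if params.interannual_sd > 0:
        year += rng.normal(0.0, params.interannual_sd)
    if extreme:
        year += _extreme_profile(params)
    return year


def make_year_pool(
    params: ClimateParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (normal-year pool, extreme-year template) for a run.

    Mirrors the use of a short observed climatology: a fixed pool of normal
    years that are concatenated in random order, plus a single extreme-year
    template (the El Niño year, kept out of the pool) that is inserted on the
    extreme-event schedule.
    """
    pool = np.stack(
        [synthesize_base_year(params, rng) for _ in range(params.n_pool_years)]
    )
    extreme = synthesize_base_year(params, rng, extreme=True)
    return pool, extreme


def warming_offsets(
    delta_t_total: float, n_years: int, increment: float = 0.5
) -> np.ndarray:
    """Per-year additive warming offsets: a staircase of fixed increments,
    evenly spaced so the cumulative offset reaches delta_t_total within the
    final decade of the run."""
    if delta_t_total < 0:
        raise ValueError("delta_t_total must be non-negative")
    if delta_t_total == 0:
        return np.zeros(n_years)
    n_inc = max(1, int(round(delta_t_total / increment)))
    step = delta_t_total / n_inc
    y = np.arange(1, n_years + 1)
    return step * np.floor(n_inc * y / n_years + 0.5)


def build_scenario_series(
    year_pool: np.ndarray,
    n_years: int,
    extreme_interval_tau: float | None,
    delta_t_total: float,
    rng: np.random.Generator,
    extreme_year: np.ndarray | None = None,
) -> Climatology:
    """Concatenate pool years in random order (with replacement), insert the
    extreme template every tau-th year, and add the warming staircase.

    tau = None or inf disables extreme events. Extreme years are placed
    deterministically at years tau, 2·tau, ... for reproducibility, and the
    warming increments apply to extreme years too (warming shifts the whole
    distribution, preserving the pool's variability).
    """
    year_pool = np.atleast_2d(np.asarray(year_pool, dtype=float))
    if year_pool.shape[1] != DAYS_PER_YEAR:
        raise ValueError("year_pool rows must be 365-day years")
    tau = extreme_interval_tau
    if tau is not None and not math.isinf(tau):
        if tau <= 0:
            raise ValueError("extreme interval tau must be positive")
        if extreme_year is None:
            raise ValueError("extreme_year template required when tau is finite")
        tau = int(tau)
    else:
        tau = None

    idx = rng.integers(0, year_pool.shape[0], size=n_years)
    years = year_pool[idx].copy()
    if tau is not None:
        for y in range(tau, n_years + 1, tau):
            years[y - 1] = extreme_year
    years += warming_offsets(delta_t_total, n_years)[:, None]
    return Climatology(years.reshape(-1), provenance="synthetic")


def monthly_means(daily: np.ndarray) -> np.ndarray:
    """Calendar-month means of a daily series that starts at a year boundary
    and ends at a month boundary."""
    daily = np.asarray(daily, dtype=float)
    if daily.size == 0:
        raise ValueError("empty temperature history")
    bounds = []
    pos = 0
    m = 0
    while pos < daily.size:
        ln = int(MONTH_LENGTHS[m % 12])
        if pos + ln > daily.size:
            raise ValueError("history must end at a calendar-month boundary")
        bounds.append((pos, pos + ln))
        pos += ln
        m += 1
    return np.array([daily[a:b].mean() for a, b in bounds])


def _lmst_from_monthly(month_means: np.ndarray, b_years: int) -> float:
    """LMST from trailing monthly means: mean over the last B 12-month blocks
    of each block's three warmest month means."""
    n_months = month_means.size
    if n_months < 12:
        raise ValueError("need at least 12 months of history for LMST")
    n_blocks = min(b_years, n_months // 12)
    tail = month_means[n_months - 12 * n_blocks :].reshape(n_blocks, 12)
    top3 = np.sort(tail, axis=1)[:, -3:]
    return float(top3.mean())


def update_lmst(history: np.ndarray, b_years: int) -> float:
    """Rolling LMST: mean of the three warmest calendar-month means per year,
    averaged over the last b_years years of daily history.

    During warm-up (history shorter than b_years) all available whole years
    are used.
    """
    if b_years <= 0:
        raise ValueError("base period must be positive")
    return _lmst_from_monthly(monthly_means(history), b_years)


def compute_dhd(trailing_daily: np.ndarray, lmst: float) -> tuple[float, int]:
    """DHD over the trailing window: sum of positive exceedances of LMST,
    and the count of days above LMST."""
    trailing_daily = np.asarray(trailing_daily, dtype=float)
    if trailing_daily.size != 120:
        raise ValueError("DHD window must be exactly 120 days")
    excess = trailing_daily - lmst
    above = excess > 0
    return float(excess[above].sum()), int(above.sum())


def compute_hr(
    dhd: float, days_above: int, dhd_threshold: float = 40.0
) -> float | None:
    """Heating rate for the month, or None when the DHD threshold is not
    strictly exceeded."""
    if dhd <= dhd_threshold:
        return None
    if days_above <= 0:
        raise RuntimeError("DHD > 0 with no days above LMST is inconsistent")
    return dhd / days_above


def bleaching_probability(
    hr: float | None,
    bleach_resistance: float,
    morphotype: str,
    params: BleachParams | None = None,
) -> float:
    """Monthly bleaching probability of a colony of the given species.

    The raw probability ramps linearly from bp_min at HR_min to 1 at HR_max
    (all corals bleach), is zero at or below HR_min, and is then scaled by
    (1 - bleach_resistance) and the morphotype susceptibility modifier.
    """
    params = params or BleachParams()
    if hr is None:
        return 0.0
    if hr < 0:
        raise ValueError("heating rate cannot be negative")
    if hr <= params.hr_min:
        return 0.0
    bp_min = params.bp_min(morphotype)
    frac = min(1.0, (hr - params.hr_min) / (params.hr_max - params.hr_min))
    bp_actual = bp_min + frac * (1.0 - bp_min)
    return bp_actual * (1.0 - bleach_resistance) * params.susceptibility(morphotype)


def required_adaptation_rate(
    delta_t_total: float, horizon_years: float = 90.0, b_years: float = 50.0
) -> float:
    """Adaptation rate (°C per decade) a community needs to track warming of
    delta_t_total over horizon_years when its thermal baseline integrates the
    last b_years: the decadal warming rate scaled by (10 / B)."""
    if b_years <= 0:
        raise ValueError("base period must be positive")
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    return (delta_t_total / (horizon_years / 10.0)) * (10.0 / b_years)


@dataclass
class ThermalTrajectory:
    """Precomputed monthly thermal state over a scenario run.

    Index m runs over scenario months (0-based). hr is NaN for months in
    which the DHD threshold was not exceeded.
    """

    lmst: np.ndarray
    dhd: np.ndarray
    days_above: np.ndarray
    hr: np.ndarray
    monthly_mean: np.ndarray

    @property
    def n_months(self) -> int:
        return int(self.lmst.size)

    def hr_or_none(self, month: int) -> float | None:
        v = self.hr[month]
        return None if np.isnan(v) else float(v)


def compute_thermal_trajectory(
    full_daily: np.ndarray,
    spinup_years: int,
    b_years: int,
    bleach: BleachParams | None = None,
) -> ThermalTrajectory:
    """Monthly LMST/DHD/HR over the scenario part of a daily series.

    full_daily holds spinup_years of spin-up climatology followed by the
    scenario years, so LMST and the 120-day DHD window are defined from the
    first scenario month. LMST for month m uses history up to the start of m
    (monthly update); DHD is evaluated on the 120 days ending at m's last day
    (the monthly bleaching check).
    """
    bleach = bleach or BleachParams()
    full_daily = np.asarray(full_daily, dtype=float)
    total_days = full_daily.size
    spin_days = spinup_years * DAYS_PER_YEAR
    if total_days % DAYS_PER_YEAR:
        raise ValueError("series must hold whole 365-day years")
    n_years = total_days // DAYS_PER_YEAR - spinup_years
    if n_years <= 0:
        raise ValueError("no scenario years after spin-up")
    if spinup_years < 1:
        raise ValueError("at least one spin-up year is required")

    month_means = monthly_means(full_daily)
    n_months = 12 * n_years
    lmst = np.empty(n_months)
    dhd = np.empty(n_months)
    days_above = np.empty(n_months, dtype=int)
    hr = np.full(n_months, np.nan)
    mmean = np.empty(n_months)

    w = bleach.window_days
    for m in range(n_months):
        global_month = spinup_years * 12 + m
        lmst[m] = _lmst_from_monthly(month_means[:global_month], b_years)
        year, moy = divmod(m, 12)
        end_day = spin_days + year * DAYS_PER_YEAR + int(MONTH_STARTS[moy + 1])
        window = full_daily[end_day - w : end_day]
        excess = window - lmst[m]
        above = excess > 0
        dhd[m] = excess[above].sum()
        days_above[m] = above.sum()
        if dhd[m] > bleach.dhd_threshold:
            hr[m] = dhd[m] / days_above[m]
        mmean[m] = month_means[global_month]
    return ThermalTrajectory(lmst, dhd, days_above, hr, mmean)


def template_event_hr(
    pool: np.ndarray, extreme_year: np.ndarray, b_years: int = 50
) -> float | None:
    """HR that the extreme-year template produces against the pool's own
    climatology (baseline for bleaching calibration).

    The pool is treated as b_years of history (recycled as needed); the DHD
    window is the 120 days ending with April of the extreme year, covering
    the warm season around the March anomaly peak.
    """
    pool = np.atleast_2d(pool)
    reps = int(np.ceil(b_years / pool.shape[0]))
    history = np.tile(pool, (reps, 1))[-b_years:].reshape(-1)
    lmst = update_lmst(history, b_years)
    end = int(MONTH_STARTS[4])  # end of April
    if end >= 120:
        window = extreme_year[end - 120 : end]
    else:
        window = np.concatenate([history[-(120 - end) :], extreme_year[:end]])
    d, n = compute_dhd(window, lmst)
    return compute_hr(d, n)


def calibrate_bleaching(
    species_resistances: Sequence[float],
    species_morphotypes: Sequence[str],
    event_hr: float,
    target_mortality: float,
    params: BleachParams | None = None,
    tol: float = 1e-4,
) -> BleachParams:
    """Fit hr_min so the expected community bleaching mortality of a single
    extreme event at event_hr matches target_mortality.

    Expected mortality per colony is bp_effective × morphotype mortality ×
    (1 - resistance); the community value averages over the supplied species.
    Returns a copy of params with hr_min replaced by the bisection solution
    (clamped to the attainable range).
    """
    params = params or BleachParams()
    res = np.asarray(species_resistances, dtype=float)
    morphs = list(species_morphotypes)

    def community_mortality(hr_min: float) -> float:
        p = replace(params, hr_min=hr_min)
        tot = 0.0
        for r, m in zip(res, morphs):
            bp = bleaching_probability(event_hr, r, m, p)
            tot += bp * p.mortality(m) * (1.0 - r)
        return tot / len(morphs)

    lo, hi = 1e-3, event_hr - 1e-6
    if community_mortality(lo) < target_mortality:
        return replace(params, hr_min=lo)
    if community_mortality(hi) > target_mortality:
        return replace(params, hr_min=hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if community_mortality(mid) > target_mortality:
            lo = mid
        else:
            hi = mid
    return replace(params, hr_min=0.5 * (lo + hi))
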