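"""Synthetic scenario generator.

Produces every input the model consumes — hourly meteorology, weekday
traffic profiles, day-type factor tables, vehicle-mix tables,
emission-factor lookup tables and receptor grids — with the statistical
structure of a mid-western U.S. urban setting: a 16-sector wind rose
with occasional calms concentrated in the early morning, double-peaked
weekday traffic that flattens on weekends and holidays, a heavy-duty
fraction that is anti-correlated with total volume, U-shaped CO/NOx
speed-emission curves and speed-flat PM2.5 dominated by heavy-duty
diesels.

Everything is deterministic under a fixed seed (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .emissions import (DAY_TYPES, EmissionFactorTable, DayTypeFactors,
                        HEAVY_CLASSES, SEASONS, SPEED_BINS, VEHICLE_CLASSES)
from .geometry import Receptor

__all__ = ["ScenarioConfig", "generate_met", "generate_traffic",
           "generate_emission_table", "generate_receptor_grid",
           "generate_scenario"]

SECTOR_WIDTH = 22.5  # degrees; 16-sector rose

#: Default wind-rose probabilities by 16 compass sectors (N=0, NNE=1, ...),
#: weighted toward SW/WSW/WNW as in Great Lakes climatology.
DEFAULT_ROSE = np.array([
    0.04, 0.05, 0.05, 0.04,   # N NNE NE ENE
    0.04, 0.05, 0.06, 0.06,   # E ESE SE SSE
    0.08, 0.10, 0.12, 0.10,   # S SSW SW WSW
    0.07, 0.06, 0.05, 0.03,   # W WNW NW NNW
])

#: Hour-of-day calm probabilities: calms cluster before the morning rush
#: (overall ~8% of hours, matching a typical urban year).
DEFAULT_CALM_PROB = np.array(
    [0.14, 0.15, 0.16, 0.17, 0.17, 0.15, 0.10, 0.06,
     0.04, 0.03, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02,
     0.03, 0.03, 0.05, 0.07, 0.09, 0.11, 0.12, 0.13])

#: Weekday hour-of-day traffic shape (fraction of the daily peak):
#: distinct 7-8 am and 4-6 pm rush hours, high plateau 7 am - 8 pm.
DEFAULT_DIURNAL = np.array(
    [0.10, 0.06, 0.05, 0.05, 0.08, 0.22, 0.55, 0.92,
     1.00, 0.80, 0.70, 0.68, 0.70, 0.72, 0.78, 0.88,
     0.98, 1.00, 0.85, 0.62, 0.48, 0.38, 0.28, 0.18])

#: Fleet composition (fractions), freeway-like: ~12% HDDV.
DEFAULT_FLEET = {
    "LDV": 0.46, "LDT1": 0.12, "LDT2": 0.12, "LDT3": 0.08, "LDT4": 0.06,
    "HDDV": 0.12, "HDBUS": 0.015, "MC": 0.025,
}

#: Daily-total day-type ratios (Saturday/Sunday/holiday volumes fall by
#: 23/32/26%; heavy-duty volumes fall by 62/73/49%).
DEFAULT_DAY_RATIOS = {"saturday": 0.77, "sunday": 0.68, "holiday": 0.74}
DEFAULT_HEAVY_RATIOS = {"saturday": 0.38, "sunday": 0.27, "holiday": 0.51}

#: Observed U.S. holidays for the scenario year.
DEFAULT_HOLIDAYS_2006 = (
    "2006-01-01", "2006-05-29", "2006-07-04", "2006-09-04",
    "2006-11-23", "2006-12-25",
)


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic study conditions.

    Defaults emulate the Detroit-like setting the model targets: mean
    wind speed ~4.3 m/s, ~8% calm hours, AADT-scale traffic with
    weekday rush hours, and a 12% heavy-duty diesel share.
    """

    seed: int = 0
    n_days: int = 365
    start: str = "2006-01-01"
    rose_probs: np.ndarray = field(default_factory=lambda: DEFAULT_ROSE.copy())
    speed_mean: float = 4.4        # m/s, per-sector draw mean
    speed_sd: float = 2.1          # m/s
    calm_prob: np.ndarray = field(
        default_factory=lambda: DEFAULT_CALM_PROB.copy())
    diurnal_shape: np.ndarray = field(
        default_factory=lambda: DEFAULT_DIURNAL.copy())
    weekday_daily_total: float = 144600.0   # vehicles/day, freeway scale
    day_ratios: dict = field(default_factory=lambda: dict(DEFAULT_DAY_RATIOS))
    heavy_ratios: dict = field(default_factory=lambda: dict(DEFAULT_HEAVY_RATIOS))
    fleet: dict = field(default_factory=lambda: dict(DEFAULT_FLEET))
    holidays: tuple = DEFAULT_HOLIDAYS_2006
    co_min_speed: float = 40.0     # mph, bottom of the U-shaped CO curve
    co_base: float = 8.0           # g/mi at the minimum, fleet LDV-like
    co_curvature: float = 0.009    # g/mi per mph^2
    pm_light: float = 0.018        # g/mi, light-duty PM2.5
    pm_heavy: float = 0.30         # g/mi, heavy-duty PM2.5

    def __post_init__(self):
        self.rose_probs = np.asarray(self.rose_probs, dtype=float)
        if self.rose_probs.shape != (16,):
            raise ValueError("wind rose must have 16 sector probabilities")
        if not np.isclose(self.rose_probs.sum(), 1.0, atol=1e-9):
            raise ValueError("wind-rose probabilities must sum to 1")
        if np.any(self.rose_probs < 0) or np.any(self.calm_prob < 0) \
                or np.any(self.calm_prob > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.speed_mean <= 0 or self.speed_sd <= 0:
            raise ValueError("wind-speed scale parameters must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


def generate_met(config: ScenarioConfig) -> pd.DataFrame:
    """Hourly meteorology: wind direction from the sector rose with
    uniform within-sector jitter, speed from a truncated normal
    (>= 0.5 m/s), and Bernoulli calm flags by hour of day.  Calm hours
    carry speed 0.

    Returns a DataFrame indexed by hour-beginning timestamps with
    columns ``wind_dir_deg``, ``wind_speed_ms``, ``calm``.
    """
    rng = config.rng(1)
    idx = pd.date_range(config.start, periods=24 * config.n_days, freq="h",
                        name="timestamp")
    n = len(idx)
    sectors = rng.choice(16, size=n, p=config.rose_probs)
    jitter = rng.uniform(-SECTOR_WIDTH / 2, SECTOR_WIDTH / 2, size=n)
    wdir = np.mod(sectors * SECTOR_WIDTH + jitter, 360.0)
    a = (0.5 - config.speed_mean) / config.speed_sd
    speed = stats.truncnorm.rvs(
        a, np.inf, loc=config.speed_mean, scale=config.speed_sd,
        size=n, random_state=rng,
    )
    calm = rng.random(n) < config.calm_prob[idx.hour]
    speed = np.where(calm, 0.0, speed)
    return pd.DataFrame(
        {"wind_dir_deg": wdir, "wind_speed_ms": speed, "calm": calm.astype(int)},
        index=idx,
    )


#: Base hourly F1 shapes (ratio of day-type volume to weekday volume):
#: late-night volumes above weekday levels, the morning rush largely
#: erased, values spanning roughly 0.2-1.4.
_F1_BASE = {
    "saturday": np.array(
        [1.37, 1.30, 1.15, 0.95, 0.70, 0.45, 0.40, 0.45,
         0.55, 0.70, 0.82, 0.90, 0.95, 0.96, 0.94, 0.90,
         0.85, 0.80, 0.80, 0.84, 0.90, 1.00, 1.10, 1.25]),
    "sunday": np.array(
        [1.25, 1.18, 1.05, 0.85, 0.58, 0.32, 0.25, 0.22,
         0.21, 0.35, 0.55, 0.70, 0.80, 0.85, 0.87, 0.87,
         0.84, 0.78, 0.72, 0.68, 0.65, 0.70, 0.80, 0.95]),
    "holiday": np.array(
        [1.30, 1.22, 1.08, 0.88, 0.62, 0.38, 0.30, 0.28,
         0.30, 0.45, 0.62, 0.75, 0.84, 0.88, 0.90, 0.90,
         0.86, 0.80, 0.75, 0.72, 0.70, 0.75, 0.85, 1.00]),
}


def _f1_profile(config, day_type) -> np.ndarray:
    """Hourly F1 factors rescaled so the volume-weighted daily total
    equals the configured day-type ratio."""
    ratio = config.day_ratios[day_type]
    shape = config.diurnal_shape
    base = _F1_BASE[day_type]
    return base * (ratio / np.average(base, weights=shape))


def generate_traffic(config: ScenarioConfig):
    """Weekday traffic profile plus the F1/F3/mix factor tables.

    Returns ``(profile, factors)`` where ``profile`` is the 24-vector of
    weekday hourly volumes (veh/h) and ``factors`` a
    :class:`~nearroad.emissions.DayTypeFactors`.  The hourly heavy-duty
    mix fraction moves opposite to total volume (highest before dawn),
    and the F1 tables scale weekend/holiday totals to the configured
    daily ratios.
    """
    shape = config.diurnal_shape
    profile = shape / shape.sum() * config.weekday_daily_total

    hours = np.arange(24)
    f1 = pd.DataFrame({"weekday": np.ones(24)}, index=hours)
    for d in ("saturday", "sunday", "holiday"):
        f1[d] = _f1_profile(config, d)

    # heavy fraction anti-correlated with volume: scale the fleet HDDV
    # share so it peaks pre-dawn and dips at rush hour.
    rel_volume = shape / shape.max()
    heavy_scale = 1.6 - 0.9 * rel_volume  # ~0.7 at peak, ~1.55 overnight
    fleet = pd.Series(config.fleet).reindex(list(VEHICLE_CLASSES))
    if fleet.isna().any() or not np.isclose(fleet.sum(), 1.0, atol=1e-9):
        raise ValueError("fleet fractions must cover all classes and sum to 1")
    heavy = [k for k in VEHICLE_CLASSES if k in HEAVY_CLASSES]
    light = [k for k in VEHICLE_CLASSES if k not in HEAVY_CLASSES]

    mix_cols = {}
    for rt in ("freeway", "arterial"):
        # arterials carry about half the freeway heavy-duty share
        rt_scale = 1.0 if rt == "freeway" else 0.5
        for h in hours:
            shares = fleet.copy()
            shares[heavy] *= heavy_scale[h] * rt_scale
            shares /= shares.sum()
            for k in VEHICLE_CLASSES:
                mix_cols.setdefault((rt, k), np.zeros(24))[h] = shares[k]
    mix = pd.DataFrame(mix_cols, index=hours)
    mix.columns = pd.MultiIndex.from_tuples(mix.columns, names=["road_type", "class"])

    f3_cols = {}
    for d in ("saturday", "sunday", "holiday"):
        total_ratio, heavy_ratio = config.day_ratios[d], config.heavy_ratios[d]
        heavy_share = float(fleet[heavy].sum())
        light_ratio = (total_ratio - heavy_ratio * heavy_share) / (1 - heavy_share)
        f3_cols[(d, "light")] = np.full(24, light_ratio)
        f3_cols[(d, "heavy")] = np.full(24, heavy_ratio)
    f3 = pd.DataFrame(f3_cols, index=hours)
    f3.columns = pd.MultiIndex.from_tuples(f3.columns, names=["day_type", "duty"])

    return profile, DayTypeFactors(f1=f1, f3=f3, mix=mix)


def generate_emission_table(config: ScenarioConfig) -> EmissionFactorTable:
    """Emission-factor lookup emulating the parent model's qualitative
    behaviour: CO and NOx convex in speed with an interior minimum,
    PM2.5 flat in speed with heavy-duty factors ~30x light-duty, and
    winter CO roughly 1.5x summer.
    """
    season_co = {"winter": 1.5, "springfall": 1.2, "summer": 1.0}
    heavy_mult = {"LDV": 1.0, "LDT1": 1.2, "LDT2": 1.3, "LDT3": 1.5, "LDT4": 1.7,
                  "HDDV": 2.5, "HDBUS": 2.2, "MC": 1.4}
    rows = []
    for season in SEASONS:
        for s in SPEED_BINS:
            co_curve = config.co_base + config.co_curvature * (s - config.co_min_speed) ** 2
            nox_curve = 0.15 * co_curve
            for k in VEHICLE_CLASSES:
                pm = config.pm_heavy if k in HEAVY_CLASSES else config.pm_light
                rows.append((
                    "CO", season, k, int(s),
                    co_curve * heavy_mult[k] * season_co[season],
                ))
                rows.append(("NOx", season, k, int(s),
                             nox_curve * (3.0 if k in HEAVY_CLASSES else 1.0)))
                rows.append(("PM2.5", season, k, int(s), pm))
    frame = pd.DataFrame(
        rows, columns=["pollutant", "season", "class", "speed_mph", "g_per_mi"]
    )
    return EmissionFactorTable(frame)


def generate_receptor_grid(x_range=(-300.0, 300.0), y_range=(-300.0, 300.0),
                           spacing=50.0, prefix="R") -> list:
    """Rectangular receptor grid on ``spacing``-metre centres."""
    xs = np.arange(x_range[0], x_range[1] + spacing / 2, spacing)
    ys = np.arange(y_range[0], y_range[1] + spacing / 2, spacing)
    receptors = []
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            receptors.append(Receptor(f"{prefix}{i:02d}_{j:02d}", (float(x), float(y))))
    return receptors


def generate_scenario(config: ScenarioConfig):
    """All inputs bundled: (met, weekday profile, DayTypeFactors,
    EmissionFactorTable)."""
    met = generate_met(config)
    profile, factors = generate_traffic(config)
    table = generate_emission_table(config)
    return met, profile, factors, table
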