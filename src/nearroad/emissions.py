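"""Hourly segment emission rates from traffic, speed and lookup tables.

The emission chain is:

1. BPR volume-delay function: S = S_FF / (1 + alpha * (V/C)**beta).
2. Day-type adjustment of the weekday hourly volume, V_D = V_WD * F1.
3. Apportionment into eight vehicle classes via the weekday mix F2 and
   the day-type light/heavy ratio F3, renormalised so class volumes sum
   to the adjusted total.
4. Seasonal g/mi/vehicle emission factors looked up at the nearest 5-mph
   speed bin, summed over classes and converted to g/h/km:

       Q = 0.625 * V * sum_K M_K * q_K(S)

   where 0.625 is the printed mi->km conversion (set ``strict_units`` to
   use 1/1.609344 instead).  The fleet-average per-vehicle rate
   E = Q / V (g/km/vehicle) is what the dispersion model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VEHICLE_CLASSES",
    "HEAVY_CLASSES",
    "SPEED_BINS",
    "SEASONS",
    "EmissionFactorTable",
    "DayTypeFactors",
    "bpr_speed",
    "adjust_total_volume",
    "class_volumes",
    "season_of",
    "segment_emission_rate",
    "fleet_rate_per_vehicle",
]

#: The eight MOBILE6.2-style vehicle classes.
VEHICLE_CLASSES = (
    "LDV", "LDT1", "LDT2", "LDT3", "LDT4", "HDDV", "HDBUS", "MC",
)
#: Classes governed by the heavy-duty F3 ratio; all others use the light ratio.
HEAVY_CLASSES = frozenset({"HDDV", "HDBUS"})
SPEED_BINS = np.arange(5, 70, 5)  # mph
SEASONS = ("winter", "springfall", "summer")
DAY_TYPES = ("weekday", "saturday", "sunday", "holiday")

MI_PER_KM_PRINTED = 0.625       # as printed in the source model
MI_PER_KM_STRICT = 1.0 / 1.609344


def bpr_speed(free_flow, volume, capacity, alpha, beta):
    """Mean travel speed (mph) from the BPR volume-delay function.

    S = S_FF / (1 + alpha * (V / C)**beta).  Monotone non-increasing in
    volume; equals the free-flow speed at zero volume.
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise ValueError("traffic volume must be non-negative")
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    s = free_flow / (1.0 + alpha * (volume / capacity) ** beta)
    if s.ndim == 0:
        return float(s)
    return s


def season_of(month: int) -> str:
    """Season label for a calendar month (Dec-Feb winter, Jun-Aug summer,
    the rest spring/fall)."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month out of range: {month}")
    m = int(month)
    if m in (12, 1, 2):
        return "winter"
    if m in (6, 7, 8):
        return "summer"
    return "springfall"


@dataclass
class EmissionFactorTable:
    """Pollutant x season x speed-bin x vehicle-class lookup, g/mi/vehicle.

    Backed by a long-format DataFrame with columns
    ``pollutant, season, class, speed_mph, g_per_mi``.  The grid must be
    complete for every (pollutant, season) pair present.
    """

    frame: pd.DataFrame
    _index: dict = field(default=None, repr=False)

    def __post_init__(self):
        required = {"pollutant", "season", "class", "speed_mph", "g_per_mi"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"emission-factor table missing columns: {sorted(missing)}")
        if (self.frame["g_per_mi"] < 0).any():
            raise ValueError("emission factors must be non-negative")
        self._index = {}
        for (pol, season), grp in self.frame.groupby(["pollutant", "season"]):
            pivot = grp.pivot_table(
                index="speed_mph", columns="class", values="g_per_mi"
            )
            want_bins = set(SPEED_BINS.tolist())
            if set(pivot.index) != want_bins or pivot.isna().any().any():
                raise ValueError(
                    f"incomplete speed-bin grid for {pol}/{season}: "
                    f"need bins {sorted(want_bins)}"
                )
            self._index[(pol, season)] = pivot.sort_index()

    @classmethod
    def from_csv(cls, path) -> "EmissionFactorTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def pollutants(self):
        return sorted({p for p, _ in self._index})

    def lookup(self, pollutant, season, vehicle_class, speed):
        """Factor (g/mi/vehicle) at the 5-mph bin nearest ``speed``.

        Ties (e.g. 52.5 mph) round up; speeds outside [5, 65] clamp to
        the end bins.
        """
        row = self.lookup_row(pollutant, season, speed)
        try:
            return float(row[vehicle_class])
        except KeyError:
            raise KeyError(f"unknown vehicle class {vehicle_class!r}") from None

    def lookup_row(self, pollutant, season, speed) -> pd.Series:
        """All class factors at the bin nearest ``speed``."""
        try:
            pivot = self._index[(pollutant, season)]
        except KeyError:
            raise KeyError(
                f"no emission factors for pollutant={pollutant!r}, season={season!r}"
            ) from None
        return pivot.loc[nearest_speed_bin(speed)]

    def factor_matrix(self, pollutant, season) -> pd.DataFrame:
        """Speed-bin x class factor matrix for one pollutant/season."""
        return self._index[(pollutant, season)]


def nearest_speed_bin(speed) -> int:
    """Nearest 5-mph bin in [5, 65]; half-bin ties round up, out-of-range
    speeds clamp to the end bins."""
    if speed <= 0:
        raise ValueError("speed must be positive")
    bin_ = int(np.floor(speed / 5.0 + 0.5)) * 5
    return int(min(max(bin_, 5), 65))


@dataclass
class DayTypeFactors:
    """Day-type adjustment tables.

    f1 : DataFrame indexed by hour (0-23) with one column per day type --
        the total-volume adjustment (weekdays identically 1).
    f3 : DataFrame indexed by hour with columns (day_type, duty) for
        duty in {"light", "heavy"} -- the class-volume ratio to weekday.
    mix : DataFrame indexed by hour with columns (road_type, class) --
        the weekday vehicle-mix fractions F2, summing to 1 per hour.
    """

    f1: pd.DataFrame
    f3: pd.DataFrame
    mix: pd.DataFrame

    def __post_init__(self):
        if (self.f1 < 0).any().any() or (self.f3 < 0).any().any():
            raise ValueError("day-type factors must be non-negative")
        if "weekday" in self.f1.columns and not np.allclose(self.f1["weekday"], 1.0):
            raise ValueError("weekday F1 must be identically 1")

    def f1_value(self, day_type, hour) -> float:
        if day_type == "weekday":
            return 1.0
        try:
            return float(self.f1.loc[hour, day_type])
        except KeyError:
            raise KeyError(f"no F1 entry for {day_type!r} hour {hour}") from None

    def f3_value(self, day_type, hour, vehicle_class) -> float:
        if day_type == "weekday":
            return 1.0
        duty = "heavy" if vehicle_class in HEAVY_CLASSES else "light"
        try:
            return float(self.f3.loc[hour, (day_type, duty)])
        except KeyError:
            raise KeyError(f"no F3 entry for {day_type!r}/{duty} hour {hour}") from None

    def mix_fractions(self, road_type, hour) -> pd.Series:
        try:
            frac = self.mix.loc[hour, road_type]
        except KeyError:
            raise KeyError(f"no mix fractions for {road_type!r} hour {hour}") from None
        if not np.isclose(frac.sum(), 1.0, atol=1e-6):
            raise ValueError(
                f"mix fractions for {road_type!r} hour {hour} sum to {frac.sum()}"
            )
        return frac


def adjust_total_volume(weekday_volume, day_type, hour, factors: DayTypeFactors):
    """Total hourly volume for a day type: V_D = V_WD * F1[day_type, hour]."""
    if weekday_volume < 0:
        raise ValueError("weekday volume must be non-negative")
    return weekday_volume * factors.f1_value(day_type, hour)


def class_volumes(total_volume, factors: DayTypeFactors, day_type, hour, road_type):
    """Apportion an (already day-type-adjusted) total volume into vehicle
    classes.

    Stage one forms unadjusted volumes V*_K = V * F2_K * F3_K; stage two
    rescales all classes by a common factor so they sum back to the
    total.  Returns a Series indexed by vehicle class.
    """
    f2 = factors.mix_fractions(road_type, hour)
    f3 = pd.Series(
        [factors.f3_value(day_type, hour, k) for k in f2.index], index=f2.index
    )
    unadjusted = total_volume * f2 * f3
    if total_volume == 0:
        return unadjusted  # all zero
    denom = unadjusted.sum()
    if denom == 0:
        raise ValueError("cannot apportion volume: all class weights are zero")
    return unadjusted * (total_volume / denom)


def fleet_rate_per_vehicle(mix_volumes, table: EmissionFactorTable,
                           speed, pollutant, season, strict_units=False):
    """Fleet-average emission rate E (g/km/vehicle) for given class
    volumes and speed."""
    mix_volumes = pd.Series(mix_volumes)
    total = mix_volumes.sum()
    if len(mix_volumes) == 0:
        raise ValueError("empty vehicle-class set")
    if total == 0:
        return 0.0
    factors = table.lookup_row(pollutant, season, speed)
    factors = factors.reindex(mix_volumes.index)
    if factors.isna().any():
        raise KeyError(
            f"classes missing from table: {list(factors.index[factors.isna()])}"
        )
    conv = MI_PER_KM_STRICT if strict_units else MI_PER_KM_PRINTED
    return conv * float((mix_volumes / total * factors).sum())


def segment_emission_rate(mix_volumes, table: EmissionFactorTable,
                          speed, pollutant, season, strict_units=False):
    """Segment emission rate Q (g/h/km): Q = 0.625 * sum_K V_K * q_K(S).

    Linear in total volume at fixed mix and speed bin.  Returns
    ``(Q, E)`` with E = Q/V the fleet-average per-vehicle rate
    (g/km/vehicle) consumed by the dispersion model (E = 0 when V = 0).
    """
    mix_volumes = pd.Series(mix_volumes)
    total = float(mix_volumes.sum())
    e = fleet_rate_per_vehicle(
        mix_volumes, table, speed, pollutant, season, strict_units=strict_units
    )
    return e * total, e
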