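"""Assemble hourly predictions over receptors and hours; aggregate and
summarise them; monitoring-campaign analytics.

Missing-value semantics run through everything here: calm hours are
``NaN`` (no Gaussian prediction is attempted), a daily mean exists only
when at least 12 of the 24 hours are available, and percentiles,
correlations and campaign errors are computed over the non-missing
support only.  Missing is never coerced to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dispersion, emissions, geometry
from .dispersion import DispersionParams, NOMINAL_VOLUME, CALM_SPEED_FLOOR

__all__ = [
    "ConcentrationSeries",
    "HourlyField",
    "FieldSummary",
    "predict_hourly",
    "daily_average",
    "select_extreme_days",
    "running_mean",
    "cross_receptor_correlation",
    "campaign_error",
    "factor_of_two_stats",
    "summarize_field",
]

log = logging.getLogger("nearroad")

MIN_HOURS_PER_DAY = 12      # daily completeness rule
MIN_CORR_OVERLAP = 10       # minimum pairwise-complete points for a correlation


@dataclass
class ConcentrationSeries:
    """Hourly concentrations at one receptor, with missing markers."""

    receptor_id: str
    pollutant: str
    units: str
    hourly: pd.Series  # DatetimeIndex (hour-beginning, local standard time)

    @property
    def daily(self) -> pd.Series:
        return daily_average(self.hourly)


@dataclass
class HourlyField:
    """Hourly concentrations for every receptor (columns) over a common
    hour index, plus bookkeeping from the prediction run."""

    values: pd.DataFrame
    pollutant: str
    units: str
    n_calm_hours: int = 0
    diagnostics: dict = field(default_factory=dict)

    def series(self, receptor_id) -> ConcentrationSeries:
        return ConcentrationSeries(
            receptor_id, self.pollutant, self.units, self.values[receptor_id]
        )

    def daily(self) -> pd.DataFrame:
        return self.values.apply(daily_average)

    def summarize(self) -> "FieldSummary":
        return summarize_field(self.daily())


def _day_types(index: pd.DatetimeIndex, holidays=()) -> np.ndarray:
    """weekday / saturday / sunday / holiday label per hour; holidays win."""
    holiday_set = {pd.Timestamp(h).date() for h in holidays}
    dow = index.dayofweek.to_numpy()
    out = np.where(dow == 5, "saturday", np.where(dow == 6, "sunday", "weekday"))
    if holiday_set:
        is_hol = np.array([d in holiday_set for d in index.date])
        out = np.where(is_hol, "holiday", out)
    return out


_DT_CODES = {d: i for i, d in enumerate(emissions.DAY_TYPES)}
_SEASON_CODES = {s: i for i, s in enumerate(emissions.SEASONS)}


def _road_hourly_inputs(road, met_index, weekday_profile, factors, ef_table,
                        pollutant, holidays, strict_units=False):
    """Per-hour traffic volume V, speed and fleet emission rate E for one
    road over the met index.  Returns (V, E) arrays."""
    hh = met_index.hour.to_numpy()
    dt_labels = _day_types(met_index, holidays)
    dt_codes = np.vectorize(_DT_CODES.__getitem__)(dt_labels)
    season_codes = np.array(
        [_SEASON_CODES[emissions.season_of(m)] for m in met_index.month]
    )

    prof = np.asarray(weekday_profile, dtype=float)
    if prof.shape != (24,):
        raise ValueError("weekday traffic profile must have 24 hourly values")

    # F1 lookup table (4 day types x 24 hours)
    f1_tab = np.ones((4, 24))
    for d in emissions.DAY_TYPES:
        for h in range(24):
            f1_tab[_DT_CODES[d], h] = factors.f1_value(d, h)
    volume = prof[hh] * f1_tab[dt_codes, hh]

    speed = emissions.bpr_speed(
        road.free_flow_speed, volume, road.capacity, road.bpr_alpha, road.bpr_beta
    )
    bins = np.clip(np.floor(np.maximum(speed, 1e-9) / 5.0 + 0.5).astype(int), 1, 13)

    # class shares per (day type, hour): normalised F2 * F3
    classes = list(emissions.VEHICLE_CLASSES)
    shares = np.zeros((4, 24, len(classes)))
    for d in emissions.DAY_TYPES:
        for h in range(24):
            cv = emissions.class_volumes(1.0, factors, d, h, road.road_type)
            shares[_DT_CODES[d], h, :] = cv.reindex(classes).to_numpy()

    # g/mi factors per (season, speed bin, class)
    q = np.zeros((3, 13, len(classes)))
    for s in emissions.SEASONS:
        mat = ef_table.factor_matrix(pollutant, s).reindex(columns=classes)
        q[_SEASON_CODES[s], :, :] = mat.to_numpy()

    conv = emissions.MI_PER_KM_STRICT if strict_units else emissions.MI_PER_KM_PRINTED
    fleet_q = np.einsum(
        "hk,hk->h", shares[dt_codes, hh, :], q[season_codes, bins - 1, :]
    )
    e_rate = conv * fleet_q  # g/km/vehicle
    return volume, e_rate


def predict_hourly(roads, receptors, met, traffic_profiles, factors, ef_table,
                   params: DispersionParams = None, pollutant="CO", units="ppm",
                   background=0.0, holidays=(), sector_interpolation=False,
                   x_policy="extrapolate", strict_units=False) -> HourlyField:
    """Predict hourly concentrations at every receptor.

    Parameters
    ----------
    roads : list of RoadSegment
    receptors : list of Receptor
    met : DataFrame with a DatetimeIndex (hourly, hour-beginning local
        standard time) and columns ``wind_dir_deg``, ``wind_speed_ms``,
        ``calm`` (truthy for calm hours).
    traffic_profiles : mapping road id -> 24 weekday hourly volumes (veh/h).
    factors : DayTypeFactors
    ef_table : EmissionFactorTable
    background : scalar added to every non-missing hour (same units as
        the output).

    Contributions from multiple roads superpose linearly per hour.  Calm
    hours (flag set or reported speed 0) are missing at every receptor;
    winds in (0, 0.5) m/s are clamped to 0.5 m/s.
    """
    params = params or dispersion.load_default_params()
    if units not in ("ppm", "ugm3"):
        raise ValueError("units must be 'ppm' or 'ugm3'")
    idx = met.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise ValueError("met must be indexed by hourly timestamps")
    full = pd.date_range(idx[0], idx[-1], freq="h")
    missing_hours = full.difference(idx)
    if len(missing_hours):
        raise ValueError(
            f"met series has {len(missing_hours)} missing hour(s), first: "
            f"{missing_hours[:5].tolist()}"
        )

    wdir = met["wind_dir_deg"].to_numpy(dtype=float)
    wspd = met["wind_speed_ms"].to_numpy(dtype=float)
    calm = met["calm"].to_numpy(dtype=bool) | (wspd <= 0.0)
    n_clamped_u = int(((wspd > 0) & (wspd < CALM_SPEED_FLOOR) & ~calm).sum())
    uspd = np.clip(wspd, CALM_SPEED_FLOOR, None)

    n_hours = len(idx)
    out = np.zeros((n_hours, len(receptors)))
    diagnostics = {
        "n_calm_hours": int(calm.sum()),
        "n_wind_clamped": n_clamped_u,
        "n_volume_clamped": 0,
        "n_x_clamped_near": 0,
        "n_x_beyond_fit": 0,
    }

    vlo, vhi = dispersion.V_RANGE
    xlo, xhi = dispersion.X_RANGE
    for road in roads:
        try:
            profile24 = traffic_profiles[road.id]
        except KeyError:
            raise KeyError(f"no traffic profile for road {road.id!r}") from None
        volume, e_rate = _road_hourly_inputs(
            road, idx, profile24, factors, ef_table, pollutant, holidays,
            strict_units=strict_units,
        )
        diagnostics["n_volume_clamped"] += int(
            ((volume < vlo) | (volume > vhi)).sum()
        )
        v_clamped = np.clip(volume, vlo, vhi)
        emission_scale = e_rate * (volume / NOMINAL_VOLUME)

        for j, rec in enumerate(receptors):
            x = geometry.perpendicular_distance(rec, road)
            if x < xlo:
                diagnostics["n_x_clamped_near"] += 1
            elif x > xhi:
                diagnostics["n_x_beyond_fit"] += 1
            iw = geometry.side_indicator(rec, road)
            theta = geometry.wind_angle(wdir, road.alignment, iw)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # clamp tallies logged below
                c = dispersion.concentration(
                    distance_x=x,
                    wind_speed_u=uspd,
                    wind_angle_theta=theta,
                    traffic_volume_v=v_clamped,
                    emission_rate_e=1.0,
                    params=params,
                    units="ppm",
                    sector_interpolation=sector_interpolation,
                    x_policy=x_policy,
                )
            # rescale: emission uses the TRUE volume, bracket the clamped one
            out[:, j] += c * emission_scale * (NOMINAL_VOLUME / v_clamped)

    if units == "ugm3":
        out *= params.ppm_to_ugm3
    out += background
    out[calm, :] = np.nan

    log.info(
        "predicted %d hours x %d receptors (%s, %s): %d calm hours, "
        "%d wind speeds clamped, %d volumes clamped, %d receptors nearer "
        "than %g m, %d beyond %g m",
        n_hours, len(receptors), pollutant, units, diagnostics["n_calm_hours"],
        n_clamped_u, diagnostics["n_volume_clamped"],
        diagnostics["n_x_clamped_near"], xlo, diagnostics["n_x_beyond_fit"], xhi,
    )
    frame = pd.DataFrame(out, index=idx, columns=[r.id for r in receptors])
    return HourlyField(frame, pollutant, units,
                       diagnostics["n_calm_hours"], diagnostics)


def daily_average(hourly: pd.Series) -> pd.Series:
    """24-hour means with the completeness rule: a day is reported only
    if at least 12 of its hourly values are non-missing."""
    grouped = hourly.groupby(hourly.index.floor("D"))
    means = grouped.mean()
    counts = grouped.count()
    return means.where(counts >= MIN_HOURS_PER_DAY)


def select_extreme_days(daily: pd.DataFrame):
    """(worst_day, best_day) by the daily concentration averaged across
    the modelled domain; ties break to the earliest date."""
    domain = daily.mean(axis=1, skipna=True)
    valid = domain.dropna()
    if valid.empty:
        raise ValueError("no day has a valid domain-mean concentration")
    worst = valid.index[np.argmax(valid.to_numpy())]
    best = valid.index[np.argmin(valid.to_numpy())]
    return worst, best


def running_mean(daily: pd.Series, window_days: int) -> pd.Series:
    """Trailing running mean over ``window_days`` days requiring at least
    half the window to be non-missing (window 1 returns the series)."""
    if window_days <= 1:
        return daily
    min_periods = int(np.ceil(window_days / 2))
    return daily.rolling(window_days, min_periods=min_periods).mean()


def cross_receptor_correlation(series_a: pd.Series, series_b: pd.Series,
                               window_days: int = 1) -> float:
    """Pearson correlation of (running-mean) daily series, pairwise
    complete.  Returns NaN when fewer than 10 days overlap."""
    a = running_mean(series_a, window_days)
    b = running_mean(series_b, window_days)
    paired = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(paired) < MIN_CORR_OVERLAP:
        log.warning(
            "cross-receptor correlation skipped: only %d overlapping days "
            "(need >= %d)", len(paired), MIN_CORR_OVERLAP,
        )
        return float("nan")
    if paired.iloc[:, 0].std() == 0 or paired.iloc[:, 1].std() == 0:
        return float("nan")
    return float(paired.iloc[:, 0].corr(paired.iloc[:, 1]))


def campaign_error(daily: pd.Series, campaign_weeks: int,
                   strategy: str = "single_period"):
    """Error of short monitoring campaigns against the annual mean.

    Enumerates every start day such that the campaign fits inside the
    series.  For each start the campaign estimate is the mean of the
    window (``single_period``) or the pooled mean of two equal windows
    offset by 26 weeks (``two_season``), and the error is
    ``|campaign mean - annual mean| / annual mean``.

    Returns a dict with the mean error and the (min, max) range, as
    fractions of the annual mean.
    """
    daily = daily.sort_index()
    if len(daily) < 365:
        raise ValueError("campaign analysis needs at least one full year of days")
    annual = daily.mean()
    if not np.isfinite(annual) or annual == 0:
        raise ValueError("annual mean is zero or undefined; error is undefined")
    ndays = 7 * int(campaign_weeks)
    vals = daily.to_numpy(dtype=float)
    n = len(vals)
    offset = 26 * 7
    errors = []
    if strategy == "single_period":
        last = n - ndays
    elif strategy == "two_season":
        last = n - ndays - offset
    else:
        raise ValueError("strategy must be 'single_period' or 'two_season'")
    if last < 0:
        raise ValueError("campaign does not fit in the series")
    for start in range(last + 1):
        window = vals[start:start + ndays]
        if strategy == "two_season":
            window = np.concatenate([window, vals[start + offset:start + offset + ndays]])
        est = np.nanmean(window) if np.isfinite(window).any() else np.nan
        if np.isfinite(est):
            errors.append(abs(est - annual) / abs(annual))
    if not errors:
        raise ValueError("no campaign window had any valid days")
    errors = np.array(errors)
    return {
        "mean_error": float(errors.mean()),
        "min_error": float(errors.min()),
        "max_error": float(errors.max()),
        "n_windows": int(len(errors)),
    }


def factor_of_two_stats(predicted: pd.Series, observed: pd.Series):
    """Evaluation statistics against paired observations.

    Returns (fraction of pairs with 0.5 <= pred/obs <= 2, Pearson r,
    relative mean bias (mean(pred) - mean(obs)) / mean(obs)).  Pairs with
    missing values or non-positive observations are dropped.
    """
    paired = pd.concat([predicted, observed], axis=1, join="inner").dropna()
    paired = paired[paired.iloc[:, 1] > 0]
    if paired.empty:
        raise ValueError("no valid prediction/observation pairs")
    ratio = paired.iloc[:, 0] / paired.iloc[:, 1]
    frac2 = float(((ratio >= 0.5) & (ratio <= 2.0)).mean())
    r = float(paired.iloc[:, 0].corr(paired.iloc[:, 1])) if len(paired) > 1 else float("nan")
    bias = float(
        (paired.iloc[:, 0].mean() - paired.iloc[:, 1].mean()) / paired.iloc[:, 1].mean()
    )
    return frac2, r, bias


@dataclass
class FieldSummary:
    """Per-receptor and domain-wide statistics of a daily field."""

    per_receptor: pd.DataFrame  # annual_mean, p98, max, n_days per receptor
    domain_mean: float
    domain_min: float
    domain_max: float
    worst_day: pd.Timestamp
    best_day: pd.Timestamp
    n_missing_days: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return self.per_receptor


def summarize_field(daily: pd.DataFrame) -> FieldSummary:
    """Summaries of a daily concentration field.

    Percentiles use linear interpolation between order statistics and are
    computed over non-missing days only (the number of excluded days per
    receptor is reported).  The 98th percentile of 24-h values is the
    statistic used for short-term standards.
    """
    annual = daily.mean(skipna=True)
    p98 = daily.quantile(0.98, interpolation="linear")
    mx = daily.max(skipna=True)
    n_days = daily.count()
    per = pd.DataFrame(
        {"annual_mean": annual, "p98_daily": p98, "max_daily": mx, "n_days": n_days}
    )
    worst, best = select_extreme_days(daily)
    n_missing = daily.isna().sum()
    log.info(
        "field summary: %d receptors, %d-%d valid days per receptor "
        "(missing days excluded from percentiles)",
        daily.shape[1], int(n_days.min()), int(n_days.max()),
    )
    return FieldSummary(
        per_receptor=per,
        domain_mean=float(annual.mean()),
        domain_min=float(annual.min()),
        domain_max=float(annual.max()),
        worst_day=worst,
        best_day=best,
        n_missing_days=n_missing,
    )
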