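"""Reduced-form line-source dispersion surrogate.

A multiplicative surrogate of a Gaussian line-source model (CALINE4-class)
with 13 fitted parameters and four meteorological/traffic inputs.  The
hourly concentration at a receptor distance X (m) from a straight road is

    C = E * (V / 10000) * B(V, X) * U**k8 * P(X; sector)        [ppm]

where

* ``E`` is the fleet-average emission rate, g/km/vehicle;
* ``V`` is the traffic volume, vehicles/h (the V/10000 factor scales the
  total segment emission rate relative to the 10,000 veh/h calibration
  condition);
* ``B`` is the volume-dispersion bracket
  ``k9 + (exp(k10*(V - k11)) - 1) * (1 - exp(k12*(X - k13)))``,
  the enhanced/diminished dilution from vehicle-induced turbulence
  relative to 10,000 veh/h (range 0.89-1.29 on the validity window);
* ``U**k8`` is the wind-speed power law, normalised so that
  ``k7 * U**k8 = 1`` near the 4 m/s calibration speed (k7 is folded into
  the starred table coefficients);
* ``P`` is the double-exponential distance profile
  ``k1* exp(-k3 (X - k2)) + k4* exp(-k6 (X - k5))`` whose six
  coefficients depend on the folded wind angle (10-degree sectors; the
  0-20 degree upwind sectors are identically zero).

Multiply by 1322 to express the output in micrograms per cubic metre.

Validity window: X in [15, 300] m, V in [1000, 15000] veh/h,
U >= 0.5 m/s (calm hours are recorded as missing, never zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import WindVector, sector_fold

__all__ = [
    "DispersionParams",
    "load_default_params",
    "distance_profile",
    "wind_speed_factor",
    "volume_dispersion_factor",
    "concentration",
    "apply_calm_policy",
    "CALM_SPEED_FLOOR",
    "NOMINAL_VOLUME",
    "X_RANGE",
    "V_RANGE",
]

CALM_SPEED_FLOOR = 0.5    # m/s
NOMINAL_VOLUME = 10000.0  # vehicles/h calibration condition
X_RANGE = (15.0, 300.0)   # m, fitted distance window
V_RANGE = (1000.0, 15000.0)  # vehicles/h, fitted volume window


class RangePolicyError(ValueError):
    pass


@dataclass
class DispersionParams:
    """Sector coefficient table (19 rows, folded angle 0-180 by 10) plus
    the global scalars k7-k13 and the ppm -> ug/m3 factor."""

    sector_table: pd.DataFrame
    k7: float = 2.81
    k8: float = -0.739
    k9: float = 0.99898
    k10: float = -0.000026515
    k11: float = 10749.0
    k12: float = -0.027061
    k13: float = 5.2826
    ppm_to_ugm3: float = 1322.0
    _cols: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        t = self.sector_table
        expected = ["k1_star", "k2", "k3", "k4_star", "k5", "k6"]
        if list(t.columns) != expected:
            raise ValueError(f"sector table columns must be {expected}")
        if not np.array_equal(t.index.to_numpy(), np.arange(0, 190, 10)):
            raise ValueError("sector table must have rows 0,10,...,180 degrees")
        if not (t.loc[[0, 10, 20]] == 0).all().all():
            raise ValueError("upwind sectors (0-20 deg) must be all-zero rows")
        if (t[["k1_star", "k3", "k4_star", "k6"]] < 0).any().any():
            raise ValueError("scale and decay coefficients must be non-negative")
        self._cols = t.to_numpy()

    @classmethod
    def from_files(cls, sector_csv, scalar_csv) -> "DispersionParams":
        table = pd.read_csv(sector_csv).set_index("angle_deg")
        scalars = pd.read_csv(scalar_csv).set_index("name")["value"]
        return cls(sector_table=table, **{k: float(scalars[k]) for k in scalars.index})

    def sector_index(self, folded_theta, interpolate=False):
        """Map folded angles to row indices (nearest 10-degree row, ties
        rounding up).  With ``interpolate`` returns (lower index, weight)."""
        t = np.asarray(folded_theta, dtype=float)
        if interpolate:
            lo = np.clip(np.floor(t / 10.0).astype(int), 0, 17)
            w = t / 10.0 - lo
            return lo, w
        return np.clip(np.floor(t / 10.0 + 0.5).astype(int), 0, 18)


def load_default_params() -> DispersionParams:
    """The packaged coefficient set (CO model, output in ppm)."""
    pkg = resources.files("nearroad.data")
    return DispersionParams.from_files(
        pkg / "sector_params.csv", pkg / "scalar_params.csv"
    )


def _clip_x(x, policy="clamp"):
    """Apply the distance range policy.  X below 15 m clamps to 15 m
    (the fit starts there); X above 300 m either extrapolates (default),
    clamps, or is masked missing per ``policy`` in
    {"clamp", "extrapolate", "missing"} for the far end."""
    x = np.asarray(x, dtype=float)
    lo, hi = X_RANGE
    below = x < lo
    above = x > hi
    if below.any():
        warnings.warn(
            f"{int(below.sum())} receptor distance(s) below {lo} m clamped to {lo} m",
            stacklevel=3,
        )
    out = np.where(below, lo, x)
    mask = np.zeros(out.shape, dtype=bool)
    if above.any():
        if policy == "missing":
            mask = above
        elif policy == "clamp":
            out = np.where(above, hi, out)
        elif policy == "extrapolate":
            warnings.warn(
                f"{int(above.sum())} receptor distance(s) beyond {hi} m "
                "extrapolate the fitted profile",
                stacklevel=3,
            )
        else:
            raise RangePolicyError(f"unknown x range policy {policy!r}")
    return out, mask


def distance_profile(x, sector_row, x_policy="extrapolate"):
    """Double-exponential concentration/distance profile for one sector.

    ``sector_row`` is a length-6 sequence (k1*, k2, k3, k4*, k5, k6).
    Returns ppm per unit emission rate at the calibration wind speed and
    volume; identically zero for the all-zero upwind rows.
    """
    k1, k2, k3, k4, k5, k6 = np.asarray(sector_row, dtype=float)
    x, mask = _clip_x(x, policy=x_policy)
    val = k1 * np.exp(-k3 * (x - k2)) + k4 * np.exp(-k6 * (x - k5))
    val = np.where(mask, np.nan, val)
    if val.ndim == 0:
        return float(val)
    return val


def wind_speed_factor(u, params: DispersionParams = None):
    """Wind-speed multiplier k7 * U**k8 relative to the 4 m/s nominal.

    Requires U >= 0.5 m/s; calm hours must be screened out upstream via
    :func:`apply_calm_policy`.
    """
    p = params or _DEFAULTS
    u = np.asarray(u, dtype=float)
    if np.any(u < CALM_SPEED_FLOOR):
        raise ValueError(
            f"wind speed below {CALM_SPEED_FLOOR} m/s reached the dispersion "
            "model; apply the calm policy first"
        )
    f = p.k7 * u ** p.k8
    if f.ndim == 0:
        return float(f)
    return f


def volume_dispersion_factor(v, x, params: DispersionParams = None,
                             x_policy="extrapolate", clamp_volume=True):
    """Bracketed volume/dispersion term of the traffic submodel.

    B(V, X) = k9 + (exp(k10*(V - k11)) - 1) * (1 - exp(k12*(X - k13))).

    Equals k9 at V = k11 for every X; spans [0.89, 1.29] (2 dp) over the
    fitted window.  Volumes outside [1000, 15000] veh/h clamp to the
    window edge (the bracket was only fitted there); independent of wind
    angle by construction.
    """
    p = params or _DEFAULTS
    v = np.asarray(v, dtype=float)
    lo, hi = V_RANGE
    if clamp_volume:
        out = (v < lo) | (v > hi)
        if out.any():
            warnings.warn(
                f"{int(out.sum())} traffic volume(s) outside [{lo:g}, {hi:g}] "
                "veh/h clamped for the dispersion bracket",
                stacklevel=2,
            )
        v = np.clip(v, lo, hi)
    x, mask = _clip_x(x, policy=x_policy)
    b = p.k9 + (np.exp(p.k10 * (v - p.k11)) - 1.0) * (1.0 - np.exp(p.k12 * (x - p.k13)))
    b = np.where(mask, np.nan, b)
    if b.ndim == 0:
        return float(b)
    return b


def apply_calm_policy(met: WindVector):
    """Screen an hour of wind for Gaussian-model usability.

    Calm flag or zero speed -> ``None`` (the hour is missing, never
    zero); speeds in (0, 0.5) m/s clamp to the 0.5 m/s floor; all other
    winds pass through unchanged.
    """
    if met.calm or met.speed == 0.0:
        return None
    if met.speed < CALM_SPEED_FLOOR:
        return WindVector(met.direction, CALM_SPEED_FLOOR, False)
    return met


def concentration(*, distance_x, wind_speed_u, wind_angle_theta,
                  traffic_volume_v, emission_rate_e,
                  params: DispersionParams = None, units="ppm",
                  sector_interpolation=False, x_policy="extrapolate"):
    """Composite hourly concentration at one receptor/road pair.

    Parameters are the four model inputs plus the fleet-average emission
    rate E (g/km/vehicle).  All arguments broadcast as numpy arrays.
    ``units`` is "ppm" or "ugm3" (the latter multiplies by 1322).
    Upwind sectors (folded angle <= 20 degrees) give exactly zero.
    Calm hours must be removed upstream; wind speeds below 0.5 m/s raise.
    """
    p = params or _DEFAULTS
    if units not in ("ppm", "ugm3"):
        raise ValueError("units must be 'ppm' or 'ugm3'")
    theta = sector_fold(wind_angle_theta)
    x = np.asarray(distance_x, dtype=float)
    v = np.asarray(traffic_volume_v, dtype=float)
    e = np.asarray(emission_rate_e, dtype=float)
    u_pow = wind_speed_factor(wind_speed_u, p) / p.k7  # plain U**k8
    bracket = volume_dispersion_factor(v, x, p, x_policy=x_policy)
    xc, mask = _clip_x(x, policy=x_policy)
    if sector_interpolation:
        lo, w = p.sector_index(theta, interpolate=True)
        prof_lo = _profile_rows(xc, p._cols[lo])
        prof_hi = _profile_rows(xc, p._cols[np.minimum(lo + 1, 18)])
        profile = (1.0 - w) * prof_lo + w * prof_hi
    else:
        idx = p.sector_index(theta)
        profile = _profile_rows(xc, p._cols[idx])
    c = e * (v / NOMINAL_VOLUME) * bracket * u_pow * profile
    c = np.where(mask, np.nan, c)
    if units == "ugm3":
        c = c * p.ppm_to_ugm3
    if c.ndim == 0:
        return float(c)
    return c


def _profile_rows(x, rows):
    """Vectorised double exponential where ``rows`` is (..., 6)."""
    rows = np.asarray(rows, dtype=float)
    k1, k2, k3 = rows[..., 0], rows[..., 1], rows[..., 2]
    k4, k5, k6 = rows[..., 3], rows[..., 4], rows[..., 5]
    return k1 * np.exp(-k3 * (x - k2)) + k4 * np.exp(-k6 * (x - k5))


_DEFAULTS = load_default_params()
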