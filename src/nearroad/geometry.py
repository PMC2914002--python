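"""Road/receptor coordinate conventions and wind-angle geometry.

Coordinates are planar projected metres (e.g. UTM); x is easting, y is
northing.  Angles are compass bearings in degrees (clockwise from north).
A straight road link is described by its alignment angle ``R`` in
[0, 180) measured from north, so ``R = 90`` is an east--west road.

The wind angle ``theta`` relates a receptor to the wind:

* ``theta = 0``   -- wind perpendicular to the road, receptor upwind;
* ``theta = 180`` -- wind perpendicular to the road, receptor downwind;
* ``theta = 90`` or ``270`` -- wind parallel to the road.

The dispersion coefficient table is indexed by the folded angle
``min(theta, 360 - theta)`` because the problem is mirror symmetric about
the road-normal plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoadSegment",
    "Receptor",
    "WindVector",
    "perpendicular_distance",
    "side_indicator",
    "wind_angle",
    "sector_fold",
]


class DegenerateRoadError(ValueError):
    """Raised when a road segment has coincident endpoints."""


def _alignment_from_endpoints(p1, p2) -> float:
    dx = p2[0] - p1[0]
    dy = p2[1] - p1[1]
    if dx == 0.0 and dy == 0.0:
        raise DegenerateRoadError("road endpoints coincide; alignment undefined")
    return math.degrees(math.atan2(dx, dy)) % 180.0


@dataclass
class RoadSegment:
    """One straight road link.

    Parameters
    ----------
    id : str
        Link identifier.
    endpoints : tuple of two (x, y) pairs, metres
        Projected planar coordinates of the segment ends.
    n_lanes : int
        Number of through lanes.
    free_flow_speed : float, mph
        Free-flow (posted/uncongested) speed.
    capacity_per_lane : float, vehicles/h/lane
        Hourly capacity of one lane (e.g. 2000 freeway, 825 arterial).
    bpr_alpha, bpr_beta : float
        Volume-delay coefficients of the BPR speed function.
    road_type : str
        "freeway" or "arterial"; selects the weekday vehicle-mix table.
    """

    id: str
    endpoints: tuple
    n_lanes: int
    free_flow_speed: float
    capacity_per_lane: float
    bpr_alpha: float
    bpr_beta: float
    road_type: str = "freeway"
    alignment: float = field(default=None)  # degrees in [0, 180); derived if None

    def __post_init__(self):
        p1, p2 = self.endpoints
        derived = _alignment_from_endpoints(p1, p2)
        if self.alignment is None:
            self.alignment = derived
        elif abs((self.alignment - derived + 90.0) % 180.0 - 90.0) > 1e-6:
            raise ValueError(
                f"road {self.id!r}: stated alignment {self.alignment} deg "
                f"does not match endpoints (derived {derived:.6f} deg)"
            )
        if not (0.0 <= self.alignment < 180.0):
            raise ValueError("alignment must lie in [0, 180)")
        if self.n_lanes <= 0 or self.free_flow_speed <= 0 or self.capacity_per_lane <= 0:
            raise ValueError("lanes, free-flow speed and capacity must be positive")

    @property
    def capacity(self) -> float:
        """Total segment capacity, vehicles/h."""
        return self.n_lanes * self.capacity_per_lane

    @property
    def north_unit(self) -> tuple:
        """Unit direction vector of the road pointing toward the
        larger-northing endpoint (larger easting for exact E-W roads)."""
        p1, p2 = self.endpoints
        dx, dy = p2[0] - p1[0], p2[1] - p1[1]
        if dy < 0 or (dy == 0 and dx < 0):
            dx, dy = -dx, -dy
        norm = math.hypot(dx, dy)
        return (dx / norm, dy / norm)


@dataclass
class Receptor:
    """A fixed point where concentrations are predicted."""

    id: str
    position: tuple  # (x, y) metres, projected


@dataclass
class WindVector:
    """One hour of wind: meteorological direction (blowing FROM, degrees),
    speed in m/s, and a calm flag.  Calm hours yield missing predictions,
    never zero."""

    direction: float
    speed: float
    calm: bool = False

    def __post_init__(self):
        self.direction = float(self.direction) % 360.0
        if self.speed < 0:
            raise ValueError("wind speed must be non-negative")


def perpendicular_distance(receptor: Receptor, road: RoadSegment) -> float:
    """Unsigned normal distance (m) from a receptor to the infinite road
    centreline.

    The road is modelled as an infinite straight line through its
    endpoints; receptors beyond the finite segment ends are still
    evaluated (the model represents a long straight element).
    """
    p1, p2 = road.endpoints
    dx, dy = p2[0] - p1[0], p2[1] - p1[1]
    norm = math.hypot(dx, dy)
    if norm == 0.0:
        raise DegenerateRoadError(f"road {road.id!r} has zero length")
    vx = receptor.position[0] - p1[0]
    vy = receptor.position[1] - p1[1]
    return abs(dx * vy - dy * vx) / norm


def side_indicator(receptor: Receptor, road: RoadSegment) -> int:
    """Side indicator I_W: 1 if the receptor lies west of the road,
    else 0.

    "West" is defined by the sign of the cross product of the road
    direction vector pointing toward the larger-northing endpoint (larger
    easting for exact east--west roads) with the road-to-receptor vector:
    positive cross product (receptor to the left when facing the
    north-pointing direction) means west.  Receptors exactly on the
    centreline get 0.
    """
    ux, uy = road.north_unit
    p1 = road.endpoints[0]
    vx = receptor.position[0] - p1[0]
    vy = receptor.position[1] - p1[1]
    cross = ux * vy - uy * vx
    return 1 if cross > 0 else 0


def wind_angle(wind_direction, road_alignment, side_iw) -> float:
    """Wind angle theta (degrees in [0, 360)) for a receptor.

    theta = MOD_360(W - R - 90 + 180*(I_W + I_R)) where W is the wind
    direction, R the road alignment, I_W the west-side indicator and
    I_R = 1 when R exceeds 90 degrees.  With this convention the
    receptor is downwind (theta = 180) exactly when the wind blows
    perpendicularly across the road toward it, for every alignment.

    Accepts scalars or numpy arrays for ``wind_direction``.
    """
    W = np.asarray(wind_direction, dtype=float)
    R = float(road_alignment)
    if not (0.0 <= R < 180.0):
        raise ValueError("road alignment must lie in [0, 180)")
    i_r = 1 if R > 90.0 else 0
    theta = np.mod(W - R - 90.0 + 180.0 * (int(side_iw) + i_r), 360.0)
    if theta.ndim == 0:
        return float(theta)
    return theta


def sector_fold(theta) -> float:
    """Fold a wind angle onto [0, 180]: min(theta, 360 - theta).

    The dispersion problem is mirror symmetric, e.g. 350 degrees is
    equivalent to 10 degrees, so the coefficient table only spans
    0-180 degrees.
    """
    t = np.mod(np.asarray(theta, dtype=float), 360.0)
    folded = np.minimum(t, 360.0 - t)
    if folded.ndim == 0:
        return float(folded)
    return folded
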