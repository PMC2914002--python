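"""CSV readers/writers for the model's input and output tables.

All tables are plain CSV.  Dialects:

* roads: ``id,x1_m,y1_m,x2_m,y2_m,lanes,sff_mph,cap_vphpl,alpha,beta[,road_type]``
* receptors: ``id,x_m,y_m``
* meteorology: ``timestamp,wind_dir_deg,wind_speed_ms,calm`` (hourly,
  hour-beginning local standard time; calm hours carry speed 0)
* weekday traffic: ``road_id,hour,total_vph``
* F1: ``day_type,hour,f1``;  F3: ``day_type,hour,duty,f3``
* vehicle mix: ``road_type,class,hour,fraction``
* emission factors: ``pollutant,season,class,speed_mph,g_per_mi``
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .emissions import DayTypeFactors, EmissionFactorTable
from .geometry import Receptor, RoadSegment

__all__ = [
    "read_roads", "read_receptors", "read_met", "read_traffic_profiles",
    "read_daytype_factors", "read_emission_factors",
    "write_met", "write_traffic_profiles", "write_daytype_factors",
    "write_emission_factors", "write_roads", "write_receptors",
]


def read_roads(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    roads = []
    for _, row in df.iterrows():
        roads.append(RoadSegment(
            id=str(row["id"]),
            endpoints=((row["x1_m"], row["y1_m"]), (row["x2_m"], row["y2_m"])),
            n_lanes=int(row["lanes"]),
            free_flow_speed=float(row["sff_mph"]),
            capacity_per_lane=float(row["cap_vphpl"]),
            bpr_alpha=float(row["alpha"]),
            bpr_beta=float(row["beta"]),
            road_type=str(row.get("road_type", "freeway")) if "road_type" in df.columns else "freeway",
        ))
    return roads


def write_roads(roads, path):
    pd.DataFrame([{
        "id": r.id,
        "x1_m": r.endpoints[0][0], "y1_m": r.endpoints[0][1],
        "x2_m": r.endpoints[1][0], "y2_m": r.endpoints[1][1],
        "lanes": r.n_lanes, "sff_mph": r.free_flow_speed,
        "cap_vphpl": r.capacity_per_lane, "alpha": r.bpr_alpha,
        "beta": r.bpr_beta, "road_type": r.road_type,
    } for r in roads]).to_csv(path, index=False)


def read_receptors(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    return [Receptor(str(r["id"]), (float(r["x_m"]), float(r["y_m"])))
            for _, r in df.iterrows()]


def write_receptors(receptors, path):
    pd.DataFrame([{"id": r.id, "x_m": r.position[0], "y_m": r.position[1]}
                  for r in receptors]).to_csv(path, index=False)


def read_met(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"], float_precision="round_trip").set_index("timestamp")
    required = {"wind_dir_deg", "wind_speed_ms", "calm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"met file missing columns: {sorted(missing)}")
    df["calm"] = df["calm"].astype(bool)
    return df


def write_met(met: pd.DataFrame, path):
    out = met.copy()
    out["calm"] = out["calm"].astype(int)
    out.index.name = "timestamp"
    out.to_csv(path)


def read_traffic_profiles(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    profiles = {}
    for rid, grp in df.groupby("road_id"):
        prof = grp.sort_values("hour").set_index("hour")["total_vph"]
        if list(prof.index) != list(range(24)):
            raise ValueError(f"traffic profile for road {rid!r} must cover hours 0-23")
        profiles[str(rid)] = prof.to_numpy(dtype=float)
    return profiles


def write_traffic_profiles(profiles: dict, path):
    rows = [{"road_id": rid, "hour": h, "total_vph": v}
            for rid, prof in profiles.items() for h, v in enumerate(prof)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_daytype_factors(f1_path, f3_path, mix_path) -> DayTypeFactors:
    f1_long = pd.read_csv(f1_path, float_precision="round_trip")
    f1 = f1_long.pivot(index="hour", columns="day_type", values="f1")
    if "weekday" not in f1.columns:
        f1["weekday"] = 1.0
    f3_long = pd.read_csv(f3_path, float_precision="round_trip")
    f3 = f3_long.pivot(index="hour", columns=["day_type", "duty"], values="f3")
    mix_long = pd.read_csv(mix_path, float_precision="round_trip")
    mix = mix_long.pivot(index="hour", columns=["road_type", "class"],
                         values="fraction")
    return DayTypeFactors(f1=f1, f3=f3, mix=mix)


def write_daytype_factors(factors: DayTypeFactors, f1_path, f3_path, mix_path):
    f1 = factors.f1.reset_index().melt(id_vars="index", var_name="day_type",
                                       value_name="f1")
    f1 = f1.rename(columns={"index": "hour"}).sort_values(["day_type", "hour"])
    f1.to_csv(f1_path, index=False)

    f3 = factors.f3.stack([0, 1], future_stack=True).rename("f3").reset_index()
    f3.columns = ["hour", "day_type", "duty", "f3"]
    f3.sort_values(["day_type", "duty", "hour"]).to_csv(f3_path, index=False)

    mix = factors.mix.stack([0, 1], future_stack=True).rename("fraction").reset_index()
    mix.columns = ["hour", "road_type", "class", "fraction"]
    mix.sort_values(["road_type", "class", "hour"]).to_csv(mix_path, index=False)


def read_emission_factors(path) -> EmissionFactorTable:
    return EmissionFactorTable.from_csv(path)


def write_emission_factors(table: EmissionFactorTable, path):
    table.frame.sort_values(
        ["pollutant", "season", "class", "speed_mph"]
    ).to_csv(path, index=False)
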