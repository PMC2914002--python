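import numpy as np
import pandas as pd
import pytest

from nearroad import (Receptor, RoadSegment, ScenarioConfig,
                      generate_scenario, load_default_params)


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def ns_road():
    """North-south 6-lane freeway through the origin (alignment 0)."""
    return RoadSegment("M39", ((0.0, -1000.0), (0.0, 1000.0)), 6, 60.0,
                       2000.0, 0.1226, 4.688, road_type="freeway")


@pytest.fixture(scope="session")
def scenario():
    """One full synthetic year under the default study conditions."""
    cfg = ScenarioConfig(seed=2025)
    met, profile, factors, table = generate_scenario(cfg)
    return cfg, met, profile, factors, table


def met_frame(wind_dir, wind_speed, calm, start="2006-01-01"):
    """Hand-built hourly met frame from equal-length arrays."""
    n = len(wind_dir)
    idx = pd.date_range(start, periods=n, freq="h")
    return pd.DataFrame(
        {"wind_dir_deg": np.asarray(wind_dir, dtype=float),
         "wind_speed_ms": np.asarray(wind_speed, dtype=float),
         "calm": np.asarray(calm, dtype=bool)},
        index=idx,
    )
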