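"""Shared fixtures: hand-built capture histories and small synthetic studies."""

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

from camsecr.datamodel import CameraTrap, CaptureHistory, DetectionRecord, Occasion
from camsecr import synthetic


def make_history(y, cams_xy, effort, sex=None, occasion_days=30):
    """Assemble a CaptureHistory from raw arrays (tests' workhorse)."""
    y = np.asarray(y, dtype=int)
    n, K, S = y.shape
    cams = [CameraTrap(f"c{k}", float(cams_xy[k][0]), float(cams_xy[k][1]),
                       grid_cell=f"0_{k}") for k in range(K)]
    from datetime import timedelta
    start = date(2020, 1, 1)
    occs = [
        Occasion(start + timedelta(days=s * occasion_days),
                 start + timedelta(days=(s + 1) * occasion_days))
        for s in range(S)
    ]
    ids = [f"i{i}" for i in range(n)]
    cov = pd.DataFrame(
        {"sex": sex if sex is not None else ["unknown"] * n,
         "group_hint": [""] * n},
        index=pd.Index(ids, name="individual_id"),
    )
    return CaptureHistory(ids, cams, occs, np.asarray(effort, float), y, cov)


def rec(ind, cam, ts, sex="female", age="adult", group=""):
    return DetectionRecord(individual_id=ind, camera_id=cam,
                           timestamp=ts if isinstance(ts, datetime)
                           else datetime.fromisoformat(ts),
                           sex=sex, age_class=age, group_hint=group)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced study (4x3 grid, 6 occasions) for fast end-to-end tests."""
    return synthetic.SimulationScenario(
        name="small", species_profile="fission_fusion", density=2.0,
        male_fraction=0.4, encounter_model="bernoulli",
        g0={"female": 0.08, "male": 0.08},
        sigma_m={"female": 500.0, "male": 500.0},
        grid_shape=(4, 3), n_occasions=6, occasion_days=30,
        id_success=0.9, co_trigger_prob=0.4, mean_unit_size=5.0,
        community_radius_m=400.0, downtime_blocks_per_camera=0.5,
    )


@pytest.fixture(scope="session")
def small_study(small_scenario):
    return synthetic.simulate_study(small_scenario, seed=42)
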