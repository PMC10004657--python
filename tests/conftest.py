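import logging

import numpy as np
import pytest

from ioh_ponv.features import CharacterizationSpec, compute_feature_table
from ioh_ponv.pipeline import preprocess_cohort
from ioh_ponv.preprocess import BPSeries, MapGrid
from ioh_ponv.simulate import SimulationConfig, simulate_cohort

logging.getLogger("ioh_ponv").setLevel(logging.ERROR)


def make_grid(values, case_id="g", step_s=15.0) -> MapGrid:
    return MapGrid(case_id=case_id, values=np.asarray(values, dtype=float), step_s=step_s)


def make_series(map_values, t=None, case_id="s", pulse_pressure=45.0) -> BPSeries:
    """Series with channels consistent with the given MAP values."""
    m = np.asarray(map_values, dtype=float)
    t = np.arange(len(m)) * 15.0 if t is None else np.asarray(t, dtype=float)
    return BPSeries(case_id=case_id, t=t, sbp=m + pulse_pressure * 2 / 3,
                    dbp=m - pulse_pressure / 3, map=m.copy())


def random_grids(n, rng, min_minutes=5, max_minutes=60):
    """Rough random MAP grids (random walk around 75 mmHg)."""
    grids = []
    for i in range(n):
        npts = rng.integers(int(min_minutes * 4) + 1, int(max_minutes * 4) + 2)
        steps = rng.normal(0, 3, size=npts)
        vals = np.clip(75 + np.cumsum(steps) - steps.mean() * np.arange(npts) / npts,
                       35, 120)
        grids.append(make_grid(vals, case_id=f"r{i}"))
    return grids


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient cohort under the default study conditions."""
    return simulate_cohort(SimulationConfig(n_patients=300, seed=42))


@pytest.fixture(scope="session")
def small_cohort_prepared(small_cohort):
    """Preprocessed small cohort: (cases, grids, exposure table for time_under_50)."""
    grids, _, _ = preprocess_cohort(small_cohort.series)
    cases = small_cohort.cases.loc[list(grids)]
    spec = CharacterizationSpec("time_under", 50)
    table = compute_feature_table(grids, [spec]).loc[cases.index]
    return cases, grids, table


@pytest.fixture(scope="session")
def calibration_cohort():
    """Larger cohort (~2000 cases) for calibration/recovery checks."""
    return simulate_cohort(SimulationConfig(n_patients=1500, seed=99))
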