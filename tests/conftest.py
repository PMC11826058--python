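"""Shared fixtures: toy wells and session-scoped simulated datasets."""

import numpy as np
import pytest

from exfrac.io import ConditionGroup, WellTimeSeries
from exfrac.simulate import SimConfig, simulate_culture, simulate_titration

TITRATION_CONCS = [0.0, 10.0, 20.0, 40.0, 80.0, 160.0]


def make_well(times, od, flu, well_id="A1", channel="gfp"):
    return WellTimeSeries(
        well_id=well_id,
        times=np.asarray(times, dtype=float),
        od600=np.asarray(od, dtype=float),
        fluorescence={channel: np.asarray(flu, dtype=float)},
    )


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(noise_od=0.0, noise_flu=0.0, n_replicates=2)


@pytest.fixture(scope="session")
def noiseless_culture(noiseless_config):
    """Noiseless wells + truth trajectory at saturating induction."""
    wells, truth = simulate_culture(noiseless_config, 160.0, return_truth=True)
    group = ConditionGroup("sim", "IPTG", 160.0, wells)
    return noiseless_config, group, truth


@pytest.fixture(scope="session")
def default_titration():
    """One titration at the generator's default noise levels."""
    cfg = SimConfig(seed=11)
    return cfg, simulate_titration(cfg, TITRATION_CONCS)


@pytest.fixture()
def tidy_files(tmp_path, default_titration):
    """Default titration written to tidy CSV + layout CSV."""
    _, titration = default_titration
    paths = titration.write(tmp_path / "sim")
    return paths
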