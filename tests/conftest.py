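import numpy as np
import pytest

import denstandard as ds
from denstandard import simulate as sim


@pytest.fixture(scope="session")
def grid_traps():
    """The reference 8x8 detector lattice at 1.5 km spacing."""
    return ds.place_traps(8, 8, 1.5)


@pytest.fixture(scope="session")
def survey_config(grid_traps):
    """Reference survey conditions: D=2/100 km², g0=0.05, sigma=2.5 km, K=90,
    state space extending 4 sigma beyond the trap hull."""
    margin = 4 * 2.5
    x0, y0, x1, y1 = grid_traps.extent()
    region = sim.Rectangle(x0 - margin, y0 - margin, x1 + margin, y1 + margin)
    return sim.SurveyConfig(
        region=region, true_density=2.0, g0=0.05, sigma_km=2.5,
        n_occasions=90, seed=20140501,
    )


@pytest.fixture(scope="session")
def simulated_survey(survey_config, grid_traps):
    """One realized survey under the reference conditions."""
    return sim.simulate_survey(survey_config, grid_traps, seed=7)


def make_history(traps, detections_spec, n_occasions):
    """Capture history from {individual: [(trap_index, occasion), ...]}."""
    inds = sorted(detections_spec)
    det = np.zeros((len(inds), traps.n_traps, n_occasions), dtype=np.uint8)
    for i, ind in enumerate(inds):
        for trap_idx, occ in detections_spec[ind]:
            det[i, trap_idx, occ] = 1
    return ds.CaptureHistory(inds, det, traps)


@pytest.fixture
def tiny_traps():
    return ds.TrapArray(["a", "b", "c", "d"], [[0, 0], [1.5, 0], [0, 1.5], [1.5, 1.5]])
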