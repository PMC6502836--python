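import numpy as np
import pytest

import fretscape as fs
from fretscape.presets import five_state_config, single_state_config

FIVE_STATE_TRUTH = np.array([0.93, 0.82, 0.70, 0.58, 0.39])


def simulate_efficiency_traces(config, n_molecules, seed,
                               background_d=2.0, background_a=2.0):
    """Simulate, QC-select and convert a dataset to efficiency traces."""
    traces = []
    for trace, _ in fs.simulate_dataset(config, n_molecules, seed=seed):
        report = fs.select_molecule(trace)
        if report.accepted:
            et = fs.efficiency_trace(trace, report,
                                     background_d=background_d,
                                     background_a=background_a)
            if et.n_bins >= 8:
                traces.append(et)
    return traces


@pytest.fixture(scope="session")
def five_state_traces():
    """66-molecule agonist-bound-like dataset: five states, 150 ms dwells."""
    return simulate_efficiency_traces(five_state_config(), 66, seed=7)


@pytest.fixture(scope="session")
def five_state_stasi(five_state_traces):
    return fs.stasi_fit(five_state_traces)


@pytest.fixture(scope="session")
def single_state_traces():
    """Apo-like dataset: one conformation at E = 0.89."""
    return simulate_efficiency_traces(single_state_config(0.89), 30, seed=11)
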