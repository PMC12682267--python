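import numpy as np
import pytest

from tsephys import synth
from tsephys.io import CellRecording, StimProtocol
from tsephys.synth import APTemplateParams, FICellParams, make_spike_train_sweep

STEP_ONSET_S = 0.1
STEP_OFFSET_S = 0.6


@pytest.fixture(scope="session")
def default_fi_cell():
    """One synthetic f-I cell at default (noisy) conditions."""
    return synth.generate_fi_cell(seed=11, cell_id="fix0")


@pytest.fixture(scope="session")
def noiseless_fi_cell():
    """One synthetic f-I cell with trace noise off (exact recovery)."""
    params = FICellParams(noise_sd_mV=0.0)
    return synth.generate_fi_cell(params, seed=5, cell_id="fix_clean")


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noise-free cohort for exact effect-recovery checks."""
    params = FICellParams(noise_sd_mV=0.0)
    cells, truths = [], []
    for s in range(5):
        c, t = synth.generate_fi_cell(params, seed=100 + s, cell_id=f"clean{s}")
        cells.append(c)
        truths.append(t)
    return cells, truths


def build_fi_cell(per_step_spikes, cell_id="manual", ra=10.0,
                  ap=APTemplateParams(), **cell_kwargs):
    """Cell from explicit spike times: per_step_spikes[i] = (no_light, light)
    lists of peak times in seconds from sweep start."""
    sweeps = []
    for i, (nl_times, lt_times) in enumerate(per_step_spikes):
        amp = 50.0 * (i + 1)
        for code, (cond, times) in enumerate((("no_light", nl_times), ("light", lt_times))):
            sweeps.append(make_spike_train_sweep(
                times, ap,
                step_amplitude_pA=amp,
                step_onset_s=STEP_ONSET_S, step_offset_s=STEP_OFFSET_S,
                cell_id=cell_id, sweep_index=2 * i + code, condition=cond,
                protocol=(StimProtocol("single_pulse", STEP_ONSET_S, 500.0, 1)
                          if cond == "light" else StimProtocol()),
            ))
    return CellRecording(cell_id=cell_id, access_resistance_MOhm=ra,
                         sweeps=sweeps, **cell_kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
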