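"""Shared fixtures: small seeded colonies and hand-built lineage tables."""

import numpy as np
import pytest

from raginfer import CellRecord, LineageTable, SimConfig, simulate_colony


def make_cell(cell_id, lb, ld, T, parent_id=None, birth_time=0.0, dt=3.0,
              law="linear", alpha=None, divided=True):
    """A single cell trajectory built from a closed-form growth law."""
    k = int(np.floor(T / dt - 1e-9))
    times = np.arange(k + 1) * dt
    if T > times[-1] + 1e-9:
        times = np.append(times, T)
    if law == "linear":
        lengths = lb + (ld - lb) * times / T
    elif law == "exponential":
        a = alpha if alpha is not None else np.log(ld / lb) / T
        lengths = lb * np.exp(a * times)
    else:
        raise ValueError(law)
    return CellRecord(cell_id=cell_id, parent_id=parent_id, times=times,
                      lengths=lengths, birth_time=birth_time, divided=divided)


@pytest.fixture(scope="session")
def exp_colony_clean():
    """Noise-free exponential colony (rate ln2/50 per min)."""
    cfg = SimConfig(growth_mode="exponential", n_cells=400,
                    meas_noise_sd=0.0, seed=11)
    return simulate_colony(cfg, seed=11), cfg


@pytest.fixture(scope="session")
def exp_colony_noisy():
    cfg = SimConfig(growth_mode="exponential", n_cells=500,
                    meas_noise_sd=0.05, seed=12)
    return simulate_colony(cfg, seed=12), cfg


@pytest.fixture(scope="session")
def linear_colony_clean():
    cfg = SimConfig(growth_mode="linear", n_cells=400,
                    meas_noise_sd=0.0, seed=13)
    return simulate_colony(cfg, seed=13), cfg


@pytest.fixture(scope="session")
def rag_colony_clean():
    cfg = SimConfig(growth_mode="rag", n_cells=400,
                    meas_noise_sd=0.0, seed=14)
    return simulate_colony(cfg, seed=14), cfg
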