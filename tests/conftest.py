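import numpy as np
import pytest

from gliacap.models import (SimulationConfig, build_signal_grid,
                            load_model_spec, simulate_ensemble)


@pytest.fixture(scope="session")
def cle_spec():
    return load_model_spec("CLE")


@pytest.fixture(scope="session")
def cle_small_grid(cle_spec):
    """16 CLE ensembles at desk scale (60 cells, coarse step)."""
    ensembles = []
    for i, sig in enumerate(build_signal_grid("CLE")):
        cfg = SimulationConfig(n_cells=60, dt=0.05, save_stride=4, seed=500 + i)
        ensembles.append(simulate_ensemble(cle_spec, sig, cfg))
    return ensembles


@pytest.fixture(scope="session")
def toy_ensembles():
    from gliacap.fixtures import make_trajectory_toy
    return make_trajectory_toy(S=4, n_per_signal=80, T=49,
                               spike_indices=(10, 30), seed=7)
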