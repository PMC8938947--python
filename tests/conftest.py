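import numpy as np
import pytest

from fpmat.kinetics import AbundanceParams
from fpmat.synth import default_cell_cycle, generate_dataset, preset_params
from fpmat.volume import CellCycleDistribution, simulate_volume

LN2 = np.log(2.0)


@pytest.fixture(scope="session")
def degenerate_dist():
    """Point-mass cycle law (T=80 min, mu=0.2 fL/min, Vd=12 fL, V0=30 fL)."""
    return CellCycleDistribution.degenerate(80.0, 0.2, 12.0, 30.0)


@pytest.fixture(scope="session")
def realistic_dist():
    return default_cell_cycle()


@pytest.fixture(scope="session")
def onestep_params():
    return AbundanceParams(kind="one_step", k_r=1.0, k_dr=0.1, k_p=1.0,
                           k_m=0.1, tau1=2.0, tau2=4.0)


@pytest.fixture(scope="session")
def t5min():
    """The 5-min sampling grid up to 200 min post-induction."""
    return np.arange(0.0, 201.0, 5.0)


@pytest.fixture(scope="session")
def vol_degenerate(degenerate_dist):
    """Deterministic trajectory: divisions at 80 and 160 min, phase 0."""
    return simulate_volume(degenerate_dist, 200.0, dt=1.0, rng=0, phase=0.0)


@pytest.fixture(scope="session")
def sfgfp_small_ds():
    """Small noisy sfGFP-like dataset shared by inference tests."""
    return generate_dataset(preset_params("sfgfp"), n_cells=20, seed=42,
                            dt=0.2)


@pytest.fixture(scope="session")
def mvenus_small_ds():
    return generate_dataset(preset_params("mvenus"), n_cells=20, seed=43,
                            dt=0.2)
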