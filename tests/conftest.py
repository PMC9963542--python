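import numpy as np
import pytest

from acoustolbm.units import build_unit_system


@pytest.fixture(scope="session")
def table1_units():
    """Unit ledger built from the channel/fluid mapping of the study:
    160 um channel on 80 nodes, water at 1027 kg/m^3 (lattice 1),
    nu 1e-6 m^2/s (lattice 0.0167)."""
    return build_unit_system(160e-6, 80, 1027.0, 1.0, 1e-6, 0.0167)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
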