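import numpy as np
import pytest

from elfxs.models import make_jellium, make_toy_water
from elfxs.surfaces import DrudePeakSet, make_drude_elf

RS = 2.0
JELLIUM_DENSITY = 3.0 / (4.0 * np.pi * RS**3)


@pytest.fixture(scope="session")
def toy_water():
    return make_toy_water()


@pytest.fixture(scope="session")
def jellium_small():
    """Coarse-mesh jellium for full-matrix response tests."""
    return make_jellium(JELLIUM_DENSITY, kmesh=(4, 4, 4), n_bands=10)


@pytest.fixture(scope="session")
def jellium_fine():
    """12^3-mesh jellium for Lindhard-limit and plasmon checks."""
    return make_jellium(JELLIUM_DENSITY, kmesh=(12, 12, 12), n_bands=15)


@pytest.fixture(scope="session")
def water_drude():
    """Water-like single-peak Drude Bethe surface with quadratic dispersion."""
    from elfxs.constants import HARTREE_EV
    from elfxs.models import WATER_MOLECULAR_VOLUME_BOHR3

    n_val = 8.0 / WATER_MOLECULAR_VOLUME_BOHR3
    wp2 = 4.0 * np.pi * n_val * HARTREE_EV**2
    peaks = DrudePeakSet([(21.0, 10.0, wp2)], dispersion_mode="quadratic")
    e = np.arange(0.5, 2000.0, 0.5)
    q = np.geomspace(0.05, 13.0, 60)
    return make_drude_elf(peaks, e, q)
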