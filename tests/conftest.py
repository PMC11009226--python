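"""Shared fixtures: noise-free synthetic inputs at the room-temperature
study conditions, reused across the module test files."""

import numpy as np
import pytest

from chex2dir import (ExchangeGenParams, FTIRGenParams, SpectralWindow,
                      simulate_2dir_series, simulate_ftir)

# printed room-temperature study conditions
AREA_RATIO_23C = 2.260          # A_SHB : A_WHB at 23 degC
MU_SHB, MU_WHB = 0.344, 0.321   # Debye
DH_KJMOL, DS_JMOLK = 6.22, 15.34
TAU_FORWARD_23C = 0.53          # ps
SPLIT_CM1 = 13.1                # cm^-1

# forward time constants (ps) and temperatures (degC) of the kinetics set
KINETIC_TEMPS_C = (23.0, 50.0, 60.0, 85.0)
TAU_FORWARD_PS = (0.53, 0.33, 0.28, 0.21)
DG_KJMOL = (1.68, 1.27, 1.11, 0.73)


@pytest.fixture(scope="session")
def ftir_params_23():
    """Generator parameters pinned to the 2.260 area ratio at 23 degC."""
    return FTIRGenParams().with_room_temperature_ratio(AREA_RATIO_23C)


@pytest.fixture(scope="session")
def spectrum_23(ftir_params_23):
    """Noise-free two-component spectrum at 23 degC."""
    return simulate_ftir(ftir_params_23, [23.0])[0]


@pytest.fixture(scope="session")
def exchange_series_23():
    """Phenomenological exchange series at the 23 degC conditions."""
    series = simulate_2dir_series(ExchangeGenParams())
    series.temperature = 23.0
    return series


@pytest.fixture(scope="session")
def norm_window():
    """Diagonal 1->2 window of the low-frequency component."""
    return SpectralWindow(1605.0, 1610.0, 1592.0, 1597.0)


@pytest.fixture(scope="session")
def cross_window():
    """5x5 cm^-1 window at (pump = SHB 0->1, probe = WHB 0->1)."""
    return SpectralWindow.centered(1607.8, 1620.9, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
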