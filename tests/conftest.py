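"""Shared fixtures: reference process conditions and session-scoped runs."""

import numpy as np
import pytest

from batchcryst import (
    PENCHEV,
    TAI_SHEI,
    ProcessSchedule,
    SolubilityPolynomial,
    SolutionBasis,
    TempConvention,
    build_grid,
    simulate_batch,
)

#: reference initial mole fraction (43 g LGA / 1000 g water)
X0 = 0.0052374


@pytest.fixture(scope="session")
def solub():
    """Solubility polynomial under the default absolute-temperature convention."""
    return SolubilityPolynomial()


@pytest.fixture(scope="session")
def solub_celsius():
    return SolubilityPolynomial(temp_convention=TempConvention.CELSIUS_AS_PRINTED)


@pytest.fixture(scope="session")
def grid40():
    """40 geometric bins spanning 1-1000 um."""
    return build_grid(1e-6, 1000e-6, 40)


@pytest.fixture(scope="session")
def basis():
    return SolutionBasis.from_loading(43.0)


@pytest.fixture(scope="session")
def schedule():
    """Linear cooling 70 -> 20 degC at 0.6 K/min."""
    return ProcessSchedule(T0=70.0, T_final=20.0, cooling_rate=0.6)


@pytest.fixture(scope="session")
def reference_run(schedule, grid40, solub, basis):
    """Crystal-free reference batch: full cooling ramp, Tai-Shei kinetics."""
    return simulate_batch(schedule, TAI_SHEI, grid40, solub, basis)


@pytest.fixture(scope="session")
def reference_run_hold45(grid40, solub, basis, schedule):
    """Same start, but the ramp ends at 45 degC and the batch holds there."""
    hold = ProcessSchedule(T0=70.0, T_final=45.0, cooling_rate=0.6)
    return simulate_batch(
        hold, TAI_SHEI, grid40, solub, basis, duration=schedule.ramp_duration
    )


@pytest.fixture(scope="session")
def penchev_run(schedule, grid40, solub, basis):
    """Reference conditions with the slow-cooling growth kinetics."""
    return simulate_batch(schedule, PENCHEV, grid40, solub, basis)
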