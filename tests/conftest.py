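"""Shared fixtures.

The expensive converged simulations (baseline with homeostasis, the
scenario suite with ventricular indices, the Fmax sweep) are session
scoped so every test file reuses one set of runs.
"""

import pytest

from rvsim.circulation import default_model
from rvsim.experiments import fmax_sweep, run_scenario_suite
from rvsim.sarcomere import SarcomereParams
from rvsim.simulator import homeostasis_adjust


@pytest.fixture(scope="session")
def sarc_params() -> SarcomereParams:
    return SarcomereParams()


@pytest.fixture(scope="session")
def baseline():
    """Homeostasis-adjusted baseline model with its converged run."""
    model, run = homeostasis_adjust(default_model())
    return model, run


@pytest.fixture(scope="session")
def suite():
    """All six study arms with ventricular indices and fold changes."""
    return run_scenario_suite(with_indices=True)


@pytest.fixture(scope="session")
def sweep():
    """Five-point Fmax sweep at baseline afterload."""
    return fmax_sweep(5)
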