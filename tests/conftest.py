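import numpy as np
import pytest

from rtdecay import UnitCell, calibrate
from rtdecay.decay_fit import DecayParameters
from rtdecay.radial_curve import generic_protein_curve
from rtdecay.reference import calibration_rows, load_reference_parameters
from rtdecay.synthetic_data import SimulationConfig, generate_series


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_parameters()


@pytest.fixture(scope="session")
def calibrated_curve():
    """Effective-Gaussian curve calibrated on the eight calibration rows."""
    return calibrate(calibration_rows(), family="effective_gaussian").curve


@pytest.fixture(scope="session")
def sim_curve():
    return generic_protein_curve()


@pytest.fixture
def cubic_cell():
    return UnitCell(79, 79, 79)


@pytest.fixture
def make_series(cubic_cell, sim_curve):
    """Factory for small synthetic series with configurable truth/seed."""

    def _make(beta=15.0, gamma=1.0, b0=20.0, seed=0, n_reflections=2000, **kw):
        config = SimulationConfig(
            cell=kw.pop("cell", cubic_cell),
            curve=kw.pop("curve", sim_curve),
            truth=DecayParameters(B0=b0, beta=beta, C=1.0, gamma=gamma),
            d_min=kw.pop("d_min", 2.0),
            seed=seed,
            n_reflections_per_wedge=n_reflections,
            **kw,
        )
        return generate_series(config)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20120)
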