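import numpy as np
import pytest

from pmgf.decay import DecayCoefficients
from pmgf.records import FieldDesign
from pmgf.simulate import GeneratorTruth, generate_screening
from pmgf.specs import ModelSpec


@pytest.fixture(scope="session")
def simple_coefficients():
    """Scalar double-exponential kernel (no factor structure), one year."""
    return DecayCoefficients(
        spec=ModelSpec(2, "1", "1"),
        names=("beta0", "beta1", "gamma1", "beta2", "gamma2"),
        values=np.array([-3.5, 0.26, -5.35, 1.59, -0.03]),
        year_levels=(2014,),
    )


@pytest.fixture(scope="session")
def small_design():
    """Reduced station layout for fast fitting tests."""
    return FieldDesign(cardinal_distances_m=(0.5, 1, 2, 4, 10, 20, 35),
                       ordinal_extra_m=())


@pytest.fixture(scope="session")
def small_records(simple_coefficients, small_design):
    """One-year synthetic screening counts from the scalar kernel."""
    truth = GeneratorTruth(coefficients=simple_coefficients,
                           design=small_design, n_per_cell=1000, seed=7)
    return generate_screening(truth)
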