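import numpy as np
import pytest

from chondronmr.glycan import ChainBuilder
from chondronmr.noe import build_restraint_set, fit_calibration
from chondronmr.synthetic import (
    SyntheticNoesyConfig,
    reference_torsion_fixture,
    simulate_noesy,
)


@pytest.fixture(scope="session")
def cn6_builder():
    return ChainBuilder(6)


@pytest.fixture(scope="session")
def cn6_fixture(cn6_builder):
    """Pseudo-deposited CN6 model at the ensemble-average torsions."""
    return reference_torsion_fixture(cn6_builder)


@pytest.fixture(scope="session")
def noiseless_peaks(cn6_fixture):
    return simulate_noesy(
        cn6_fixture, SyntheticNoesyConfig(k_true=500.0, overlap_grouping=True)
    )


@pytest.fixture(scope="session")
def calibration(noiseless_peaks):
    refs = [
        (p.intensity, p.known_distance)
        for p in noiseless_peaks
        if p.role == "reference"
    ]
    return fit_calibration(refs)


@pytest.fixture(scope="session")
def cn6_restraints(noiseless_peaks, calibration):
    return build_restraint_set(noiseless_peaks, calibration)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
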