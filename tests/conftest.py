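import numpy as np
import pytest

import marrowdose as md


@pytest.fixture(scope="session")
def decay_data():
    return md.lu177_decay()


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default tumor-free desk phantom, noise-free."""
    return md.build_phantom(md.default_phantom_spec(seed=1))


@pytest.fixture(scope="session")
def phantom_density(phantom_bundle):
    return md.hu_to_density(phantom_bundle.ct_hu, phantom_bundle.calibration)


TINY_GRID = dict(energies_kev=np.array([10.0, 300.0, 2500.0]),
                 bvfs=np.array([0.03, 0.35]),
                 cfs=np.array([0.01, 0.99]))


@pytest.fixture(scope="session")
def tiny_eaf3():
    """Small 3-compartment table for fast engine tests."""
    return md.build_eaf_table(TINY_GRID, 300, seed=101, compartments=3)


@pytest.fixture(scope="session")
def tiny_eaf4():
    return md.build_eaf_table(TINY_GRID, 300, seed=102, compartments=4)
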