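import numpy as np
import pytest

from lungmorph import allometry, phantomgen


@pytest.fixture(scope="session")
def table1_records():
    return allometry.load_table1()


@pytest.fixture(scope="session")
def neonate_phantom():
    """One neonate phantom shared by segmentation/stereology tests."""
    spec = phantomgen.PhantomSpec.for_stage("neonate", rng_seed=11)
    return phantomgen.generate_stage_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced two-lobe phantom for fast unit tests."""
    spec = phantomgen.PhantomSpec(
        stage_label="neonate",
        sac_diameter_target=200.0,
        septum_thickness_target=30.0,
        subdivision_rounds=0,
        spacing=10.0,
        n_lobes=2,
        noise_sd=0.0,
        blur_sigma=0.0,
        rng_seed=5,
    )
    return phantomgen.generate_stage_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
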