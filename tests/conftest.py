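import numpy as np
import pytest

from gmnet.synthetic import CohortDesign


@pytest.fixture(scope="session")
def region_table():
    from gmnet.regions import aal90_table

    return aal90_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231359)


def small_design(**overrides) -> CohortDesign:
    """A fast-to-generate design for unit tests (not the study defaults)."""
    base = dict(
        group_sizes={"CSVD-c": 4, "CSVD-n": 4, "control": 4},
        voxels_per_region=(60, 120),
        seed=7,
    )
    base.update(overrides)
    return CohortDesign(**base)


@pytest.fixture()
def tiny_cohort():
    from gmnet.synthetic import generate_cohort

    return generate_cohort(small_design())
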