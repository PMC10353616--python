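import numpy as np
import pytest

from dalff.datatypes import BoldRun
from dalff.synthetic import CohortConfig, RoiSphere, generate_cohort


def small_cohort_config(seed=0, **overrides):
    """A fast desk-scale cohort: 14x16x12 grid, T=80, 5+5 subjects."""
    defaults = dict(
        n_patients=5,
        n_controls=5,
        grid_shape=(14, 16, 12),
        n_timepoints=80,
        effect_rois=[RoiSphere(center_voxel=(9, 10, 6), radius_mm=7.0, label="rectus_r")],
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_cohort_config(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_run(rng):
    data = rng.normal(size=(5, 6, 4, 30))
    return BoldRun(data=data, tr_s=2.0)
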