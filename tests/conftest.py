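import numpy as np
import pytest

from phenosalt.fce import TraitMatrix
from phenosalt.fixtures import (
    CanopySpec,
    CohortSpec,
    SceneSpec,
    make_canopy,
    make_cohort,
    make_scene,
)


@pytest.fixture(scope="session")
def default_scene():
    return make_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def stressed_scene():
    return make_scene(SceneSpec(stress=1.0, seed=1))


@pytest.fixture(scope="session")
def box_canopy():
    spec = CanopySpec(shape="box", dimensions=(20.0, 20.0, 15.0), point_density=9.0, seed=3)
    return make_canopy(spec)


@pytest.fixture(scope="session")
def labelled_outlier_canopy():
    """~1000 surface points plus 10 planted outliers."""
    spec = CanopySpec(
        shape="box",
        dimensions=(9.0, 9.0, 7.0),
        point_density=2.0,
        outlier_count=10,
        seed=11,
    )
    return make_canopy(spec)


@pytest.fixture(scope="session")
def cohort():
    return make_cohort(CohortSpec(n_samples=12, m_traits=19, noise_sd=0.3, seed=4))


@pytest.fixture()
def small_matrix():
    return TraitMatrix(
        sample_ids=["a", "b", "c", "d"],
        trait_names=["t1", "t2", "t3"],
        values=np.array(
            [
                [1.0, 9.0, 0.2],
                [2.0, 7.0, 0.4],
                [3.0, 5.0, 0.6],
                [4.0, 1.0, 0.9],
            ]
        ),
        polarity=["positive", "negative", "positive"],
    )
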