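import numpy as np
import pytest

from scamflux import ConditionSpec, MechanismParams, ScenePlan
from scamflux.simulate import NOISE_FREE, build_scene, render_stack


@pytest.fixture(scope="session")
def mech():
    return MechanismParams()


@pytest.fixture(scope="session")
def small_plan():
    """A compact field with five comfortably separated cells."""
    return ScenePlan(image_width=192, image_height=192, n_cells=5, rng_seed=7)


@pytest.fixture(scope="session")
def small_scene(small_plan):
    return build_scene(small_plan)


@pytest.fixture(scope="session")
def default_scene():
    """Default 30-cell field used for segmentation/quantification checks."""
    return build_scene(ScenePlan(rng_seed=11))


@pytest.fixture(scope="session")
def app_condition():
    return ConditionSpec(substrate="APP+", substrate_conc_uM=2.0)


@pytest.fixture(scope="session")
def noise_free_app_stack(default_scene, app_condition, mech):
    stack, cell_truth, cond_truth = render_stack(
        default_scene, app_condition, mech, noise=NOISE_FREE, seed=0
    )
    return stack, cell_truth, cond_truth
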