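import numpy as np
import pytest

from surgskill import synthdata


@pytest.fixture(scope="session")
def default_rule():
    return synthdata.default_score_rule()


@pytest.fixture(scope="session")
def trajectory_cases(default_rule):
    """700 labeled synthetic cases under the default trajectory spec
    (600 train / 100 held-out in the recovery tests)."""
    base = synthdata.TrajectorySpec()
    return [
        synthdata.generate_trajectory_case(
            base.with_seed(i), default_rule, surgery_id=f"surgery_{i:04d}")
        for i in range(700)
    ]


@pytest.fixture(scope="session")
def scene_pair():
    return synthdata.generate_scene(synthdata.SceneSpec(seed=3))
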