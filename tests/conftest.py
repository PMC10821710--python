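import numpy as np
import pytest

from im2im.synthdata import FixtureSpec, make_task_pairs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def labelfree_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("labelfree2d")
    spec = FixtureSpec(task="labelfree", dim=2, n_images=10, seed=123)
    make_task_pairs(spec, root)
    return root


@pytest.fixture(scope="session")
def instance_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("instance2d")
    spec = FixtureSpec(task="instance", dim=2, n_images=10, seed=7, n_objects=(2, 2))
    make_task_pairs(spec, root)
    return root
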