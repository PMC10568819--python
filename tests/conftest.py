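import numpy as np
import pytest

from famdelay.anthropometrics import make_synthetic_reference
from famdelay.task_engine import TaskConfig


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def lms_table():
    return make_synthetic_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
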