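import numpy as np
import pytest
from hypothesis import settings

import suncompass as sc

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def render_spec():
    return sc.RenderSpec()


@pytest.fixture(scope="session")
def kernel(render_spec):
    return sc.build_kernel((14.0, 6.0), 7.0, 16.0, render_spec.image_size)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
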