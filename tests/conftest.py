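import numpy as np
import pytest

from perfudim.phantom import PhantomConfig, generate_vascular_tree, render_scan_pair


@pytest.fixture(scope="session")
def small_phantom_config():
    return PhantomConfig(grid_shape=(24, 24, 24), n_branches=7, noise_sd=0.0,
                         rng_seed=9)


@pytest.fixture(scope="session")
def small_phantom_pair(small_phantom_config):
    tree, _ = generate_vascular_tree(small_phantom_config)
    return render_scan_pair(tree, small_phantom_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
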