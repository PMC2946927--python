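import numpy as np
import pytest

import spikecascade as sc


@pytest.fixture(scope="session")
def cascade_16k():
    """Depth-14 log-normal cascade ISI series, the recovery workhorse."""
    return sc.gen_cascade_isi(
        sc.CascadeParams(depth=14, level_var=0.05), 2 ** 14, seed=2014
    )


@pytest.fixture(scope="session")
def poisson_isi_100k():
    """Unit-rate Poisson ISI series, the memoryless baseline."""
    return sc.to_isi(sc.gen_poisson(1.0, 10 ** 5, seed=77))


@pytest.fixture
def simple_train():
    return sc.SpikeTrain(times=np.array([0.0, 1.0, 3.0, 6.0]), unit_id="u")
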