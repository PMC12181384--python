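import numpy as np
import pytest

from sporeseg.pipeline import run_end_to_end_demo


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full end-to-end run (simulate -> train -> evaluate -> count)
    on the reduced configuration, shared by every test that inspects
    learned behaviour."""
    out = tmp_path_factory.mktemp("demo")
    results = run_end_to_end_demo(seed=1, out=out)
    return results, out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
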