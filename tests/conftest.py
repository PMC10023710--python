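import numpy as np
import pytest

from shouldersim.specimen import reference_specimen


@pytest.fixture(scope="session")
def ref_specimen():
    return reference_specimen()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230317)


@pytest.fixture(scope="session")
def abduction_trial(ref_specimen):
    """One full abduction trial with clean diagnostics recorded."""
    from shouldersim.simulate import run_trial

    return run_trial(ref_specimen, "abduction", seed=11, record_clean=True)
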