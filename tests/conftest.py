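import pytest

from tehgt.simulate import make_master


@pytest.fixture(scope="session")
def master():
    """The simulated 1,610-nt master element with a 1,020-nt ORF."""
    return make_master(seed=0)
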