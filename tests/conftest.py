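import pytest

from regsign import datasets


@pytest.fixture(scope="session")
def myod1_net():
    return datasets.myod1_network()


@pytest.fixture(scope="session")
def target_evidence():
    return datasets.direct_target_evidence()
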