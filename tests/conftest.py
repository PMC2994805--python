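import pytest

import mssusmod as m


@pytest.fixture(scope="session")
def sweep_80_recessive():
    """Full (r, n) grid at the 20% dominant / 80% recessive composition."""
    return m.sweep(composition=(0.2, 0.8, 0.0))


@pytest.fixture(scope="session")
def sweep_all_dominant():
    return m.sweep(composition=(1.0, 0.0, 0.0))
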