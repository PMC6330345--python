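import pytest

from somaclone.simulate import ClonePanelSpec


@pytest.fixture
def panel() -> ClonePanelSpec:
    return ClonePanelSpec()
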