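import pytest

from uds.lexicon import load_packaged_lexicon


@pytest.fixture(scope="session")
def lex():
    return load_packaged_lexicon()
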