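import pytest

from concysfind import load_substitution_matrix


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")
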