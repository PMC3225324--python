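import pytest

from spadkit import (default_vocabulary, natural_residue_library,
                     residue_bit_table)


@pytest.fixture(scope="session")
def natural_lib():
    return natural_residue_library()


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def nat_table(natural_lib, vocab):
    return residue_bit_table(natural_lib, vocab)
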