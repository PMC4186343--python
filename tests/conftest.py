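import pytest

from hlag.gene_model import build_gene_model
from hlag.tables import load_reference_tables


@pytest.fixture(scope="session")
def model():
    return build_gene_model()


@pytest.fixture(scope="session")
def ref():
    return load_reference_tables()
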