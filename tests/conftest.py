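import pytest

from fluctspec.synthetic_data import synthetic_reference


@pytest.fixture(scope="session")
def ref():
    """Synthetic rpoB CDS reference (4029 nt, printed RRDR coordinates)."""
    return synthetic_reference()
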