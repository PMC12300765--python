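import pytest

from roifuse import load_reference


@pytest.fixture(scope="session")
def reference():
    """Packaged chromosome gene-count reference (full set incl. chr22)."""
    return load_reference()


@pytest.fixture(scope="session")
def reference_compat():
    """Reference restricted to the original index set 1-21, X, Y."""
    return load_reference(paper_compat=True)
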