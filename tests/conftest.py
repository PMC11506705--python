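import pytest

from prmkit import load_builtin_h1_assay


@pytest.fixture(scope="session")
def h1_assay():
    return load_builtin_h1_assay()


@pytest.fixture(scope="session")
def h1_true_amounts(h1_assay):
    """A plausible complement: a few dominant subtypes, two minor ones (ng)."""
    return dict(zip(h1_assay.subtypes, (0.5, 0.3, 1.5, 0.8, 2.0, 1.8, 0.2)))
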