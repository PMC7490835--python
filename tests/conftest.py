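import pytest
from hypothesis import settings

from msdeconv.datasets import methane_example, neon_example

# Deterministic property tests: same examples on every run.
settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def methane_ds():
    """CH4-at-m/z-15 validation campaign (Faraday cup)."""
    return methane_example()


@pytest.fixture(scope="session")
def neon_ds():
    """20Ne-at-m/z-20 validation campaign (electron multiplier)."""
    return neon_example()


@pytest.fixture(scope="session")
def table3_bases(methane_ds):
    """CH4 / N2 / Air basis spectra of the methane campaign."""
    return methane_ds.block.basis


@pytest.fixture(scope="session")
def table5_bases(neon_ds):
    """H2O / Ne / Ar basis spectra of the neon campaign."""
    return neon_ds.block.basis
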