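import pytest

from glycocoo import SynthParams, fixture_haptoglobin, fixture_worked_example, synth


@pytest.fixture(scope="session")
def hapto():
    return fixture_haptoglobin()


@pytest.fixture(scope="session")
def worked():
    return fixture_worked_example()


@pytest.fixture(scope="session")
def small_synth():
    """A seeded synthetic dataset with its ground truth (the query oracle)."""
    return synth(SynthParams(n_proteins=8, seed=11))
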