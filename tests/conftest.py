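"""Shared fixtures: panels and seeded synthetic datasets."""

import pytest

from matesel.panel import LocusPanel, matched_locus, reference_panel
from matesel.simulate import PopulationConfig, error_free, simulate_dataset


@pytest.fixture(scope="session")
def panel():
    """The 10-locus reference panel with published error rates."""
    return reference_panel()


@pytest.fixture(scope="session")
def ef_panel():
    """The reference panel with all error rates zeroed."""
    return reference_panel(with_errors=False)


@pytest.fixture(scope="session")
def small_panel():
    """Three 4-allele loci, no errors: cheap exact computations."""
    return LocusPanel(tuple(matched_locus(f"L{i}", 4, 0.6) for i in range(3)))


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset (with genotyping errors), seed 7."""
    return simulate_dataset(PopulationConfig(), seed=7)


@pytest.fixture(scope="session")
def ef_dataset():
    """Error-free dataset on the error-free panel, seed 3."""
    return simulate_dataset(error_free(), reference_panel(with_errors=False), seed=3)
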