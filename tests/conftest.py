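import numpy as np
import pandas as pd
import pytest

from accstrat.synthgen import (
    CohortConfig, default_genome, default_signature, generate_cohort,
    simulate_cohort_reads, simulate_counts, simulate_survival,
)


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def signature():
    return default_signature()


@pytest.fixture(scope="session")
def default_cohort(genome):
    """The default study-condition cohort (n=68, 72/10/18, depth 20k)."""
    cohort = generate_cohort(CohortConfig(seed=1), genome)
    simulate_survival(cohort)
    return cohort


@pytest.fixture(scope="session")
def default_reads(default_cohort):
    """Per-sample coverage tracks and clipped reads for the default cohort."""
    return simulate_cohort_reads(default_cohort)


@pytest.fixture(scope="session")
def default_counts(default_cohort, signature):
    return simulate_counts(default_cohort, signature)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
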