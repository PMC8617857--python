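import numpy as np
import pytest

from pgxlos.cohort_synth import (
    GeneratorConfig,
    apply_cohort_filters,
    generate_raw_cohort,
)
from pgxlos.pgx_kb import default_knowledge_base


@pytest.fixture(scope="session")
def kb():
    return default_knowledge_base()


@pytest.fixture(scope="session")
def small_cohort(kb):
    """A modest filtered/scored cohort shared by fast tests."""
    cfg = GeneratorConfig(n_patients=3000, seed=42)
    raw = generate_raw_cohort(cfg, kb)
    cohort, tally = apply_cohort_filters(raw, kb)
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
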