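import numpy as np
import pytest

from rasodesign import CohortSpec, generate_cohort, parse_iupac
from rasodesign.susceptibility import DEFAULT_CONSENSUS


@pytest.fixture(scope="session")
def default_pattern():
    return parse_iupac(DEFAULT_CONSENSUS)


@pytest.fixture(scope="session")
def small_cohort():
    """70 valid nonsense / 20 frameshift / 10 truncated, seeded."""
    spec = CohortSpec(n_nonsense=70, n_frameshift=20, n_truncated=10,
                      fraction_consensus_match=10 / 70, seed=42)
    transcripts, variants, truth = generate_cohort(spec)
    return spec, transcripts, variants, truth


@pytest.fixture(scope="session")
def full_cohort():
    """The default study conditions: 500 rows, 35 planted matches."""
    spec = CohortSpec(seed=7)
    transcripts, variants, truth = generate_cohort(spec)
    return spec, transcripts, variants, truth


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, full_cohort):
    """The default cohort written to disk (FASTA + CSV + truth JSON)."""
    spec, *_ = full_cohort
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(spec, out_dir=out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
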