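import numpy as np
import pytest

from mitopop.seqio import Alignment
from mitopop.simulate import make_study_fixture


@pytest.fixture(scope="session")
def study():
    """Deterministic 93-individual, 7-deme, 27-haplotype fixture."""
    aln, truth = make_study_fixture(seed=1)
    return aln, truth


@pytest.fixture(scope="session")
def study_aln(study):
    return study[0]


def make_alignment(seqs, demes=None, partitions=None):
    ids = [f"i{k}" for k in range(len(seqs))]
    demes = demes or ["d1"] * len(seqs)
    return Alignment(
        ids=ids, seqs=list(seqs), partitions=partitions or {},
        deme_of=dict(zip(ids, demes)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
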