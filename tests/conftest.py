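import pytest
from pyfaidx import Fasta

from txcontext.fixtures import make_fixture


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic dataset shared across the suite."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture(str(outdir), seed=7)


@pytest.fixture(scope="session")
def genome(dataset):
    return Fasta(dataset.fasta)


@pytest.fixture(scope="session")
def models_by_tid(dataset):
    return {m.transcript_id: m for m in dataset.models}
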