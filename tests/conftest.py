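import pytest

from lncpep.simulate import make_universe, write_universe


@pytest.fixture(scope="session")
def universe():
    """A deterministic synthetic universe with >= 50 spiked peptides."""
    return make_universe(seed=11)


@pytest.fixture(scope="session")
def universe_paths(universe, tmp_path_factory):
    """The same universe written out as standard-format fixture files."""
    outdir = tmp_path_factory.mktemp("fixture")
    return write_universe(universe, outdir)


@pytest.fixture(scope="session")
def genome_by_name(universe):
    return dict(universe.genome)


@pytest.fixture(scope="session")
def transcripts_by_id(universe):
    return {t.transcript_id: t for t in universe.transcripts}
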