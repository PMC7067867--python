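import pytest

from srnakit import align, annotate, fixtures, qc


@pytest.fixture(scope="session")
def spec():
    return fixtures.FixtureSpec(seed=17)


@pytest.fixture(scope="session")
def fixture_set(spec):
    return fixtures.make_all(spec)


@pytest.fixture(scope="session")
def qualified_reads(fixture_set):
    reads, _ = qc.qc_reads(fixture_set.reads, qc.QCConfig())
    return reads


@pytest.fixture(scope="session")
def aligned(fixture_set, qualified_reads):
    """(alignments, unmapped) of the qualified fixture reads."""
    return align.micro_align(qualified_reads, fixture_set.genome_fixture.genome, 1)


@pytest.fixture(scope="session")
def feature_index(fixture_set):
    return annotate.FeatureIndex(fixture_set.genome_fixture.features)
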