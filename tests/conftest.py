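import pytest

from anser import simulate


@pytest.fixture(scope="session")
def small_genome() -> str:
    return simulate.make_genome(10_000, gc=0.40, seed=11)


@pytest.fixture(scope="session")
def small_reads(small_genome):
    return simulate.make_reads(small_genome, depth=20, read_length=80,
                               error_rate=0.0, seed=11)
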