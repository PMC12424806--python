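import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_accession():
    """A small error-free accession assembled to unitigs: (genome, reads, graph)."""
    from unisearch.kmer import KmerSpec
    from unisearch.assembly import assemble_unitigs
    from unisearch.sim import SimSpec, simulate_genome, simulate_reads

    spec = SimSpec(genome_length=3000, coverage=25, seed=101)
    genome = simulate_genome(spec, unique_kmers_k=21)
    reads = simulate_reads(genome, spec)
    graph = assemble_unitigs(reads, KmerSpec(21))
    return genome, reads, graph
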