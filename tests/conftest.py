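import pytest
from hypothesis import HealthCheck, settings

from junctionscope.models import GeneSpec, GenomeSpec
from junctionscope.presets import default_genome_spec, default_truth_events
from junctionscope.simulate import build_toy_genome, make_event_transcript

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """Default toy genome: (genome dict, models dict)."""
    return build_toy_genome(default_genome_spec())


@pytest.fixture(scope="session")
def genome(toy):
    return toy[0]


@pytest.fixture(scope="session")
def models(toy):
    return toy[1]


@pytest.fixture(scope="session")
def truths(genome, models):
    """The 20 default truth events with genomic breakpoints filled in."""
    return [make_event_transcript(genome, models, t)[1]
            for t in default_truth_events()]


@pytest.fixture(scope="session")
def three_gene_toy():
    """Compact 3-gene annotation for exhaustive classifier checks."""
    spec = GenomeSpec(
        n_chromosomes=2, chrom_length=8000, seed=11,
        genes=(GeneSpec("ALPHA", "+", 6, exon_length=120, intron_length=80,
                        kinase_domain_exons=(4, 6), chrom="chr1"),
               GeneSpec("BETA", "-", 8, exon_length=100, intron_length=60,
                        kinase_domain_exons=(5, 8), autoinhibitory_exons=(1, 3),
                        chrom="chr1"),
               GeneSpec("GAMMA", "+", 5, exon_length=150, intron_length=90,
                        chrom="chr2")))
    return build_toy_genome(spec)
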