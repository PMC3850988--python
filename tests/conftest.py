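import pytest

from sasd.build import BuildConfig, build_database
from sasd.fixtures import FixtureSpec, generate_fixture
from sasd.gene_models import load_annotation


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """One 4-exon plus-strand gene, all features 200 nt, stop-free."""
    outdir = tmp_path_factory.mktemp("fx_small")
    spec = FixtureSpec(
        n_genes=1, exons_per_gene=4,
        exon_length_range=(200, 200), intron_length_range=(200, 200),
        strand_policy="all_plus", seed=1,
    )
    return generate_fixture(spec, outdir)


@pytest.fixture(scope="session")
def small_models(small_fixture):
    models, genome = load_annotation(small_fixture.gtf_path, small_fixture.genome_path)
    return models, genome


@pytest.fixture(scope="session")
def small_entries(small_models):
    models, genome = small_models
    entries, manifest = build_database(models, genome, BuildConfig())
    return entries, manifest


@pytest.fixture(scope="session")
def two_gene_fixture(tmp_path_factory):
    """Two genes x 4 exons, variable feature lengths, seed 7."""
    outdir = tmp_path_factory.mktemp("fx_two")
    spec = FixtureSpec(n_genes=2, exons_per_gene=4, seed=7)
    return generate_fixture(spec, outdir)
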