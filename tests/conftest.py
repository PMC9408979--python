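import pytest

from teacr.simulate import SimConfig, simulate_genome


SMALL_CONFIG = dict(
    n_chroms=2,
    chrom_len=300_000,
    n_genes=40,
    n_tes=80,
    n_acrs=60,
    n_gene_pairs=6,
    n_sweeps=1,
    cds_codons=120,
)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Full-size synthetic bundle at the study conditions (shared)."""
    out = tmp_path_factory.mktemp("bundle_default")
    return simulate_genome(SimConfig(seed=7), out)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Desk-scale bundle for structural / io round-trip checks."""
    out = tmp_path_factory.mktemp("bundle_small")
    return simulate_genome(SimConfig(seed=11, **SMALL_CONFIG), out)
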