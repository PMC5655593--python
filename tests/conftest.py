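import pytest

from omegapair.synthetic_data import SimConfig, simulate_genome_pair


@pytest.fixture(scope="session")
def small_pair():
    """A 50-gene genome pair at omega 0.2, kappa 2, t 0.3 (seeded)."""
    cfg = SimConfig(
        n_genes=50,
        gene_len_codons=300,
        omega=0.2,
        kappa=2.0,
        t=0.3,
        noncoding_fraction=0.2,
        seed=1,
    )
    return simulate_genome_pair(cfg)


@pytest.fixture(scope="session")
def sense_codons():
    from omegapair.codon_evolution import code_tables

    return code_tables(11).sense_codons
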