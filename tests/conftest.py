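import numpy as np
import pytest

from allelescan.cas import CasRegistry, load_default_registry
from allelescan.fixtures import (
    FixtureSpec,
    generate_cohort,
    generate_genes,
    generate_genome,
    write_fasta,
)
from allelescan.targetability import write_gene_table


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def spcas9(registry):
    return registry["SpCas9"]


@pytest.fixture(scope="session")
def sacas9(registry):
    return registry["SaCas9"]


@pytest.fixture(scope="session")
def cas12a(registry):
    return registry["AsCas12a"]


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def toy_world(tmp_path_factory):
    """A small synthetic world shared across tests: 12-sample phased cohort,
    100-kb genome, 5 genes, SpCas9+SaCas9 registry, all written to disk."""
    spec = FixtureSpec(seed=11, n_samples=12, n_variants=80)
    genome = generate_genome(spec)
    cohort = generate_cohort(spec, genome)
    genes = generate_genes(spec, genome)
    d = tmp_path_factory.mktemp("toy_world")
    write_fasta(genome, d / "genome.fa")
    cohort.write_vcf(d / "cohort.vcf")
    write_gene_table(genes, d / "genes.tsv")
    reg = load_default_registry()
    small = CasRegistry([reg["SpCas9"], reg["SaCas9"]])
    return {
        "spec": spec,
        "genome": genome,
        "cohort": cohort,
        "genes": genes,
        "registry": small,
        "fasta": str(d / "genome.fa"),
        "vcf": str(d / "cohort.vcf"),
        "genes_path": str(d / "genes.tsv"),
        "dir": d,
    }
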