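import numpy as np
import pytest

from chartographer.contacts import ContactRecord
from chartographer.genome import GeneModel, GenomeLayout
from chartographer.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def genome():
    return GenomeLayout(("chr1", "chr2", "chr3"), (30_000_000,) * 3)


@pytest.fixture(scope="session")
def gene_models():
    return [
        GeneModel("GENE0001", "chr1", "+", 1_000_000, 1_010_000, "mRNA"),
        GeneModel("GENE0002", "chr1", "-", 5_000_000, 5_020_000, "mRNA"),
        GeneModel("GENE0003", "chr2", "+", 10_000_000, 10_005_000, "mRNA"),
        GeneModel("LNC0001", "chr2", "-", 20_000_000, 20_012_000, "lncRNA"),
        GeneModel("UTL0001", "chr3", "+", 15_000_000, 15_001_000, "UTL"),
    ]


def random_records(rng, genome, gene_models, n, sample_id="S1"):
    """Uniformly random valid contact records for I/O and binning tests."""
    genes = rng.choice(len(gene_models), size=n)
    records = []
    sizes = genome.sizes
    for i, gi in enumerate(genes):
        g = gene_models[gi]
        dna_chrom = rng.choice(genome.chrom_names)
        records.append(ContactRecord(
            read_id=f"r{i}",
            rna_gene_id=g.gene_id,
            rna_chrom=g.chrom,
            rna_pos=int(rng.integers(g.start, g.end)),
            rna_strand=g.strand,
            dna_chrom=str(dna_chrom),
            dna_pos=int(rng.integers(0, sizes[dna_chrom])),
            dna_strand=str(rng.choice(["+", "-"])),
            annotation_class=str(rng.choice(["exon", "intron", "intergenic"])),
            sample_id=sample_id,
        ))
    return records


@pytest.fixture(scope="session")
def dataset():
    """Default-conditions synthetic dataset shared across test modules."""
    return simulate_dataset(SimulationConfig(), seed=7)
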