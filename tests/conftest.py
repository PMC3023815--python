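import numpy as np
import pytest

from gwascorrect.genotype_io import GenotypeDataset, SnpRecord
from gwascorrect.synthetic import (
    HaplotypePanel,
    PhenotypeModel,
    assign_phenotypes,
    simulate_genotypes,
    simulate_panel,
)


def make_dataset(dosages, labels=None, chrom="1", sample_prefix="s", snp_prefix="rs"):
    """Hand-rolled dataset from a raw dosage matrix (rows = samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    snps = [
        SnpRecord(id=f"{snp_prefix}{j}", chromosome=chrom, position=(j + 1) * 100,
                  allele_a="A", allele_b="C")
        for j in range(m)
    ]
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    return GenotypeDataset(snps=snps, samples=samples, dosages=dosages, labels=labels)


def mixed_pool_panel(n_blocks, block_size, seed, k_low=2, k_high=4, maf_min=0.01):
    """Blocky panel with per-block pool size drawn uniformly on [k_low, k_high]."""
    return simulate_panel(
        n_blocks=n_blocks,
        block_size_sampler=block_size,
        pool_size=lambda rng: int(rng.integers(k_low, k_high + 1)),
        maf_min=maf_min,
        seed=seed,
    )


def independent_snp_panel(n_snps, seed, pool_size=40):
    """Panel of single-SNP blocks: mutually independent markers.

    A large haplotype pool keeps allele frequencies away from the rare-allele
    regime in which the four-gamete test cannot see recombination (the
    minor-minor haplotype of two independent rare SNPs falls below any
    frequency cutoff), so the independence limit is clean."""
    return simulate_panel(
        n_blocks=n_snps, block_size_sampler=1, pool_size=pool_size, seed=seed
    )


@pytest.fixture(scope="session")
def blocky_dataset():
    """Medium blocky panel with null labels, shared across read-only tests:
    60 blocks of 5 SNPs, mixed pools of 2-4 haplotypes, 400 samples."""
    panel = mixed_pool_panel(60, 5, seed=42)
    ds = simulate_genotypes(panel, 400, seed=43)
    labels = assign_phenotypes(ds, PhenotypeModel(kind="null", prevalence=0.5), seed=44)
    return panel, ds.with_labels(labels)
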