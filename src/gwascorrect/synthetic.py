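"""Synthetic case/control genotype data with block-structured LD.

The generator uses a haplotype-pool model: the genome is a sequence of
independent blocks, each carrying a small pool of K haplotypes with Dirichlet
sampling weights.  A diploid sample draws two haplotypes per block, so LD is
complete freedom ("free recombination") between blocks and strong within
them.  Within a block every SNP pair is constrained to show at most three of
the four possible two-locus gametes in the implied population, i.e. pairwise
|D'| = 1 while r^2 varies with the pool — the textbook signature of a
haplotype block with no internal recombination.  This gives LD-block
algorithms a known ground-truth partition and makes the gap between "number
of blocks" and "number of effective tests" a controlled quantity.

Phenotypes are Bernoulli: a constant case probability under the null, or a
per-dosage case probability (p0, p1, p2) at one causal SNP under the
additive alternative.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .genotype_io import GenotypeDataset, SnpRecord

__all__ = [
    "HaplotypeBlock",
    "HaplotypePanel",
    "PhenotypeModel",
    "simulate_panel",
    "simulate_genotypes",
    "assign_phenotypes",
]


class ConfigurationError(ValueError):
    """Raised when generator constraints are infeasible."""


@dataclass
class HaplotypeBlock:
    """A pool of K distinct haplotypes (rows) over the block's SNPs, with
    sampling weights summing to one."""

    haplotypes: np.ndarray  # (K, L) of 0/1
    weights: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != self.weights.shape[0]:
            raise ValueError("haplotype/weight shape mismatch")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Population frequency of the 1-allele at each SNP."""
        return self.weights @ self.haplotypes


@dataclass
class HaplotypePanel:
    """Ordered blocks defining the simulated population's LD structure."""

    blocks: list[HaplotypeBlock]
    maf_min: float = 0.01

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.blocks)

    def block_spans(self) -> list[tuple[int, int]]:
        """Ground-truth half-open SNP index range of each block."""
        spans, start = [], 0
        for b in self.blocks:
            spans.append((start, start + b.n_snps))
            start += b.n_snps
        return spans

    def allele_freqs(self) -> np.ndarray:
        return np.concatenate([b.allele_freqs() for b in self.blocks])


@dataclass
class PhenotypeModel:
    """Bernoulli phenotype model.

    kind="null": every sample is a case with probability ``prevalence``,
    independent of genotype.  kind="additive": the case probability is
    ``case_probs[d]`` where d is the sample's dosage at ``causal_snp``.
    """

    kind: str = "null"
    prevalence: float = 0.5
    causal_snp: str | None = None
    case_probs: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.kind not in ("null", "additive"):
            raise ValueError(f"unknown phenotype model kind {self.kind!r}")
        probs = (self.prevalence, *self.case_probs)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("case probabilities must lie in [0, 1]")
        if self.kind == "additive" and self.causal_snp is None:
            raise ValueError("additive model requires a causal SNP id")


def _resolve_sizes(block_size_sampler, n_blocks: int, rng: np.random.Generator) -> list[int]:
    if isinstance(block_size_sampler, (int, np.integer)):
        return [int(block_size_sampler)] * n_blocks
    if callable(block_size_sampler):
        return [int(block_size_sampler(rng)) for _ in range(n_blocks)]
    sizes = [int(s) for s in block_size_sampler]
    if len(sizes) != n_blocks:
        raise ConfigurationError("block size list length must equal n_blocks")
    return sizes


def _fourth_gamete_free(col: np.ndarray, prev: np.ndarray) -> bool:
    """True if ``col`` realises at most 3 gametes with every column of ``prev``."""
    if prev.size == 0:
        return True
    # gamete (a, b) present iff some haplotype carries it; all weights are
    # positive so presence in the pool means positive population frequency
    c = col[:, None]
    present = np.stack(
        [((prev == a) & (c == b)).any(axis=0) for a in (0, 1) for b in (0, 1)]
    )
    return not bool(present.all(axis=0).any())


def simulate_panel(
    n_blocks: int,
    block_size_sampler: int | Sequence[int] | Callable[[np.random.Generator], int] = 5,
    pool_size: int | Sequence[int] | Callable[[np.random.Generator], int] = 4,
    maf_min: float = 0.01,
    seed: int | None = 0,
    max_column_tries: int = 2000,
    max_block_restarts: int = 200,
) -> HaplotypePanel:
    """Draw a haplotype panel: ``n_blocks`` independent blocks, each a pool of
    K distinct haplotypes with Dirichlet(1) weights.

    ``block_size_sampler`` and ``pool_size`` may each be a constant, a
    per-block sequence, or a callable drawing from the supplied generator.
    Haplotype columns are drawn uniformly over {0,1}^K and rejected until
    (a) the implied population MAF of every SNP is >= ``maf_min`` and (b) no
    SNP pair within the block realises all four gametes; coinciding haplotype
    draws are merged (weights summed) so each pool holds distinct haplotypes.
    Deterministic given ``seed``.
    """
    if n_blocks < 1:
        raise ConfigurationError("need at least one block")
    rng = np.random.default_rng(seed)
    sizes = _resolve_sizes(block_size_sampler, n_blocks, rng)
    pools = _resolve_sizes(pool_size, n_blocks, rng)
    if any(s < 1 for s in sizes):
        raise ConfigurationError("block sizes must be >= 1")
    if any(k < 1 for k in pools):
        raise ConfigurationError("need at least one haplotype per block")
    if maf_min > 0 and any(k == 1 for k in pools):
        raise ConfigurationError(
            "a single-haplotype pool is monomorphic and cannot satisfy maf_min > 0"
        )

    blocks: list[HaplotypeBlock] = []
    for size, k in zip(sizes, pools):
        for _restart in range(max_block_restarts):
            weights = rng.dirichlet(np.ones(k))
            prev = np.empty((k, 0), dtype=np.int8)
            ok = True
            for _l in range(size):
                for _try in range(max_column_tries):
                    col = rng.integers(0, 2, size=k).astype(np.int8)
                    freq = float(weights @ col)
                    if not (maf_min <= freq <= 1.0 - maf_min):
                        continue
                    if _fourth_gamete_free(col, prev):
                        break
                else:
                    ok = False
                    break
                prev = np.column_stack([prev, col])
            if ok:
                # merge coinciding haplotypes (common for short blocks) so the
                # pool is a set of distinct haplotypes with summed weights
                uniq, inverse = np.unique(prev, axis=0, return_inverse=True)
                w = np.zeros(uniq.shape[0])
                np.add.at(w, inverse, weights)
                blocks.append(HaplotypeBlock(haplotypes=uniq.astype(np.int8), weights=w))
                break
        else:
            raise ConfigurationError(
                f"could not satisfy MAF/LD constraints for a block of size {size} "
                f"with pool size {k}, maf_min={maf_min}"
            )
    return HaplotypePanel(blocks=blocks, maf_min=maf_min)


def simulate_genotypes(
    panel: HaplotypePanel,
    n_samples: int,
    seed: int | None = 0,
    chromosome: str = "1",
    position_step: int = 1000,
) -> GenotypeDataset:
    """Draw unrelated diploid samples from the panel.

    Each sample takes two independent haplotype draws per block (blocks
    independent, emulating free inter-block recombination); dosage is their
    sum.  No missingness is introduced.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    parts = []
    for block in panel.blocks:
        k = len(block.weights)
        draws = rng.choice(k, size=(n_samples, 2), p=block.weights)
        parts.append(block.haplotypes[draws[:, 0]] + block.haplotypes[draws[:, 1]])
    dosages = np.concatenate(parts, axis=1).astype(np.int8)
    m = dosages.shape[1]
    snps = [
        SnpRecord(
            id=f"snp{j:06d}",
            chromosome=chromosome,
            position=(j + 1) * position_step,
            allele_a="A",
            allele_b="B",
        )
        for j in range(m)
    ]
    samples = [f"ind{i:05d}" for i in range(n_samples)]
    return GenotypeDataset(snps=snps, samples=samples, dosages=dosages)


def assign_phenotypes(
    dataset: GenotypeDataset,
    model: PhenotypeModel,
    seed: int | None = 0,
) -> np.ndarray:
    """Independent Bernoulli case/control labels under the given model."""
    rng = np.random.default_rng(seed)
    if model.kind == "null":
        probs = np.full(dataset.n_samples, model.prevalence)
    else:
        ids = dataset.snp_ids()
        try:
            j = ids.index(model.causal_snp)
        except ValueError as exc:
            raise ValueError(f"causal SNP {model.causal_snp!r} not in dataset") from exc
        dose = dataset.dosages[:, j]
        if (dose < 0).any():
            raise ValueError("causal SNP has missing genotypes")
        probs = np.asarray(model.case_probs, dtype=float)[dose]
    return (rng.random(dataset.n_samples) < probs).astype(np.int8)
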