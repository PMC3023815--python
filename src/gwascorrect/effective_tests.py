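"""Effective number of independent tests from PCA of the LD correlation
matrix (the simpleM procedure).

For a region of SNPs, M_eff is the smallest number of principal components of
the composite (dosage) correlation matrix whose eigenvalues capture a fixed
fraction C of the total variance (C = 0.995 by convention).  Summing M_eff
over regions that are cut at LD-block boundaries gives a genome-wide
effective test count, usable directly in a Bonferroni adjustment
alpha / M_eff.  Regions should be kept well below the sample count: a sample
correlation matrix has rank at most n-1, which mechanically caps M_eff for
oversized regions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "Region",
    "EffectiveTestCount",
    "composite_correlation",
    "meff_from_eigenvalues",
    "choose_regions",
    "simplem_meff",
]


@dataclass(frozen=True)
class Region:
    """Half-open SNP column range [start, stop) on one chromosome."""

    chromosome: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.stop:
            raise ValueError("empty or inverted region")

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class EffectiveTestCount:
    """Per-region and total effective test counts at variance fraction C."""

    per_region: tuple[int, ...]
    total: int
    variance_fraction: float


def composite_correlation(dataset: GenotypeDataset, region: Region) -> np.ndarray:
    """Pairwise-complete Pearson correlation of the region's dosage columns.

    Monomorphic columns get a unit diagonal and zero off-diagonals, so they
    contribute exactly one eigenvalue of 1 (one test) to the region.
    """
    X = dataset.dosages[:, region.start : region.stop]
    n, m = X.shape
    mask = (X != MISSING).astype(np.float64)
    X0 = np.where(X == MISSING, 0, X).astype(np.float64)
    nn = mask.T @ mask
    s = mask.T @ X0  # s[i, j] = sum of column j over samples observed at both i and j
    ss = mask.T @ (X0 * X0)
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = nn * sxy - s.T * s
        var_i = nn * ss.T - s.T * s.T
        var_j = nn * ss - s * s
        corr = cov / np.sqrt(var_i * var_j)
    bad = ~np.isfinite(corr) | (var_i <= 1e-12) | (var_j <= 1e-12) | (nn <= 1)
    corr = np.where(bad, 0.0, np.clip(corr, -1.0, 1.0))
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def meff_from_eigenvalues(eigvals: np.ndarray, c: float = 0.995) -> int:
    """Smallest m such that the m largest eigenvalues sum to at least a
    fraction ``c`` of the total.  Tiny negative eigenvalues (down to -1e-8,
    rounding debris from pairwise-complete correlations) are clipped to 0."""
    ev = np.asarray(eigvals, dtype=float)
    if ev.size == 0:
        raise ValueError("no eigenvalues")
    if (ev < -1e-8).any():
        raise ValueError("matrix has a substantially negative eigenvalue")
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    ev = np.sort(ev)[::-1]
    cum = np.cumsum(ev)
    target = c * total - 1e-9 * total
    return int(np.searchsorted(cum, target) + 1)


def choose_regions(dataset: GenotypeDataset, block_partition, target_size: int = 5000) -> list[Region]:
    """Cut the genome into analysis regions of about ``target_size`` SNPs,
    closing each region at the first LD-block boundary that reaches the
    target.  No region ever splits a block; a block larger than the target
    becomes its own region (with a warning)."""
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    regions: list[Region] = []
    for chrom, start, stop in dataset.chromosome_spans():
        units = block_partition.units(start, stop)
        cur_start, cur_len = None, 0
        for ustart, ustop in units:
            if ustop - ustart > target_size:
                warnings.warn(
                    f"LD block of {ustop - ustart} SNPs exceeds region target "
                    f"{target_size}; it forms its own region",
                    stacklevel=2,
                )
            if cur_start is None:
                cur_start = ustart
            cur_len += ustop - ustart
            if cur_len >= target_size:
                regions.append(Region(chromosome=chrom, start=cur_start, stop=ustop))
                cur_start, cur_len = None, 0
        if cur_start is not None:
            regions.append(Region(chromosome=chrom, start=cur_start, stop=stop))
    return regions


def simplem_meff(
    dataset: GenotypeDataset, regions: list[Region], c: float = 0.995
) -> EffectiveTestCount:
    """Total effective test count: sum over regions of the eigenvalue-rule
    M_eff of the region's composite correlation matrix."""
    covered = sorted((r.start, r.stop) for r in regions)
    pos = 0
    for start, stop in covered:
        if start != pos:
            raise ValueError("regions must cover all SNPs exactly once, in order")
        pos = stop
    if pos != dataset.n_snps:
        raise ValueError("regions must cover all SNPs exactly once")
    per_region = []
    for region in regions:
        corr = composite_correlation(dataset, region)
        eigvals = np.linalg.eigvalsh(corr)
        per_region.append(meff_from_eigenvalues(eigvals, c))
    return EffectiveTestCount(
        per_region=tuple(per_region), total=int(sum(per_region)), variance_fraction=c
    )
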