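"""Pairwise LD from unphased genotypes and haplotype-block partitions.

Two-locus haplotype frequencies are estimated by EM (the double-heterozygote
cell is the only phase-ambiguous one), giving D, D' and r^2 per SNP pair, and
a likelihood-grid confidence interval for |D'|.  Three block definitions are
implemented with their conventional parameters:

* Gabriel: blocks whose endpoint pairs are in "strong LD" by D' CI criteria
  and where at most a small fraction of informative pairs show strong
  historical recombination.
* Solid spine of LD: first and last SNP of a block each in high |D'| with
  every SNP between them.
* Four-gamete: a block breaks where a pair exhibits all four two-locus
  haplotypes above a frequency cutoff (evidence of recombination).

A partition's block count plus its singleton count is the test count used in
block-based Bonferroni corrections.  Pairs are evaluated within a sliding
index window (``max_dist``) on each chromosome.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "TwoLocusCounts",
    "HaplotypeFreqs",
    "LdPoint",
    "LdBlockPartition",
    "em_haplotype_freqs",
    "pair_loglik",
    "ld_stats",
    "dprime_ci",
    "gabriel_blocks",
    "solid_spine_blocks",
    "four_gamete_blocks",
    "block_test_count",
    "chunked_partition",
]

# haplotype order used throughout: AB, Ab, aB, ab
#   (capital = the allele whose dosage is counted, at each locus)
_HAP_ALLELES = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
# genotype-cell <- haplotype-pair incidence: T[cell, h1*4+h2] = 1 iff the
# unordered pair (h1, h2) produces dosage cell (g1, g2); cell index = 3*g1+g2
_T = np.zeros((9, 16))
for _h1 in range(4):
    for _h2 in range(4):
        _g1 = _HAP_ALLELES[_h1, 0] + _HAP_ALLELES[_h2, 0]
        _g2 = _HAP_ALLELES[_h1, 1] + _HAP_ALLELES[_h2, 1]
        _T[3 * _g1 + _g2, 4 * _h1 + _h2] = 1.0

# base haplotype contributions of each phase-unambiguous genotype cell:
# _BASE[cell, hap] = haplotypes contributed per sample in that cell
_BASE = np.zeros((9, 4))
for _c in range(9):
    _g1, _g2 = divmod(_c, 3)
    if (_g1, _g2) == (1, 1):
        continue  # ambiguous double heterozygote
    # alleles at locus 1: _g1 copies of A; locus 2: _g2 copies of B.
    # the decomposition into two haplotypes is unique when at most one locus
    # is heterozygous: pair the heterozygous locus's alleles arbitrarily with
    # the homozygous locus's identical alleles
    _a1 = [1] * _g1 + [0] * (2 - _g1)
    _a2 = [1] * _g2 + [0] * (2 - _g2)
    for _al1, _al2 in [(_a1[0], _a2[0]), (_a1[1], _a2[1])]:
        _BASE[_c, int(np.flatnonzero((_HAP_ALLELES == [_al1, _al2]).all(axis=1))[0])] += 1.0
_DOUBLE_HET = 4  # flat cell index of (1, 1)


@dataclass(frozen=True)
class TwoLocusCounts:
    """3x3 joint dosage counts for a SNP pair; n[g1][g2]."""

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.int64)
        if t.shape != (3, 3) or (t < 0).any():
            raise ValueError("counts must be a non-negative 3x3 table")
        if t.sum() == 0:
            raise ValueError("empty two-locus table")
        object.__setattr__(self, "table", t)

    @property
    def n(self) -> int:
        return int(self.table.sum())

    def allele_freqs(self) -> tuple[float, float]:
        """(p_A, p_B): sample frequency of the counted allele at each locus."""
        n = 2.0 * self.n
        p_a = (2 * self.table[2, :].sum() + self.table[1, :].sum()) / n
        p_b = (2 * self.table[:, 2].sum() + self.table[:, 1].sum()) / n
        return float(p_a), float(p_b)


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequencies (p_AB, p_Ab, p_aB, p_ab)."""

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    converged: bool = True

    def __post_init__(self) -> None:
        vec = self.as_array()
        if (vec < -1e-9).any() or abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must be a distribution")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


@dataclass(frozen=True)
class LdPoint:
    d: float
    d_prime: float
    r2: float


@dataclass
class LdBlockPartition:
    """Ordered non-overlapping multi-SNP blocks over a dataset's SNP columns;
    every SNP outside a block is an implicit singleton."""

    n_snps: int
    blocks: list[tuple[int, int]]  # half-open index ranges, each of length >= 2
    chromosome_spans: list[tuple[str, int, int]]
    algorithm: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.blocks = sorted(tuple(b) for b in self.blocks)
        prev_stop = 0
        for start, stop in self.blocks:
            if stop - start < 2:
                raise ValueError("blocks must contain at least 2 SNPs")
            if start < prev_stop:
                raise ValueError("blocks overlap")
            if not 0 <= start < stop <= self.n_snps:
                raise ValueError("block out of range")
            if not any(cs <= start and stop <= ce for _c, cs, ce in self.chromosome_spans):
                raise ValueError("block crosses a chromosome boundary")
            prev_stop = stop

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_singletons(self) -> int:
        return self.n_snps - sum(stop - start for start, stop in self.blocks)

    def units(self, start: int = 0, stop: int | None = None):
        """Blocks and singletons, in order, as half-open ranges covering
        [start, stop) exactly once."""
        stop = self.n_snps if stop is None else stop
        out = []
        pos = start
        for bstart, bstop in self.blocks:
            if bstop <= start or bstart >= stop:
                continue
            out.extend((j, j + 1) for j in range(pos, bstart))
            out.append((bstart, bstop))
            pos = bstop
        out.extend((j, j + 1) for j in range(pos, stop))
        return out

    @classmethod
    def all_singletons(cls, dataset: GenotypeDataset) -> "LdBlockPartition":
        return cls(
            n_snps=dataset.n_snps,
            blocks=[],
            chromosome_spans=dataset.chromosome_spans(),
            algorithm="singletons",
        )

    def to_bed_frame(self, dataset: GenotypeDataset):
        """BED-like table (chrom, start position, end position, n_snps) with
        0-based half-open physical coordinates."""
        import pandas as pd

        rows = []
        for start, stop in self.blocks:
            rows.append(
                {
                    "chrom": dataset.snps[start].chromosome,
                    "start": dataset.snps[start].position - 1,
                    "end": dataset.snps[stop - 1].position,
                    "n_snps": stop - start,
                }
            )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])


def block_test_count(partition: LdBlockPartition) -> int:
    """Number of tests implied by a partition: blocks plus singleton SNPs."""
    return partition.n_blocks + partition.n_singletons


# ---------------------------------------------------------------------------
# Two-locus EM and LD statistics
# ---------------------------------------------------------------------------

def _em_batch(counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """Vectorised two-locus EM over P pairs.

    counts: (P, 9) flattened 3x3 tables.  Returns (freqs (P, 4), converged
    (P,), n_iter (P,)).  Initialised at linkage equilibrium nudged toward the
    coupling phase, which escapes the saddle point of phase-symmetric tables.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 1:
        counts = counts[None, :]
    p, _ = counts.shape
    n2 = 2.0 * counts.sum(axis=1)  # haplotypes per pair
    # observed allele frequencies
    g1 = counts.reshape(p, 3, 3)
    p_a = (2 * g1[:, 2, :].sum(axis=1) + g1[:, 1, :].sum(axis=1)) / n2
    p_b = (2 * g1[:, :, 2].sum(axis=1) + g1[:, :, 1].sum(axis=1)) / n2
    # LE start with a small positive-D perturbation (bounded to stay valid)
    d0 = 0.01 * np.minimum.reduce([p_a * p_b, (1 - p_a) * (1 - p_b),
                                   p_a * (1 - p_b), (1 - p_a) * p_b])
    f = np.stack(
        [p_a * p_b + d0, p_a * (1 - p_b) - d0, (1 - p_a) * p_b - d0,
         (1 - p_a) * (1 - p_b) + d0],
        axis=1,
    )
    base = counts @ _BASE  # phase-unambiguous haplotype counts, (P, 4)
    ndh = counts[:, _DOUBLE_HET]
    converged = np.zeros(p, dtype=bool)
    iters = np.zeros(p, dtype=int)
    for it in range(max_iter):
        cis = f[:, 0] * f[:, 3]
        trans = f[:, 1] * f[:, 2]
        denom = cis + trans
        with np.errstate(invalid="ignore", divide="ignore"):
            pcis = np.where(denom > 0, cis / np.maximum(denom, 1e-300), 0.5)
        hap = base.copy()
        hap[:, 0] += ndh * pcis
        hap[:, 3] += ndh * pcis
        hap[:, 1] += ndh * (1.0 - pcis)
        hap[:, 2] += ndh * (1.0 - pcis)
        f_new = hap / n2[:, None]
        delta = np.abs(f_new - f).max(axis=1)
        newly = ~converged & (delta < tol)
        iters[~converged] = it + 1
        converged |= newly
        f = f_new
        if converged.all():
            break
    return f, converged, iters


def em_haplotype_freqs(
    counts: TwoLocusCounts, tol: float = 1e-8, max_iter: int = 1000
) -> HaplotypeFreqs:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    Every genotype cell except the double heterozygote is phase-unambiguous;
    the double-heterozygote mass is split between cis and trans phase each
    E-step.  Convergence: max frequency change < ``tol``.  A table that has
    not converged at ``max_iter`` returns the current estimate flagged
    ``converged=False``.
    """
    p_a, p_b = counts.allele_freqs()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("both SNPs must be polymorphic in the table")
    f, conv, _ = _em_batch(counts.table.reshape(1, 9), tol=tol, max_iter=max_iter)
    f = np.clip(f[0], 0.0, 1.0)
    f = f / f.sum()
    return HaplotypeFreqs(*map(float, f), converged=bool(conv[0]))


def pair_loglik(counts: TwoLocusCounts, freqs: HaplotypeFreqs) -> float:
    """Observed-data log-likelihood of a genotype table under random union of
    gametes with the given haplotype frequencies."""
    f = freqs.as_array()
    cell = _T @ np.outer(f, f).ravel()
    return float(counts.table.ravel() @ np.log(np.maximum(cell, 1e-300)))


def ld_stats(freqs: HaplotypeFreqs) -> LdPoint:
    """D, |D'| and r^2 from haplotype frequencies.

    D = p_AB - p_A p_B; D' = |D| / D_max with the standard marginal-dependent
    bound; r^2 = D^2 / (p_A p_a p_B p_b).
    """
    f = freqs.as_array()
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    if not (0 < p_a < 1) or not (0 < p_b < 1):
        raise ValueError("monomorphic marginal: LD undefined")
    d = f[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max <= 0 else min(abs(d) / d_max, 1.0)
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdPoint(d=float(d), d_prime=float(d_prime), r2=float(min(r2, 1.0)))


def _grid_posteriors(counts: np.ndarray, grid: int = 101):
    """Normalised likelihood mass over a |D'| grid for P pairs.

    counts: (P, 9).  The table's likelihood is evaluated at haplotype
    frequencies parameterised by |D'| at the fixed observed allele
    frequencies, after orienting each pair so the EM-estimated D is >= 0.
    Returns (grid values (G,), mass (P, G)).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim == 1:
        counts = counts[None, :]
    p = counts.shape[0]
    f_em, _, _ = _em_batch(counts)
    d_em = f_em[:, 0] - (f_em[:, 0] + f_em[:, 1]) * (f_em[:, 0] + f_em[:, 2])
    flip = d_em < 0
    # swapping the allele labels at locus 2 reverses the table's columns
    tables = counts.reshape(p, 3, 3).copy()
    tables[flip] = tables[flip][:, :, ::-1]
    counts_o = tables.reshape(p, 9)

    n2 = 2.0 * counts_o.sum(axis=1)
    g = counts_o.reshape(p, 3, 3)
    p_a = (2 * g[:, 2, :].sum(axis=1) + g[:, 1, :].sum(axis=1)) / n2
    p_b = (2 * g[:, :, 2].sum(axis=1) + g[:, :, 1].sum(axis=1)) / n2
    d_max = np.minimum(p_a * (1 - p_b), (1 - p_a) * p_b)  # positive-D branch

    dgrid = np.linspace(0.0, 1.0, grid)
    d = dgrid[None, :] * d_max[:, None]  # (P, G)
    f = np.empty((p, grid, 4))
    f[:, :, 0] = p_a[:, None] * p_b[:, None] + d
    f[:, :, 1] = p_a[:, None] * (1 - p_b[:, None]) - d
    f[:, :, 2] = (1 - p_a[:, None]) * p_b[:, None] - d
    f[:, :, 3] = (1 - p_a[:, None]) * (1 - p_b[:, None]) + d
    f = np.clip(f, 0.0, 1.0)
    outer = f[:, :, :, None] * f[:, :, None, :]  # (P, G, 4, 4)
    cell = outer.reshape(p, grid, 16) @ _T.T  # (P, G, 9)
    loglik = np.einsum("pgc,pc->pg", np.log(np.maximum(cell, 1e-300)), counts_o)
    loglik -= loglik.max(axis=1, keepdims=True)
    mass = np.exp(loglik)
    mass /= mass.sum(axis=1, keepdims=True)
    return dgrid, mass


def dprime_ci(
    counts: TwoLocusCounts, grid: int = 101, coverage: float = 0.90
) -> tuple[float, float]:
    """Likelihood-grid confidence interval for |D'|.

    The genotype-table likelihood is evaluated on a grid of |D'| values at
    the observed allele frequencies, normalised to unit mass; the bounds cut
    (1-coverage)/2 tails on each side.  A degenerate (single-point) mass
    collapses the interval to that point.
    """
    dgrid, mass = _grid_posteriors(counts.table.reshape(1, 9), grid=grid)
    lo, hi = _ci_from_mass(dgrid, mass, (1.0 - coverage) / 2.0)
    return float(lo[0]), float(hi[0])


def _ci_from_mass(dgrid: np.ndarray, mass: np.ndarray, tail: float):
    cum = np.cumsum(mass, axis=1)
    below = cum - mass  # mass strictly below each grid point
    above = 1.0 - cum  # mass strictly above
    eps = 1e-12
    lo_idx = (below <= tail + eps).sum(axis=1) - 1  # largest index still allowed
    hi_idx = mass.shape[1] - (above <= tail + eps).sum(axis=1)
    hi_idx = np.minimum(hi_idx, mass.shape[1] - 1)
    lo_idx = np.clip(lo_idx, 0, mass.shape[1] - 1)
    lo = dgrid[lo_idx]
    hi = dgrid[np.maximum(hi_idx, lo_idx)]
    return lo, hi


# ---------------------------------------------------------------------------
# Pair enumeration over a banded window
# ---------------------------------------------------------------------------

def _band_pairs(spans, max_dist: int):
    """All within-chromosome index pairs (i < j <= i + max_dist)."""
    ii, jj = [], []
    for _chrom, start, stop in spans:
        for i in range(start, stop - 1):
            hi = min(stop, i + 1 + max_dist)
            ii.extend([i] * (hi - i - 1))
            jj.extend(range(i + 1, hi))
    return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int)


def _joint_counts(X: np.ndarray, ii: np.ndarray, jj: np.ndarray, chunk: int = 4096):
    """(P, 9) joint dosage count tables for the requested column pairs;
    samples missing at either SNP are dropped."""
    p = ii.size
    out = np.empty((p, 9), dtype=np.int64)
    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        a = X[:, ii[lo:hi]]
        b = X[:, jj[lo:hi]]
        for g1 in range(3):
            ea = a == g1
            for g2 in range(3):
                out[lo:hi, 3 * g1 + g2] = (ea & (b == g2)).sum(axis=0)
    return out


def _pair_freqs(dataset: GenotypeDataset, max_dist: int):
    """EM haplotype frequencies for every banded pair.

    Returns (ii, jj, freqs (P,4), informative (P,) bool, counts (P,9));
    pairs touching a monomorphic (or all-missing) SNP are marked
    uninformative with NaN frequencies.
    """
    ii, jj = _band_pairs(dataset.chromosome_spans(), max_dist)
    if ii.size == 0:
        return ii, jj, np.empty((0, 4)), np.empty(0, dtype=bool), np.empty((0, 9), dtype=np.int64)
    counts = _joint_counts(dataset.dosages, ii, jj)
    g = counts.reshape(-1, 3, 3)
    tot = g.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = (2 * g[:, 2, :].sum(axis=1) + g[:, 1, :].sum(axis=1)) / (2.0 * tot)
        p_b = (2 * g[:, :, 2].sum(axis=1) + g[:, :, 1].sum(axis=1)) / (2.0 * tot)
    informative = (tot > 0) & (p_a > 0) & (p_a < 1) & (p_b > 0) & (p_b < 1)
    freqs = np.full((ii.size, 4), np.nan)
    if informative.any():
        freqs[informative], _, _ = _em_batch(counts[informative])
    return ii, jj, freqs, informative, counts


def _dprime_from_freqs(freqs: np.ndarray) -> np.ndarray:
    """Vectorised |D'| for an array of haplotype frequency rows (NaN-safe)."""
    p_a = freqs[:, 0] + freqs[:, 1]
    p_b = freqs[:, 0] + freqs[:, 2]
    d = freqs[:, 0] - p_a * p_b
    with np.errstate(invalid="ignore"):
        d_max = np.where(
            d >= 0,
            np.minimum(p_a * (1 - p_b), (1 - p_a) * p_b),
            np.minimum(p_a * p_b, (1 - p_a) * (1 - p_b)),
        )
        out = np.abs(d) / d_max
    out = np.where(np.isfinite(out), np.minimum(out, 1.0), 0.0)
    return out


def _band_lookup(n_snps: int, max_dist: int, ii, jj, values, fill=0.0):
    """Dense (n_snps, max_dist) band table: band[j, j-i-1] = value(i, j)."""
    band = np.full((n_snps, max_dist), fill, dtype=float)
    band[jj, jj - ii - 1] = values
    return band


# ---------------------------------------------------------------------------
# Block algorithms
# ---------------------------------------------------------------------------

def gabriel_blocks(
    dataset: GenotypeDataset,
    ci_upper_min: float = 0.98,
    ci_lower_min: float = 0.70,
    strong_fraction: float = 0.95,
    recomb_upper: float = 0.90,
    max_dist: int = 250,
    grid: int = 101,
    coverage: float = 0.90,
) -> LdBlockPartition:
    """Haplotype blocks by the D' confidence-interval protocol.

    A pair is in *strong LD* when its |D'| CI satisfies lower >= ci_lower_min
    and upper >= ci_upper_min, and shows *strong recombination* when the CI
    upper bound is < recomb_upper; other pairs are uninformative.  A candidate
    block is a contiguous range whose endpoint pair is in strong LD and in
    which at least ``strong_fraction`` of informative pairs are strong LD
    rather than recombinant.  Candidates are accepted greedily by decreasing
    length (ties to the leftmost), skipping overlaps.
    """
    ii, jj, _freqs, informative, counts = _pair_freqs(dataset, max_dist)
    strong = np.zeros(ii.size, dtype=bool)
    recomb = np.zeros(ii.size, dtype=bool)
    if informative.any():
        dgrid, mass = _grid_chunked(counts[informative], grid)
        lo, hi = _ci_from_mass(dgrid, mass, (1.0 - coverage) / 2.0)
        strong[informative] = (lo >= ci_lower_min - 1e-12) & (hi >= ci_upper_min - 1e-12)
        recomb[informative] = hi < recomb_upper
    spans = dataset.chromosome_spans()
    out: list[tuple[int, int]] = []
    for _chrom, start, stop in spans:
        in_span = (ii >= start) & (jj < stop)
        chrom_blocks = _gabriel_blocks_one_chrom(
            ii[in_span] - start,
            jj[in_span] - start,
            strong[in_span],
            recomb[in_span],
            informative[in_span],
            stop - start,
            strong_fraction,
        )
        out.extend((start + a, start + b) for a, b in chrom_blocks)
    return LdBlockPartition(
        n_snps=dataset.n_snps,
        blocks=out,
        chromosome_spans=spans,
        algorithm="gabriel",
        params={
            "ci_upper_min": ci_upper_min,
            "ci_lower_min": ci_lower_min,
            "strong_fraction": strong_fraction,
            "recomb_upper": recomb_upper,
            "max_dist": max_dist,
        },
    )


def _grid_chunked(counts: np.ndarray, grid: int, chunk: int = 8192):
    masses = []
    dgrid = None
    for lo in range(0, counts.shape[0], chunk):
        dgrid, mass = _grid_posteriors(counts[lo : lo + chunk], grid=grid)
        masses.append(mass)
    return dgrid, np.concatenate(masses, axis=0)


def _gabriel_blocks_one_chrom(ii, jj, strong, recomb, informative, m, strong_fraction):
    if m < 2 or not strong.any():
        return []
    # dense upper-triangular indicator matrices + 2-D prefix sums give O(1)
    # informative-pair fractions for any candidate range
    s_mat = np.zeros((m, m))
    r_mat = np.zeros((m, m))
    s_mat[ii[strong], jj[strong]] = 1.0
    r_mat[ii[recomb], jj[recomb]] = 1.0
    s_cum = s_mat.cumsum(axis=0).cumsum(axis=1)
    r_cum = r_mat.cumsum(axis=0).cumsum(axis=1)

    def rect(cum, a, b):
        # sum over rows a..b, cols a..b (pairs with a <= i < j <= b)
        total = cum[b, b]
        left = cum[b, a - 1] if a > 0 else 0.0
        top = cum[a - 1, b] if a > 0 else 0.0
        corner = cum[a - 1, a - 1] if a > 0 else 0.0
        return total - left - top + corner

    cand_a = ii[strong]
    cand_b = jj[strong]
    good = []
    for a, b in zip(cand_a, cand_b):
        ns = rect(s_cum, a, b)
        nr = rect(r_cum, a, b)
        if ns + nr > 0 and ns / (ns + nr) >= strong_fraction - 1e-12:
            good.append((a, b))
    # greedy: longest first, ties to the leftmost
    good.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
    occupied = np.zeros(m, dtype=bool)
    blocks = []
    for a, b in good:
        if not occupied[a : b + 1].any():
            blocks.append((a, b + 1))
            occupied[a : b + 1] = True
    return blocks


def solid_spine_blocks(
    dataset: GenotypeDataset,
    dprime_min: float = 0.8,
    max_dist: int = 250,
) -> LdBlockPartition:
    """Solid-spine-of-LD blocks: maximal ranges whose first and last SNP are
    each in |D'| >= dprime_min with every SNP between them (and with each
    other), grown greedily left to right."""
    ii, jj, freqs, informative, _counts = _pair_freqs(dataset, max_dist)
    dp = np.zeros(ii.size)
    dp[informative] = _dprime_from_freqs(freqs[informative])
    blocks: list[tuple[int, int]] = []
    spans = dataset.chromosome_spans()
    band = _band_lookup(dataset.n_snps, max_dist, ii, jj, dp)

    def d_of(i: int, j: int) -> float:
        if j - i > max_dist:
            return 0.0
        return band[j, j - i - 1]

    for _chrom, start, stop in spans:
        a = start
        while a < stop - 1:
            b = a
            while b + 1 < stop:
                nb = b + 1
                if d_of(a, nb) < dprime_min:
                    break
                if any(d_of(k, nb) < dprime_min for k in range(a + 1, nb)):
                    break
                b = nb
            if b > a:
                blocks.append((a, b + 1))
                a = b + 1
            else:
                a += 1
    return LdBlockPartition(
        n_snps=dataset.n_snps,
        blocks=blocks,
        chromosome_spans=spans,
        algorithm="solid_spine",
        params={"dprime_min": dprime_min, "max_dist": max_dist},
    )


def four_gamete_blocks(
    dataset: GenotypeDataset,
    fourth_freq_cutoff: float = 0.01,
    max_dist: int = 250,
) -> LdBlockPartition:
    """Four-gamete blocks: grown left to right, breaking before a SNP whose
    EM haplotype frequencies with any SNP already in the block show all four
    gametes at frequency >= ``fourth_freq_cutoff``."""
    ii, jj, freqs, informative, _counts = _pair_freqs(dataset, max_dist)
    shows_recomb = np.zeros(ii.size, dtype=bool)
    if informative.any():
        shows_recomb[informative] = (
            freqs[informative].min(axis=1) >= fourth_freq_cutoff - 1e-12
        )
    band = _band_lookup(dataset.n_snps, max_dist, ii, jj, shows_recomb.astype(float))
    spans = dataset.chromosome_spans()
    blocks: list[tuple[int, int]] = []
    for _chrom, start, stop in spans:
        a = start
        for j in range(start + 1, stop):
            broke = any(
                band[j, j - k - 1] > 0.5 for k in range(max(a, j - max_dist), j)
            )
            if broke:
                if j - a >= 2:
                    blocks.append((a, j))
                a = j
        if stop - a >= 2:
            blocks.append((a, stop))
    return LdBlockPartition(
        n_snps=dataset.n_snps,
        blocks=blocks,
        chromosome_spans=spans,
        algorithm="four_gamete",
        params={"fourth_freq_cutoff": fourth_freq_cutoff, "max_dist": max_dist},
    )


_ALGORITHMS = {
    "gabriel": gabriel_blocks,
    "spine": solid_spine_blocks,
    "fourgamete": four_gamete_blocks,
}


def chunked_partition(
    dataset: GenotypeDataset, algorithm: str, chunk_size: int, **params
) -> LdBlockPartition:
    """Run a block algorithm on overlapping chunks and stitch the results.

    Each chunk after the first starts at the first SNP of the last full block
    of the previous chunk, so blocks truncated by a chunk boundary are
    re-detected whole — the standard protocol for analysing a chromosome too
    large to fit in memory at once.  On data whose LD range is shorter than
    the chunk size this reproduces the single-pass partition exactly.
    """
    if chunk_size < 2:
        raise ValueError("chunk_size must be >= 2")
    fn = _ALGORITHMS[algorithm]
    spans = dataset.chromosome_spans()
    blocks: list[tuple[int, int]] = []
    for _chrom, start, stop in spans:
        pos = start
        while pos < stop:
            end = min(pos + chunk_size, stop)
            sub = dataset.take_snps(range(pos, end))
            part = fn(sub, **params)
            sub_blocks = [(pos + a, pos + b) for a, b in part.blocks]
            if end >= stop:
                blocks.extend(sub_blocks)
                break
            if sub_blocks:
                *accept, last = sub_blocks
                blocks.extend(accept)
                if last[0] > pos:
                    pos = last[0]  # re-analyse from the start of the last block
                else:
                    blocks.append(last)
                    pos = last[1]
            else:
                pos = end
    return LdBlockPartition(
        n_snps=dataset.n_snps,
        blocks=blocks,
        chromosome_spans=spans,
        algorithm=f"{algorithm}(chunked)",
        params=dict(params, chunk_size=chunk_size),
    )
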