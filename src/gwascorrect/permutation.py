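"""Label-permutation minP null distribution and closed-form FWER corrections.

The permutation minP distribution is the study-wide gold standard: permute
case/control labels B times, run the genome-wide trend scan each time, and
record the minimum p-value.  Its empirical alpha-quantile is the study-wide
significance threshold; its ECDF evaluated at any candidate threshold is that
threshold's "corresponding alpha" (the family-wise error rate it actually
buys).  Bonferroni (alpha/n) and the family-wise error formula
1-(1-alpha)^n cover the independence limit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .association import _prepare_matrix, _trend_from_sums
from .genotype_io import GenotypeDataset

__all__ = [
    "MinPDistribution",
    "permute_minp",
    "perm_threshold",
    "perm_corrected_p",
    "corresponding_alpha",
    "familywise_error",
    "bonferroni_threshold",
    "sidak_threshold",
]


@dataclass
class MinPDistribution:
    """Sorted minimum p-values from B independent label permutations."""

    minp: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.minp = np.sort(np.asarray(self.minp, dtype=np.float64))
        if self.minp.size < 1:
            raise ValueError("empty minP distribution")
        if (self.minp <= 0).any() or (self.minp > 1).any():
            raise ValueError("minP values must lie in (0, 1]")

    @property
    def b(self) -> int:
        return int(self.minp.size)

    def save_tsv(self, path) -> None:
        lines = [f"# B={self.b}", f"# seed={self.seed}", "minp"]
        lines += [repr(float(v)) for v in self.minp]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load_tsv(cls, path) -> "MinPDistribution":
        seed = None
        values = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line == "minp":
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key.strip() == "seed" and val.strip() != "None":
                    seed = int(val)
                continue
            values.append(float(line))
        return cls(minp=np.asarray(values), seed=seed)


def permute_minp(
    dataset: GenotypeDataset,
    labels: np.ndarray | None = None,
    b: int = 10_000,
    seed: int | None = 0,
    batch_size: int = 256,
) -> MinPDistribution:
    """Genome-wide minimum trend-test p-value over B label permutations.

    Monomorphic-in-sample SNPs are excluded from the minimum.  Permutation
    streams are derived from ``seed`` in fixed-size batches, so results are
    reproducible and independent of how batches would be scheduled.
    """
    if labels is None:
        labels = dataset.labels
    if labels is None:
        raise ValueError("no labels supplied")
    y = np.asarray(labels, dtype=np.float64)
    if y.shape != (dataset.n_samples,):
        raise ValueError("labels length does not match sample count")
    if not (((y == 0) | (y == 1)).all() and (y == 0).any() and (y == 1).any()):
        raise ValueError("labels must be binary with both classes present")
    if b < 1:
        raise ValueError("need at least one permutation")

    X0, mask, n, sx, sxx = _prepare_matrix(dataset.dosages)
    var_x = sxx - sx * sx / np.maximum(n, 1)
    testable = var_x > 1e-10
    if not testable.any():
        raise ValueError("dataset has zero testable (polymorphic) SNPs")
    complete = bool((mask == 1.0).all())

    n_batches = (b + batch_size - 1) // batch_size
    streams = np.random.SeedSequence(seed).spawn(n_batches)
    out = np.empty(b)
    pos = 0
    for child in streams:
        rng = np.random.default_rng(child)
        nb = min(batch_size, b - pos)
        perms = rng.permuted(np.tile(y, (nb, 1)), axis=1)
        sxy = perms @ X0  # (nb, m)
        if complete:
            sy = np.full((nb, 1), y.sum())
        else:
            sy = perms @ mask
        _, p, _ = _trend_from_sums(sxy, sy, n[None, :], sx[None, :], sxx[None, :])
        p = np.where(testable[None, :], p, np.inf)
        out[pos : pos + nb] = p.min(axis=1)
        pos += nb
    return MinPDistribution(minp=out, seed=seed)


def _quantile_index(alpha: float, b: int) -> int:
    """Order-statistic index (0-based) of the conservative alpha-quantile:
    the ceil(alpha*B)-th smallest value."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    k = math.ceil(alpha * b - 1e-9)
    return max(k, 1) - 1


def perm_threshold(dist: MinPDistribution, alpha: float = 0.05) -> float:
    """Empirical alpha-quantile of the minP distribution: the per-test
    threshold with estimated study-wide error alpha."""
    return float(dist.minp[_quantile_index(alpha, dist.b)])


def perm_corrected_p(dist: MinPDistribution, p) -> float | np.ndarray:
    """Permutation-corrected (study-wide) p-value: (#{minP <= p} + 1)/(B + 1)."""
    p_arr = np.asarray(p, dtype=float)
    if (p_arr < 0).any() or (p_arr > 1).any():
        raise ValueError("p must lie in [0, 1]")
    count = np.searchsorted(dist.minp, p_arr, side="right")
    out = (count + 1.0) / (dist.b + 1.0)
    out = np.where(p_arr >= 1.0, 1.0, np.minimum(out, 1.0))
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


def corresponding_alpha(dist: MinPDistribution, threshold: float) -> float:
    """ECDF of the minP distribution at ``threshold``: the study-wide
    significance level a per-test threshold actually corresponds to."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return float(np.searchsorted(dist.minp, threshold, side="right") / dist.b)


def familywise_error(alpha: float, n: int) -> float:
    """Probability of at least one false positive among n independent tests
    at per-test level alpha: 1 - (1 - alpha)^n."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if n < 0 or int(n) != n:
        raise ValueError("n must be a non-negative integer")
    return float(-math.expm1(n * math.log1p(-alpha))) if alpha < 1.0 else (1.0 if n else 0.0)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests


def sidak_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold 1 - (1 - alpha)^(1/n) (exact under independence)."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return float(-math.expm1(math.log1p(-alpha) / n_tests))
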