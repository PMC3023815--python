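"""Per-SNP case/control association: the Cochran-Armitage (Mantel) trend test.

With additive scores (0, 1, 2) on genotype dosage x and case indicator y the
signed statistic is

    Z = sum_i x_i (y_i - ybar) / sqrt( ybar (1 - ybar) sum_i (x_i - xbar)^2 )

over pairwise-complete (non-missing) samples, asymptotically standard normal
under the null; Z^2 is the usual 1-df trend chi-square.  Two-sided p-values
throughout.  SNPs with zero genotype variance in the analysed samples are
flagged monomorphic and reported with Z = 0, p = 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genotype_io import MISSING, GenotypeDataset

__all__ = ["TrendResult", "trend_test", "assoc_scan"]

# genotype variance below this (in raw sum-of-squares units) counts as zero
_VAR_TOL = 1e-10
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class TrendResult:
    z: float
    p: float
    n_used: int
    monomorphic: bool


def _prepare_matrix(X: np.ndarray):
    """Split a dosage matrix into zero-filled values and an observation mask
    plus the per-column sums the trend statistic needs."""
    X = np.asarray(X)
    mask = (X != MISSING).astype(np.float64)
    X0 = np.where(X == MISSING, 0, X).astype(np.float64)
    n = mask.sum(axis=0)
    sx = X0.sum(axis=0)
    sxx = (X0 * X0).sum(axis=0)
    return X0, mask, n, sx, sxx


def _trend_from_sums(sxy, sy, n, sx, sxx):
    """Vectorised trend Z and p from sufficient statistics.

    All arguments broadcast; returns (z, p, monomorphic) where monomorphic
    also covers columns with no case/control contrast among used samples.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = sy / n
        var_x = sxx - sx * sx / n
        num = sxy - sx * ybar
        den2 = ybar * (1.0 - ybar) * var_x
        z = num / np.sqrt(den2)
    degenerate = ~(den2 > _VAR_TOL)
    z = np.where(degenerate, 0.0, z)
    p = np.clip(2.0 * norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    p = np.where(degenerate, 1.0, p)
    mono = ~(var_x > _VAR_TOL)
    return z, p, degenerate | mono


def trend_test(dosages: np.ndarray, labels: np.ndarray) -> TrendResult:
    """Trend test for one SNP; missing dosages are dropped pairwise."""
    x = np.asarray(dosages)
    y = np.asarray(labels)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dosages and labels must be 1-D and the same length")
    if ((y != 0) & (y != 1)).any():
        raise ValueError("labels must be binary 0/1")
    used = x != MISSING
    yu = y[used]
    if used.sum() == 0 or not ((yu == 0).any() and (yu == 1).any()):
        raise ValueError("need at least one case and one control among used samples")
    X0, mask, n, sx, sxx = _prepare_matrix(x[:, None])
    yf = y.astype(np.float64)
    sxy = yf @ X0
    sy = yf @ mask
    z, p, mono = _trend_from_sums(sxy, sy, n, sx, sxx)
    return TrendResult(
        z=float(z[0]), p=float(p[0]), n_used=int(n[0]), monomorphic=bool(mono[0])
    )


def assoc_scan(dataset: GenotypeDataset, labels: np.ndarray | None = None) -> pd.DataFrame:
    """Trend-test every SNP against the case/control labels.

    Returns a DataFrame with one row per SNP, in map order: snp_id, chrom,
    pos, z, p, n_used, monomorphic.
    """
    if labels is None:
        labels = dataset.labels
    if labels is None:
        raise ValueError("dataset has no labels and none were supplied")
    y = np.asarray(labels)
    if y.shape != (dataset.n_samples,):
        raise ValueError("labels length does not match sample count")
    if ((y != 0) & (y != 1)).any():
        raise ValueError("labels must be binary 0/1 for association scans")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("need at least one case and one control")
    X0, mask, n, sx, sxx = _prepare_matrix(dataset.dosages)
    yf = y.astype(np.float64)
    sxy = yf @ X0
    sy = yf @ mask
    z, p, mono = _trend_from_sums(sxy, sy, n, sx, sxx)
    return pd.DataFrame(
        {
            "snp_id": dataset.snp_ids(),
            "chrom": [s.chromosome for s in dataset.snps],
            "pos": [s.position for s in dataset.snps],
            "z": z,
            "p": p,
            "n_used": n.astype(int),
            "monomorphic": mono,
        }
    )
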