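"""Method comparison: gauge every correction's threshold against the
permutation minP distribution.

``compare_methods`` runs the configured corrections — Bonferroni,
permutation, the MVN sliding-window approximation, simpleM, and the three
LD-block-count Bonferronis — on one dataset, then reads each threshold's
*corresponding alpha* (the study-wide error it actually buys) off a single
shared permutation minP distribution.  ``subset_delta`` repeats the
comparison on a case-subsampled dataset and reports how much each method's
threshold moves, a probe of sample-size sensitivity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effective_tests import choose_regions, simplem_meff
from .genotype_io import GenotypeDataset
from .ld_blocks import (
    LdBlockPartition,
    block_test_count,
    four_gamete_blocks,
    gabriel_blocks,
    solid_spine_blocks,
)
from .mvn import band_correlation, mvn_threshold, sample_null_minp
from .permutation import (
    MinPDistribution,
    bonferroni_threshold,
    corresponding_alpha,
    perm_threshold,
    permute_minp,
)

__all__ = ["EvalConfig", "ComparisonReport", "SubsetDelta", "compare_methods", "subset_delta"]

ALL_METHODS = ("bonferroni", "permutation", "simplem", "mvn", "gabriel", "fourgamete", "spine")


@dataclass
class EvalConfig:
    """Knobs for one comparison run; defaults follow the package's standard
    operating point (see docs/methods.md for rationale)."""

    alpha: float = 0.05
    methods: tuple[str, ...] = ALL_METHODS
    b_permutations: int = 10_000
    mvn_iterations: int = 10_000
    mvn_window: int = 100
    simplem_variance_fraction: float = 0.995
    simplem_target_region_size: int = 5000
    ld_max_dist: int = 250
    gabriel_params: dict = field(default_factory=dict)
    spine_params: dict = field(default_factory=dict)
    fourgamete_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class ComparisonReport:
    """Per-method (threshold, corresponding alpha) rows plus run metadata —
    the machine analogue of a published method-comparison table."""

    table: pd.DataFrame
    minp: MinPDistribution
    config: EvalConfig
    n_snps: int
    n_samples: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class SubsetDelta:
    """Per-method threshold change (subset minus full) under case subsampling."""

    table: pd.DataFrame
    n_cases: int
    n_controls: int
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _method_thresholds(
    dataset: GenotypeDataset, labels: np.ndarray, config: EvalConfig
) -> tuple[dict[str, tuple[float, str]], MinPDistribution]:
    """Compute each configured method's per-test threshold.

    Returns ({method: (threshold, parameter string)}, shared minP dist).
    The permutation distribution is computed whenever any corresponding-alpha
    is wanted, which is always.
    """
    alpha = config.alpha
    minp = permute_minp(
        dataset, labels, b=config.b_permutations, seed=config.seed
    )
    results: dict[str, tuple[float, str]] = {}
    errors: dict[str, str] = {}
    spine_part: LdBlockPartition | None = None
    for method in config.methods:
        try:
            if method == "bonferroni":
                thr = bonferroni_threshold(alpha, dataset.n_snps)
                desc = f"n={dataset.n_snps}"
            elif method == "permutation":
                thr = perm_threshold(minp, alpha)
                desc = f"B={config.b_permutations}"
            elif method == "mvn":
                corr = band_correlation(dataset, window=config.mvn_window)
                sample = sample_null_minp(
                    corr, n_iter=config.mvn_iterations, seed=config.seed + 1
                )
                thr = mvn_threshold(sample, alpha)
                desc = f"window={config.mvn_window}, iters={config.mvn_iterations}"
            elif method == "simplem":
                if spine_part is None:
                    spine_part = solid_spine_blocks(
                        dataset, max_dist=config.ld_max_dist, **config.spine_params
                    )
                regions = choose_regions(
                    dataset, spine_part, target_size=config.simplem_target_region_size
                )
                meff = simplem_meff(dataset, regions, c=config.simplem_variance_fraction)
                thr = bonferroni_threshold(alpha, meff.total)
                desc = (
                    f"M_eff={meff.total}, C={config.simplem_variance_fraction}, "
                    f"regions={len(regions)}"
                )
            elif method == "gabriel":
                part = gabriel_blocks(
                    dataset, max_dist=config.ld_max_dist, **config.gabriel_params
                )
                n_tests = block_test_count(part)
                thr = bonferroni_threshold(alpha, n_tests)
                desc = f"blocks={part.n_blocks}, singletons={part.n_singletons}"
            elif method == "spine":
                spine_part = solid_spine_blocks(
                    dataset, max_dist=config.ld_max_dist, **config.spine_params
                )
                n_tests = block_test_count(spine_part)
                thr = bonferroni_threshold(alpha, n_tests)
                desc = f"blocks={spine_part.n_blocks}, singletons={spine_part.n_singletons}"
            elif method == "fourgamete":
                part = four_gamete_blocks(
                    dataset, max_dist=config.ld_max_dist, **config.fourgamete_params
                )
                n_tests = block_test_count(part)
                thr = bonferroni_threshold(alpha, n_tests)
                desc = f"blocks={part.n_blocks}, singletons={part.n_singletons}"
            results[method] = (thr, desc)
        except Exception as exc:  # record per-row failure, let others proceed
            errors[method] = str(exc)
    for method, msg in errors.items():
        results[method] = (float("nan"), f"error: {msg}")
    return results, minp


def compare_methods(
    dataset: GenotypeDataset, labels: np.ndarray | None = None, config: EvalConfig | None = None
) -> ComparisonReport:
    """Run every configured correction on one dataset and gauge each
    threshold against the shared permutation minP distribution.

    Rows are sorted by threshold ascending (most conservative first).
    """
    config = config or EvalConfig()
    if labels is None:
        labels = dataset.labels
    if labels is None:
        raise ValueError("no labels supplied")
    results, minp = _method_thresholds(dataset, labels, config)
    rows = []
    for method in config.methods:
        thr, desc = results[method]
        rows.append(
            {
                "method": method,
                "parameters": desc,
                "threshold": thr,
                "corresponding_alpha": (
                    corresponding_alpha(minp, thr) if np.isfinite(thr) else float("nan")
                ),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "threshold", kind="stable", na_position="last"
    ).reset_index(drop=True)
    return ComparisonReport(
        table=table,
        minp=minp,
        config=config,
        n_snps=dataset.n_snps,
        n_samples=dataset.n_samples,
    )


def subset_delta(
    dataset: GenotypeDataset,
    labels: np.ndarray | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    seed: int = 0,
    config: EvalConfig | None = None,
) -> SubsetDelta:
    """Threshold change when the analysis is repeated on a random sample of
    ``n_cases`` cases and ``n_controls`` controls (drawn without replacement;
    defaults keep every control).  delta = threshold_subset - threshold_full.
    """
    config = config or EvalConfig()
    if labels is None:
        labels = dataset.labels
    if labels is None:
        raise ValueError("no labels supplied")
    labels = np.asarray(labels)
    case_idx = np.flatnonzero(labels == 1)
    control_idx = np.flatnonzero(labels == 0)
    n_cases = len(case_idx) if n_cases is None else n_cases
    n_controls = len(control_idx) if n_controls is None else n_controls
    if n_cases > len(case_idx) or n_controls > len(control_idx):
        raise ValueError("requested subset exceeds available cases/controls")
    rng = np.random.default_rng(seed)
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(case_idx, size=n_cases, replace=False),
                rng.choice(control_idx, size=n_controls, replace=False),
            ]
        )
    )
    sub = dataset.take_samples(keep)
    sub_labels = labels[keep]
    # same config (including seeds) for both runs: the subset re-analysis is
    # the identical procedure on fewer samples, so a full-size "subset"
    # reproduces the full-data thresholds exactly
    full_res, _ = _method_thresholds(dataset, labels, config)
    sub_res, _ = _method_thresholds(sub, sub_labels, config)
    rows = []
    for method in config.methods:
        t_full = full_res[method][0]
        t_sub = sub_res[method][0]
        rows.append(
            {
                "method": method,
                "threshold_full": t_full,
                "threshold_subset": t_sub,
                "delta": t_sub - t_full,
            }
        )
    return SubsetDelta(
        table=pd.DataFrame(rows), n_cases=n_cases, n_controls=n_controls, seed=seed
    )
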