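"""Two-locus EM, D' statistics and CIs, and the three block algorithms."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwascorrect.ld_blocks import (
    HaplotypeFreqs,
    LdBlockPartition,
    TwoLocusCounts,
    _grid_posteriors,
    block_test_count,
    chunked_partition,
    dprime_ci,
    em_haplotype_freqs,
    four_gamete_blocks,
    gabriel_blocks,
    ld_stats,
    pair_loglik,
    solid_spine_blocks,
)
from gwascorrect.synthetic import HaplotypeBlock, HaplotypePanel, simulate_genotypes

from conftest import independent_snp_panel, make_dataset, mixed_pool_panel


def table_from_haplotype_draws(freqs, n, seed):
    """Sample N genotype pairs from two independent haplotype draws."""
    rng = np.random.default_rng(seed)
    hap_alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    draws = rng.choice(4, size=(n, 2), p=freqs)
    g = hap_alleles[draws[:, 0]] + hap_alleles[draws[:, 1]]
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (g[:, 0], g[:, 1]), 1)
    return TwoLocusCounts(table=table)


def grid_search_loglik_max(counts, n_grid=2001, refinements=3):
    """Brute-force likelihood maximum over p_AB at the observed margins,
    sharpened by successive grid refinement (final resolution ~1e-10)."""
    p_a, p_b = counts.allele_freqs()
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)

    def ll_of(pab):
        f = np.array([pab, p_a - pab, p_b - pab, 1 - p_a - p_b + pab])
        f = np.clip(f, 0.0, 1.0)
        f = f / f.sum()
        return pair_loglik(counts, HaplotypeFreqs(*f))

    best = -np.inf
    for _ in range(refinements):
        grid = np.linspace(lo, hi, n_grid)
        lls = np.array([ll_of(p) for p in grid])
        k = int(lls.argmax())
        best = max(best, float(lls[k]))
        lo = grid[max(k - 2, 0)]
        hi = grid[min(k + 2, n_grid - 1)]
    return best


class TestEm:
    def test_phase_unambiguous_table_matches_direct_counting(self):
        # no double heterozygotes: haplotype counts are read off the table
        table = np.array([[10, 4, 2], [3, 0, 5], [1, 2, 8]])
        counts = TwoLocusCounts(table=table)
        freqs = em_haplotype_freqs(counts)
        hap = np.zeros(4)  # AB, Ab, aB, ab
        for g1 in range(3):
            for g2 in range(3):
                n = table[g1, g2]
                a1 = [1] * g1 + [0] * (2 - g1)
                a2 = [1] * g2 + [0] * (2 - g2)
                for al1, al2 in [(a1[0], a2[0]), (a1[1], a2[1])]:
                    idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(al1, al2)]
                    hap[idx] += n
        hap /= hap.sum()
        assert freqs.as_array() == pytest.approx(hap, abs=1e-9)

    def test_all_double_het_reaches_grid_search_maximum(self):
        counts = TwoLocusCounts(table=np.array([[0, 0, 0], [0, 40, 0], [0, 0, 0]]))
        freqs = em_haplotype_freqs(counts)
        ll_em = pair_loglik(counts, freqs)
        assert ll_em == pytest.approx(grid_search_loglik_max(counts), abs=1e-6)

    @pytest.mark.parametrize("true_f", [(0.4, 0.1, 0.1, 0.4), (0.7, 0.1, 0.15, 0.05),
                                        (0.25, 0.25, 0.25, 0.25)])
    def test_recovers_known_frequencies_at_large_n(self, true_f):
        counts = table_from_haplotype_draws(np.array(true_f), 10_000, seed=5)
        freqs = em_haplotype_freqs(counts)
        est = freqs.as_array()
        best = min(
            np.abs(est - np.array(true_f)).max(),
            # the all-double-het direction is phase-symmetric; accept the
            # mirrored solution when the data cannot distinguish them
            np.abs(est[[1, 0, 3, 2]] - np.array(true_f)).max()
            if true_f == (0.25, 0.25, 0.25, 0.25) else np.inf,
        )
        assert best < 0.02

    def test_em_matches_grid_search_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(12):
            table = rng.integers(0, 12, size=(3, 3))
            counts = TwoLocusCounts(table=table + (table.sum() == 0))
            p_a, p_b = counts.allele_freqs()
            if p_a in (0, 1) or p_b in (0, 1):
                continue
            freqs = em_haplotype_freqs(counts)
            assert pair_loglik(counts, freqs) >= grid_search_loglik_max(counts) - 1e-6

    def test_likelihood_monotone_in_iterations(self):
        counts = table_from_haplotype_draws(np.array([0.35, 0.15, 0.2, 0.3]), 200, seed=11)
        lls = []
        for k in range(1, 15):
            freqs = em_haplotype_freqs(counts, tol=0.0, max_iter=k)
            lls.append(pair_loglik(counts, freqs))
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))


class TestLdStats:
    def test_complete_coupling(self):
        pt = ld_stats(HaplotypeFreqs(0.5, 0.0, 0.0, 0.5))
        assert pt.d_prime == pytest.approx(1.0)
        assert pt.r2 == pytest.approx(1.0)

    def test_independence(self):
        pt = ld_stats(HaplotypeFreqs(0.35, 0.35, 0.15, 0.15))
        assert pt.d == pytest.approx(0.0, abs=1e-12)
        assert pt.d_prime == pytest.approx(0.0, abs=1e-9)
        assert pt.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_expanded_formulas(self):
        f = HaplotypeFreqs(0.4, 0.1, 0.1, 0.4)
        pt = ld_stats(f)
        d = 0.4 - 0.5 * 0.5
        assert pt.d == pytest.approx(d)
        assert pt.d_prime == pytest.approx(d / min(0.5 * 0.5, 0.5 * 0.5))
        assert pt.r2 == pytest.approx(d * d / 0.5**4)

    def test_monomorphic_marginal_rejected(self):
        with pytest.raises(ValueError):
            ld_stats(HaplotypeFreqs(0.6, 0.4, 0.0, 0.0))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_r2_never_exceeds_dprime(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(4))
        p_a, p_b = f[0] + f[1], f[0] + f[2]
        if min(p_a, 1 - p_a, p_b, 1 - p_b) < 1e-3:
            return
        pt = ld_stats(HaplotypeFreqs(*f))
        assert pt.r2 <= pt.d_prime + 1e-9


class TestDprimeCi:
    def test_grid_mass_normalised(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            table = rng.integers(0, 10, size=(3, 3)) + 1
            _, mass = _grid_posteriors(table.reshape(1, 9))
            assert mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_complete_ld_concentrates_with_sample_size(self):
        prev = 0.0
        for n, seed in [(50, 1), (500, 2), (5000, 3)]:
            counts = table_from_haplotype_draws(np.array([0.6, 0.0, 0.0, 0.4]), n, seed)
            lo, hi = dprime_ci(counts)
            assert hi == pytest.approx(1.0)
            assert lo >= prev - 0.05
            prev = lo
        assert lo >= 0.98

    def test_tiny_sample_is_uninformative(self):
        counts = TwoLocusCounts(table=np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1]]))
        lo, hi = dprime_ci(counts)
        assert lo <= 0.1
        assert hi - lo > 0.5


def ground_truth_dataset(seed, n_blocks=25, n_samples=1200):
    panel = mixed_pool_panel(n_blocks, 5, seed=seed)
    ds = simulate_genotypes(panel, n_samples, seed=seed + 1)
    return panel, ds


class TestBlockAlgorithms:
    def test_two_haplotype_block_recovered_by_all(self):
        panel = HaplotypePanel(blocks=[
            HaplotypeBlock(haplotypes=np.array([[1, 0, 1, 0, 1], [0, 1, 0, 1, 0]]),
                           weights=np.array([0.6, 0.4])),
        ])
        ds = simulate_genotypes(panel, 2000, seed=21)
        for fn in (gabriel_blocks, solid_spine_blocks, four_gamete_blocks):
            part = fn(ds)
            assert part.blocks == [(0, 5)], fn.__name__

    def test_independent_snps_yield_singletons(self):
        panel = independent_snp_panel(60, seed=23)
        ds = simulate_genotypes(panel, 800, seed=24)
        for fn in (gabriel_blocks, solid_spine_blocks, four_gamete_blocks):
            part = fn(ds, max_dist=20)
            assert part.n_blocks == 0, fn.__name__
            assert block_test_count(part) == 60

    def test_panel_blocks_mostly_recovered(self):
        panel, ds = ground_truth_dataset(seed=25)
        truth = set(panel.block_spans())
        for fn in (gabriel_blocks, solid_spine_blocks, four_gamete_blocks):
            part = fn(ds, max_dist=20)
            recovered = truth & set(part.blocks)
            assert len(recovered) >= 0.8 * len(truth), fn.__name__

    def test_planted_recombinant_splits_four_gamete_block(self):
        # two half-blocks joined by 5% recombinant haplotypes: across the
        # SNP 2|3 boundary all four gametes (10, 01, 11, 00) segregate
        haps = np.array([
            [1, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 1],
            [1, 1, 1, 1, 1, 1],
            [0, 0, 0, 0, 0, 0],
        ])
        panel = HaplotypePanel(blocks=[
            HaplotypeBlock(haplotypes=haps, weights=np.array([0.45, 0.45, 0.05, 0.05]))
        ])
        ds = simulate_genotypes(panel, 4000, seed=27)
        part = four_gamete_blocks(ds, fourth_freq_cutoff=0.01)
        # no block may span the recombination point between SNP 2 and SNP 3
        assert all(stop <= 3 or start >= 3 for start, stop in part.blocks)
        assert len(part.blocks) == 2

    def test_lower_cutoff_enlarges_recombination_set(self):
        _, ds = ground_truth_dataset(seed=29, n_blocks=15, n_samples=600)
        strict = four_gamete_blocks(ds, fourth_freq_cutoff=0.005, max_dist=20)
        # structural validity of the variant partition
        assert strict.n_blocks + strict.n_singletons <= ds.n_snps
        covered = sum(b - a for a, b in strict.blocks)
        assert covered + strict.n_singletons == ds.n_snps

    def test_gabriel_tighter_ci_bound_shrinks_strong_set(self):
        _, ds = ground_truth_dataset(seed=31, n_blocks=15, n_samples=600)
        loose = gabriel_blocks(ds, ci_lower_min=0.70, max_dist=20)
        tight = gabriel_blocks(ds, ci_lower_min=0.85, max_dist=20)
        covered_loose = sum(b - a for a, b in loose.blocks)
        covered_tight = sum(b - a for a, b in tight.blocks)
        assert covered_tight <= covered_loose + 1  # tightening cannot grow coverage much
        for part in (loose, tight):
            assert block_test_count(part) == part.n_blocks + part.n_singletons

    def test_spine_with_duplicated_trio_at_dprime_one(self):
        rng = np.random.default_rng(33)
        col = rng.integers(0, 3, 400).astype(np.int8)
        other = rng.integers(0, 3, 400).astype(np.int8)
        ds = make_dataset(np.column_stack([col, col, col, other]))
        part = solid_spine_blocks(ds, dprime_min=1.0)
        assert (0, 3) in part.blocks

    def test_spine_variant_partitions_remain_valid(self):
        _, ds = ground_truth_dataset(seed=35, n_blocks=15, n_samples=600)
        for dmin in (0.80, 0.95):
            part = solid_spine_blocks(ds, dprime_min=dmin, max_dist=20)
            covered = sum(b - a for a, b in part.blocks)
            assert covered + part.n_singletons == ds.n_snps
            assert all(b - a >= 2 for a, b in part.blocks)


class TestPartitionBookkeeping:
    def test_block_test_count_cases(self):
        spans = [("1", 0, 57)]
        all_single = LdBlockPartition(n_snps=57, blocks=[], chromosome_spans=spans)
        assert block_test_count(all_single) == 57
        one_block = LdBlockPartition(n_snps=57, blocks=[(0, 57)], chromosome_spans=spans)
        assert block_test_count(one_block) == 1
        mixed = LdBlockPartition(
            n_snps=57, blocks=[(i * 5, i * 5 + 5) for i in range(10)],
            chromosome_spans=spans,
        )
        assert block_test_count(mixed) == 10 + 7

    def test_invalid_partitions_rejected(self):
        spans = [("1", 0, 10)]
        with pytest.raises(ValueError):
            LdBlockPartition(n_snps=10, blocks=[(0, 1)], chromosome_spans=spans)
        with pytest.raises(ValueError):
            LdBlockPartition(n_snps=10, blocks=[(0, 4), (3, 7)], chromosome_spans=spans)

    def test_chunked_analysis_reproduces_single_pass(self):
        panel, ds = ground_truth_dataset(seed=37, n_blocks=30, n_samples=700)
        for algorithm in ("gabriel", "spine", "fourgamete"):
            single = {
                "gabriel": gabriel_blocks,
                "spine": solid_spine_blocks,
                "fourgamete": four_gamete_blocks,
            }[algorithm](ds, max_dist=20)
            stitched = chunked_partition(ds, algorithm, chunk_size=40, max_dist=20)
            assert stitched.blocks == single.blocks, algorithm
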