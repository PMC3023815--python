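# Methods

This note documents the statistical models, algorithmic conventions and
numerical choices behind `gwascorrect`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Genotype container and QC

Genotypes live in a samples × SNPs dosage matrix coded 0/1/2 (copies of the
B allele) with −1 for missing, columns strictly sorted by (chromosome,
position).  PLINK text `.ped`/`.map` is the interchange format; the `.map`
carries no allele columns, so allele orientation is fixed by first
appearance in the file: the first non-missing allele seen at a SNP becomes
allele A and dosage counts the other.  A consequence is that a column whose
first genotype is homozygous-B re-reads with swapped labels and complemented
dosages; `GenotypeDataset.equals` treats that orientation flip as equality
because it is the same genetic information.

Per-SNP QC keeps a SNP iff call rate > 0.95, MAF ≥ 0.01, and exact
Hardy–Weinberg p ≥ `hwe_alpha`.  The HWE test is the exact conditional test:
enumerate every heterozygote count achievable at the observed allele counts,
weight by the multinomial coefficient times 2^het, and sum the
probabilities no larger than the observed configuration's (a relative slack
of 1e−12 guards the tie comparison).  The exact test is preferred over the
asymptotic chi-square because it is well defined at any sample size,
including the tiny tables used in tests.  `hwe_alpha` defaults to 1e−6, a
common screening value; it is a free parameter because no single convention
exists.  Removal accounting uses the precedence call rate → MAF → HWE; the
surviving set is order-independent.

## Trend test

Association is the 1-df Cochran–Armitage (Mantel) trend test with additive
scores (0, 1, 2):

    Z = Σ xᵢ(yᵢ − ȳ) / sqrt( ȳ(1 − ȳ) Σ (xᵢ − x̄)² )

over pairwise-complete samples, two-sided p = 2Φ(−|Z|).  Z² is algebraically
identical to the textbook count-based trend chi-square (the suite verifies
this, and verifies the exact permutation distribution of the statistic
against brute-force label enumeration at n = 16).  Missing dosages are
dropped per SNP, which preserves per-SNP exchangeability under label
permutation.  Zero genotype variance in the analysed samples yields Z = 0,
p = 1 and a monomorphic flag; such SNPs are excluded from genome-wide
minima.

## Permutation minP

`permute_minp` draws B full label permutations, scans all SNPs per
permutation, and records the minimum p.  The whole scan is three matrix
products per batch of permutations, so B = 10,000 on desk-scale data costs
seconds.  Conventions, shared by the MVN analogue:

* threshold at level α = the ⌈αB⌉-th smallest minP (conservative order
  statistic);
* corrected p = (#{minP ≤ p} + 1)/(B + 1) (add-one smoothing; never zero);
* corresponding α of a threshold t = ECDF at t, #{minP ≤ t}/B.

Permutation streams derive from one seed in fixed-size batches, so results
do not depend on scheduling.  Closed forms `familywise_error`
(1 − (1 − α)^n), `bonferroni_threshold` (α/n) and `sidak_threshold`
(1 − (1 − α)^(1/n)) cover the independence limit and reference arithmetic.

## MVN sliding-window null

Under label permutation, the correlation between trend statistics at two
SNPs equals the Pearson correlation of their dosage columns — for binary or
quantitative phenotypes alike, which is why a quantitative-trait formulation
applies unchanged to case/control data.  `band_correlation` estimates that
correlation in a band of width `window` per chromosome (pairwise-complete;
monomorphic columns flagged and excluded).  `sample_null_minp` then draws
Z ~ MVN(0, banded Σ) sequentially: each Zᵢ is normal given the previous
min(window−1, i−1) coordinates, with regression coefficients solved from the
band (ridge 1e−6 on the local system, and conditional variances floored at
1e−6 so duplicated SNPs cannot make the band singular).  Per replicate the
minimum two-sided p is recorded; thresholds and corrected p-values reuse the
permutation conventions.

The window defaults to 100 SNPs.  Any window wider than the longest LD
stretch is sufficient; the suite checks that widening the window beyond the
simulated block size moves the threshold by less than its own Monte-Carlo
error.  Cost is O(window² · SNPs) for the plan plus O(iterations · window ·
SNPs) for sampling.

## simpleM (effective number of tests)

For a region of SNPs, the composite LD correlation matrix is the Pearson
correlation of dosage columns (phase-free; pairwise-complete; monomorphic
columns contribute an isolated unit eigenvalue).  M_eff of the region is the
smallest m whose m largest eigenvalues sum to ≥ C of the trace, C = 0.995;
eigenvalues as low as −1e−8 are clipped to zero (rounding debris from
pairwise-complete estimation), anything lower is an error.  The genome-wide
M_eff is the sum over regions, and the correction is Bonferroni at α/M_eff.

Regions are cut by `choose_regions`: whole LD blocks (solid-spine partition
by default, the cheapest) are accumulated greedily until a target size is
reached, so no region splits a block.  Two practical rules matter:

* **Keep regions well below the sample count.**  A sample correlation matrix
  from n individuals has rank ≤ n − 1, so a region of size approaching n has
  its M_eff capped mechanically by rank, not by LD; the eigenvalue rule is
  only meaningful for regions ≪ n.  The package's tests use regions of ~100
  SNPs at n ≥ 500 for this reason.
* **Totals are integers.**  Each region's M_eff rounds up, so re-cutting the
  genome into more regions drifts the total up by ~1 count per extra
  boundary.  On a 1,000-SNP panel (total M_eff ≈ 350) re-cuts move the total
  well under 1%; on very small panels the ±1 granularity can exceed 1%.

## Pairwise LD and haplotype blocks

Two-locus haplotype frequencies come from the standard EM for unphased
genotypes: every 3×3 genotype cell is phase-unambiguous except the double
heterozygote, whose mass is split between cis and trans phase each E-step in
proportion to the current frequency products.  The EM is vectorised across
all pairs in a window simultaneously.  Initialisation is linkage equilibrium
plus a small positive-D perturbation: the LE point is a stationary saddle
for phase-symmetric tables (e.g. all double heterozygotes), and the nudge
lets EM reach a maximum there; the tie toward the coupling phase is a
documented convention (the two maxima have identical likelihood).
Convergence is max frequency change < 1e−8, 1,000 iterations, with a
non-convergence flag.  The suite verifies the EM likelihood against a
refined grid search and checks monotonicity of the likelihood per iteration.

From frequencies: D = p_AB − p_A p_B; D′ = |D|/D_max with the standard
marginal bound; r² = D²/(p_A p_a p_B p_b).  The |D′| confidence interval is
a likelihood grid: with allele frequencies fixed at their observed values
and the pair oriented so the EM estimate of D is non-negative, the genotype
table's likelihood is evaluated at 101 values of |D′| in [0, 1], normalised
to unit mass, and the bounds cut (1 − coverage)/2 strict tails on each side
(coverage 0.90, i.e. 5%/95% bounds — the convention of the standard
block-calling software; a single-point mass collapses the interval).

Block definitions, with their conventional parameters:

* **Gabriel**: a pair is in strong LD if CI_low ≥ 0.70 and CI_high ≥ 0.98,
  and shows strong recombination if CI_high < 0.90; others are
  uninformative.  A candidate block is a range whose endpoint pair is in
  strong LD and in which ≥ 95% of informative pairs are strong rather than
  recombinant ("5% of informative markers" is read as the tolerated
  recombinant fraction — the opposite reading would accept any region).
  Candidates are accepted longest-first (ties leftmost), skipping overlaps;
  2-D prefix sums over the pair-classification matrices make each
  candidate's fraction O(1).
* **Solid spine of LD**: maximal ranges whose first and last SNP each have
  D′ ≥ 0.8 with every SNP between them (and with each other), grown greedily
  left to right.
* **Four-gamete**: blocks grow left to right and break before a SNP whose EM
  haplotype frequencies with any SNP already in the block show all four
  gametes at frequency ≥ 1%.

The test count of a partition is blocks + singleton SNPs, used in
`bonferroni_threshold`.  Pairs are only evaluated within a per-chromosome
index window (`max_dist`, default 250 SNPs); the synthetic panels carry no
longer-range LD, and desk-scale runs use smaller windows for speed.
`chunked_partition` implements the stitching protocol for memory-limited
runs — each chunk restarts at the first SNP of the previous chunk's last
block — and reproduces the single-pass partition exactly when LD is shorter
than the chunk.

Known behaviours worth noting: the four-gamete test cannot see recombination
between rare SNPs (the minor–minor haplotype sits below any frequency
cutoff), so independence checks use common variants; Gabriel fragments an
occasional true block when a rare haplotype leaves some pair CIs too wide to
be informative.  Both match the behaviour of the standard implementations.

## Synthetic data

The generator is a haplotype-pool model chosen over coalescent simulation
for exact control of block boundaries and closed-form oracles.  The genome
is `n_blocks` independent blocks; block b carries a pool of K distinct
haplotypes with Dirichlet(1) weights; a diploid sample is two independent
haplotype draws per block, dosage their sum, no missingness.  Haplotype
columns are drawn uniformly over {0,1}^K and rejected until (a) the implied
population MAF of every SNP is ≥ `maf_min` (0.01) and (b) no within-block
SNP pair realises all four gametes.  Constraint (b) is the package's design
choice: a pool containing a fourth gamete is statistically indistinguishable
from recombination inside the block, which would destroy the ground-truth
partition the block algorithms are tested against.  With it, every
within-block pair has |D′| = 1 while r² varies with the pool — the regime in
which "number of blocks" and "number of effective tests" genuinely diverge
(a K-haplotype block supports up to K − 1 independent contrasts but counts
as one block).  Coinciding haplotype draws are merged with summed weights so
pools are sets of distinct haplotypes.

Default shapes mirror a dense-array GWAS at desk scale: 100–200 blocks of
~5 SNPs, pools of 2–4 haplotypes (drawn per block), 200–1,600 samples;
independence limits use single-SNP blocks with a large pool (K = 40) so
allele frequencies stay away from the rare-variant regime.  Phenotypes are
independent Bernoulli draws: constant prevalence under the null, or
per-dosage case probabilities (p0, p1, p2) at one causal SNP.

What the generator does **not** emulate: population stratification,
relatedness, genotyping missingness/error, physical (kb) distance, long- or
intermediate-range LD, and realistic site-frequency spectra.  Passing tests
therefore demonstrate the corrections' behaviour under clean blocky LD with
exchangeable samples — the regime the methods themselves assume — not their
robustness to confounding, which permutation itself does not provide.

## Evaluation pipeline

`compare_methods` computes every configured method's threshold on one
dataset and reads every corresponding α off a single shared permutation
distribution (the common gauge; per-method re-permutation would add noise
without information).  `subset_delta` re-runs the identical procedure — same
configuration and seeds — on a case-subsample (all controls kept by
default) and reports signed threshold deltas (subset − full); a full-size
subset reproduces the full-data thresholds exactly.  On unbalanced designs
re-balanced by subsampling, the permutation threshold moves noticeably (the
extreme tail of the minP null depends on sample size and case/control ratio
through the discreteness of the trend statistic) while simpleM and MVN move
little: they depend on labels not at all, only on re-estimated genotype
correlations.  Deltas are reported signed; sensitivity comparisons use
magnitudes.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; fixed seeds reproduce
results bit-for-bit, independent of batching.  The package's own test and
reproduction runs use: comparison runs of 1,000 SNPs × 1,000 samples with
B = n_iter = 5,000; independence runs of 1,000 SNPs × 500 samples with
B = 2,000; 500-replicate calibration at 500 SNPs × 200 samples with B = 499
per replicate (chosen so the threshold-exceedance event has probability
exactly 25/500 under exchangeability); and 20-seed subset experiments at
400 SNPs × 600 samples with B = n_iter = 2,000 so permutation and MVN face
equal Monte-Carlo noise.  These sizes keep any single experiment under a
couple of minutes on one CPU while leaving the Monte-Carlo error well inside
the tolerances asserted.

## Known limitations

* Gabriel tie-breaking (longest-first, leftmost) and the informative-pair
  conventions are one defensible reading of the standard protocol; block
  counts can shift by a few per cent under alternatives.
* The |D′| CI grid (101 points) quantises bounds at 0.01; irrelevant at the
  0.70/0.90/0.98 cutpoints but visible if thresholds were set between grid
  points.
* The MVN band treats correlation beyond the window and across chromosomes
  as exactly zero; data with genuine long-range LD would need a wider
  window.
* simpleM totals inherit the per-region integer ceiling described above.
* On blocky panels of 5-SNP blocks with ≤ 4 haplotypes, the block-count
  corrections' corresponding α lands at roughly twice the nominal level
  (≈0.09–0.11 at α = 0.05) — clearly anti-conservative, though the effect
  grows with within-block diversity and is stronger still on real dense
  arrays.
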