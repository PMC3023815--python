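"""Genotype containers, PLINK text-format I/O, and per-SNP quality control.

The central object is :class:`GenotypeDataset`: a samples x SNPs dosage matrix
coded 0/1/2 (count of the B allele) with ``-1`` marking a missing genotype,
an ordered SNP map sorted by (chromosome, position), and an optional binary
case/control phenotype.  Datasets round-trip losslessly through the
whitespace-delimited PLINK ``.ped``/``.map`` text formats.

QC follows standard GWAS per-SNP filtering: call rate, minor allele
frequency, and an exact conditional Hardy-Weinberg equilibrium test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammaln

MISSING = -1
#: Allele token PLINK uses for a missing call.
MISSING_ALLELE = "0"

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeDataset",
    "QcReport",
    "read_ped_map",
    "write_ped_map",
    "hwe_test",
    "hwe_het_count_probs",
    "qc_filter",
]


class PedFormatError(ValueError):
    """Raised for malformed .ped/.map input; message names the offending line."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic marker: identifier, map position, and its two allele labels.

    ``allele_a`` is the first-seen (reference for coding) allele; dosage counts
    copies of ``allele_b``.  ``allele_b`` is ``"0"`` when the SNP was
    monomorphic in the source data and the second allele is unknown.
    """

    id: str
    chromosome: str
    position: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position for SNP {self.id!r}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"identical alleles for SNP {self.id!r}")


def _chrom_key(chrom: str):
    """Sort chromosomes numerically when possible, lexicographically otherwise."""
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix with map and optional case/control labels.

    Invariants enforced on construction: matrix shape matches the SNP map and
    sample list, every entry is in {-1, 0, 1, 2}, SNP ids are unique, and
    columns are strictly sorted by (chromosome, position) — columns are
    reordered automatically if the input order differs.

    labels: per-sample phenotype, 1 = case, 0 = control, -1 = unknown; or None.
    """

    snps: list[SnpRecord]
    samples: list[str]
    dosages: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x SNPs) matrix")
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if m:
            vals = np.unique(self.dosages)
            bad = vals[(vals < -1) | (vals > 2)]
            if bad.size:
                raise ValueError(f"invalid dosage values {bad.tolist()}")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        order = sorted(
            range(m), key=lambda j: (_chrom_key(self.snps[j].chromosome), self.snps[j].position)
        )
        if order != list(range(m)):
            self.snps = [self.snps[j] for j in order]
            self.dosages = np.ascontiguousarray(self.dosages[:, order])
        keys = [(_chrom_key(s.chromosome), s.position) for s in self.snps]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chromosome, position) in SNP map")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match sample count")
            if m or n:
                bad = np.setdiff1d(np.unique(self.labels), [-1, 0, 1])
                if bad.size:
                    raise ValueError(f"invalid label values {bad.tolist()}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def chromosome_spans(self) -> list[tuple[str, int, int]]:
        """Half-open column ranges [(chrom, start, stop), ...] in map order."""
        spans: list[tuple[str, int, int]] = []
        for j, s in enumerate(self.snps):
            if spans and spans[-1][0] == s.chromosome:
                spans[-1] = (s.chromosome, spans[-1][1], j + 1)
            else:
                spans.append((s.chromosome, j, j + 1))
        return spans

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return 1.0 - self.missing_mask().mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency among non-missing genotypes."""
        obs = self.dosages != MISSING
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(obs, self.dosages, 0).sum(axis=0) / denom
        freq = np.where(denom > 0, freq, 0.0)
        return np.minimum(freq, 1.0 - freq)

    def genotype_counts(self) -> np.ndarray:
        """Per-SNP (n0, n1, n2) genotype counts, shape (n_snps, 3)."""
        return np.stack([(self.dosages == g).sum(axis=0) for g in (0, 1, 2)], axis=1)

    # -- subsetting ------------------------------------------------------
    def take_snps(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        return GenotypeDataset(
            snps=[self.snps[j] for j in index],
            samples=list(self.samples),
            dosages=self.dosages[:, index].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index, dtype=int)
        return GenotypeDataset(
            snps=list(self.snps),
            samples=[self.samples[i] for i in index],
            dosages=self.dosages[index, :].copy(),
            labels=None if self.labels is None else self.labels[index].copy(),
        )

    def with_labels(self, labels: np.ndarray | None) -> "GenotypeDataset":
        return GenotypeDataset(
            snps=list(self.snps),
            samples=list(self.samples),
            dosages=self.dosages.copy(),
            labels=None if labels is None else np.asarray(labels, dtype=np.int8).copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        """Semantic equality: same samples, map and genotypes.

        A SNP column counts as equal if it matches exactly, or with its
        allele labels swapped and dosages complemented (the same genotypes in
        the opposite orientation — unavoidable in PLINK text round trips when
        the first non-missing genotype is homozygous for the B allele).  An
        unknown second allele (``"0"``) matches any label.
        """
        if self.samples != other.samples or len(self.snps) != len(other.snps):
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        if self.labels is not None and not np.array_equal(self.labels, other.labels):
            return False
        for j, (s, o) in enumerate(zip(self.snps, other.snps)):
            if (s.id, s.chromosome, s.position) != (o.id, o.chromosome, o.position):
                return False
            a = self.dosages[:, j]
            b = other.dosages[:, j]
            unknown = MISSING_ALLELE in (s.allele_b, o.allele_b)
            same = (s.allele_a == o.allele_a and (unknown or s.allele_b == o.allele_b)
                    and np.array_equal(a, b))
            flipped = (o.allele_a in (s.allele_b, MISSING_ALLELE)
                       and (unknown or o.allele_b == s.allele_a)
                       and np.array_equal(np.where(a >= 0, 2 - a, MISSING), b))
            if not (same or flipped):
                return False
        return True


@dataclass(frozen=True)
class QcReport:
    """Per-SNP QC accounting.  Each removed SNP is counted once, under the
    reporting precedence call rate -> MAF -> HWE."""

    n_input_snps: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_output_snps: int

    def __post_init__(self) -> None:
        removed = self.n_removed_call_rate + self.n_removed_maf + self.n_removed_hwe
        if self.n_output_snps != self.n_input_snps - removed:
            raise ValueError("QC report counts are inconsistent")


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read whitespace-delimited PLINK text files into a :class:`GenotypeDataset`.

    The ``.map`` file has four columns (chromosome, id, genetic distance,
    position); the ``.ped`` file has six leading columns (family, individual,
    father, mother, sex, phenotype) followed by two allele tokens per SNP.
    Dosage counts copies of the B allele, where A is the first non-missing
    allele seen in file order at that SNP.  ``0 0`` marks a missing genotype;
    phenotype 1 maps to control, 2 to case, anything else to unknown.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    snps_raw: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise PedFormatError(
                f"{map_path}:{lineno}: expected 4 columns in .map, got {len(parts)}"
            )
        chrom, snp_id, _cm, pos = parts
        try:
            pos_i = int(pos)
        except ValueError as exc:
            raise PedFormatError(f"{map_path}:{lineno}: bad position {pos!r}") from exc
        snps_raw.append((snp_id, chrom, pos_i))
    m = len(snps_raw)

    samples: list[str] = []
    pheno: list[int] = []
    rows: list[np.ndarray] = []
    # first-seen allele bookkeeping, per SNP
    allele_a: list[str | None] = [None] * m
    allele_b: list[str | None] = [None] * m

    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise PedFormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} columns, got {len(parts)}"
            )
        samples.append(parts[1])
        pheno.append({"1": 0, "2": 1}.get(parts[5], MISSING))
        row = np.full(m, MISSING, dtype=np.int8)
        for j in range(m):
            a1, a2 = parts[6 + 2 * j], parts[7 + 2 * j]
            if (a1 == MISSING_ALLELE) != (a2 == MISSING_ALLELE):
                raise PedFormatError(
                    f"{ped_path}:{lineno}: half-missing genotype at SNP {snps_raw[j][0]}"
                )
            if a1 == MISSING_ALLELE:
                continue
            dose = 0
            for a in (a1, a2):
                if allele_a[j] is None:
                    allele_a[j] = a
                elif a != allele_a[j] and allele_b[j] is None:
                    allele_b[j] = a
                if a == allele_b[j]:
                    dose += 1
                elif a != allele_a[j]:
                    raise PedFormatError(
                        f"{ped_path}:{lineno}: more than two alleles at SNP "
                        f"{snps_raw[j][0]} ({allele_a[j]}/{allele_b[j]}/{a})"
                    )
            row[j] = dose
        rows.append(row)

    dosages = (
        np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    )
    snps = [
        SnpRecord(
            id=sid,
            chromosome=chrom,
            position=pos,
            allele_a=allele_a[j] if allele_a[j] is not None else "A",
            allele_b=allele_b[j] if allele_b[j] is not None else MISSING_ALLELE,
        )
        for j, (sid, chrom, pos) in enumerate(snps_raw)
    ]
    labels: np.ndarray | None
    if samples and any(p != MISSING for p in pheno):
        labels = np.asarray(pheno, dtype=np.int8)
    else:
        labels = None
    return GenotypeDataset(snps=snps, samples=samples, dosages=dosages, labels=labels)


def write_ped_map(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset as PLINK text; re-reading yields an equal dataset."""
    map_lines = [
        f"{s.chromosome}\t{s.id}\t0\t{s.position}" for s in dataset.snps
    ]
    Path(map_path).write_text("\n".join(map_lines) + ("\n" if map_lines else ""))

    ped_lines = []
    for i, sample in enumerate(dataset.samples):
        if dataset.labels is None:
            ph = "-9"
        else:
            ph = {0: "1", 1: "2"}.get(int(dataset.labels[i]), "-9")
        fields = [sample, sample, "0", "0", "0", ph]
        for j, s in enumerate(dataset.snps):
            d = int(dataset.dosages[i, j])
            if d == MISSING:
                fields += [MISSING_ALLELE, MISSING_ALLELE]
            else:
                # d copies of allele_b; alleles written a-first so that the
                # first-seen coding on re-read reproduces the same dosages
                fields += [s.allele_a] * (2 - d) + [s.allele_b] * d
        ped_lines.append(" ".join(fields))
    Path(ped_path).write_text("\n".join(ped_lines) + ("\n" if ped_lines else ""))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_het_count_probs(n_minor: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional null distribution of the heterozygote count.

    Given ``n_minor`` copies of the minor allele among ``n_total`` diploid
    genotypes, returns (het_counts, probabilities) of every achievable
    heterozygote count under random mating with fixed allele counts.
    Probabilities sum to one.
    """
    if n_total < 1:
        raise ValueError("need at least one genotype")
    if not 0 <= n_minor <= 2 * n_total:
        raise ValueError("impossible minor allele count")
    n_major = 2 * n_total - n_minor
    rare = min(n_minor, n_major)
    hets = np.arange(rare % 2, rare + 1, 2)
    # genotype layout: hom_rare = (rare-h)/2, hom_common = (2N - rare - h)/2
    hom_r = (rare - hets) // 2
    hom_c = (2 * n_total - rare - hets) // 2
    logp = (
        math.lgamma(n_total + 1)
        - gammaln(hom_r + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(hom_c + 1.0)
        + hets * math.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    return hets, probs


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (at the observed allele
    counts) no more probable than the observed one.  Monomorphic samples have
    a single achievable configuration and return p = 1.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("negative genotype count")
    n_total = n_AA + n_Aa + n_aa
    if n_total < 1:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa
    hets, probs = hwe_het_count_probs(min(n_a, 2 * n_total - n_a), n_total)
    p_obs = probs[hets == n_Aa]
    if p_obs.size == 0:  # parity mismatch cannot happen with consistent counts
        raise ValueError("inconsistent genotype counts")
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(
    dataset: GenotypeDataset,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply per-SNP QC: keep a SNP iff call rate > ``call_rate_min``, MAF >=
    ``maf_min`` and exact HWE p >= ``hwe_alpha``.

    Removals are reported with precedence call rate -> MAF -> HWE (each SNP
    counted once); which SNPs survive does not depend on that order.
    """
    if dataset.n_snps == 0:
        raise ValueError("empty dataset")
    call = dataset.call_rate()
    maf = dataset.maf()
    counts = dataset.genotype_counts()
    fail_call = ~(call > call_rate_min)
    fail_maf = maf < maf_min
    hwe_p = np.ones(dataset.n_snps)
    # HWE only needs evaluating where the SNP could still fail it
    for j in np.flatnonzero(~fail_call & ~fail_maf):
        n0, n1, n2 = (int(c) for c in counts[j])
        if n0 + n1 + n2 > 0:
            hwe_p[j] = hwe_test(n0, n1, n2)
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_call | fail_maf | fail_hwe)
    report = QcReport(
        n_input_snps=dataset.n_snps,
        n_removed_call_rate=int(fail_call.sum()),
        n_removed_maf=int((fail_maf & ~fail_call).sum()),
        n_removed_hwe=int((fail_hwe & ~fail_call & ~fail_maf).sum()),
        n_output_snps=int(keep.sum()),
    )
    return dataset.take_snps(np.flatnonzero(keep)), report
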