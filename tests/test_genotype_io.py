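"""PLINK text round-trips, the exact HWE test, and the per-SNP QC filter."""
import math
import tempfile
from fractions import Fraction
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwascorrect.genotype_io import (
    GenotypeDataset,
    PedFormatError,
    SnpRecord,
    hwe_het_count_probs,
    hwe_test,
    qc_filter,
    read_ped_map,
    write_ped_map,
)

from conftest import make_dataset


def write_files(tmp_path, ped_text, map_text):
    ped = tmp_path / "d.ped"
    mp = tmp_path / "d.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp


MAP2 = "1 rs1 0 100\n1 rs2 0 200\n"


class TestPedMapIO:
    def test_empty_ped_keeps_all_snps(self, tmp_path):
        ped, mp = write_files(tmp_path, "", MAP2)
        ds = read_ped_map(ped, mp)
        assert ds.n_samples == 0
        assert ds.snp_ids() == ["rs1", "rs2"]

    def test_hand_fixture_round_trips_bit_identically(self, tmp_path):
        ped_text = (
            "f1 s1 0 0 0 2 A A G T\n"
            "f2 s2 0 0 0 1 A C T T\n"
        )
        ped, mp = write_files(tmp_path, ped_text, MAP2)
        ds = read_ped_map(ped, mp)
        # A first-seen at rs1 -> dosage counts the C allele
        assert ds.dosages.tolist() == [[0, 1], [1, 2]]
        assert ds.labels.tolist() == [1, 0]
        out_ped = tmp_path / "o.ped"
        out_map = tmp_path / "o.map"
        write_ped_map(ds, out_ped, out_map)
        again = read_ped_map(out_ped, out_map)
        assert ds.equals(again)
        # and the second write is byte-identical to the first
        out2_ped = tmp_path / "o2.ped"
        out2_map = tmp_path / "o2.map"
        write_ped_map(again, out2_ped, out2_map)
        assert out_ped.read_text() == out2_ped.read_text()
        assert out_map.read_text() == out2_map.read_text()

    def test_missing_genotype_parsed_and_emitted_as_zero_tokens(self, tmp_path):
        ped_text = "f1 s1 0 0 0 2 0 0 G T\nf2 s2 0 0 0 1 A C T T\n"
        ped, mp = write_files(tmp_path, ped_text, MAP2)
        ds = read_ped_map(ped, mp)
        assert (ds.dosages == -1).sum() == 1
        assert ds.dosages[0, 0] == -1
        out_ped, out_map = tmp_path / "o.ped", tmp_path / "o.map"
        write_ped_map(ds, out_ped, out_map)
        first_line = out_ped.read_text().splitlines()[0].split()
        assert first_line[6:8] == ["0", "0"]

    @pytest.mark.parametrize(
        "bad_ped, match",
        [
            ("f1 s1 0 0 0 2 A A G\n", ":1"),  # ragged: one allele short
            ("f1 s1 0 0 0 2 A A G T\nf2 s2 0 0 0 1 A C C T\n", ":2"),
        ],
    )
    def test_format_errors_name_the_line(self, tmp_path, bad_ped, match):
        # second case: third distinct allele (C) at rs2 after G/T seen
        ped, mp = write_files(tmp_path, bad_ped, MAP2)
        with pytest.raises(PedFormatError, match=match):
            read_ped_map(ped, mp)

    def test_zero_snp_dataset_writes_valid_empty_marker_files(self, tmp_path):
        ds = GenotypeDataset(
            snps=[], samples=["a", "b"], dosages=np.empty((2, 0), dtype=np.int8)
        )
        out_ped, out_map = tmp_path / "o.ped", tmp_path / "o.map"
        write_ped_map(ds, out_ped, out_map)
        again = read_ped_map(out_ped, out_map)
        assert again.n_snps == 0 and again.samples == ["a", "b"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 12),
           m=st.integers(1, 10), miss_rate=st.floats(0.0, 0.3))
    def test_random_datasets_round_trip(self, seed, n, m, miss_rate):
        rng = np.random.default_rng(seed)
        dosages = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        dosages[rng.random((n, m)) < miss_rate] = -1
        labels = rng.integers(0, 2, size=n).astype(np.int8)
        ds = make_dataset(dosages, labels=labels)
        with tempfile.TemporaryDirectory() as tmpdir:
            tmp = Path(tmpdir)
            write_ped_map(ds, tmp / "d.ped", tmp / "d.map")
            again = read_ped_map(tmp / "d.ped", tmp / "d.map")
        assert ds.equals(again)
        assert np.array_equal(ds.dosages != -1, again.dosages != -1)

    def test_columns_sorted_by_chromosome_then_position(self):
        snps = [
            SnpRecord(id="b", chromosome="2", position=50),
            SnpRecord(id="a", chromosome="1", position=900),
        ]
        ds = GenotypeDataset(snps=snps, samples=["s"], dosages=np.array([[2, 0]], dtype=np.int8))
        assert ds.snp_ids() == ["a", "b"]
        assert ds.dosages.tolist() == [[0, 2]]


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational brute-force enumeration of the conditional HWE test."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        ways = Fraction(math.factorial(n),
                        math.factorial(hom_r) * math.factorial(h) * math.factorial(hom_c))
        weights[h] = ways * Fraction(2) ** h
    total = sum(weights.values())
    obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHweExact:
    def test_monomorphic_is_certain(self):
        assert hwe_test(25, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts", [(1, 0, 1), (25, 50, 25), (3, 1, 4), (0, 5, 0), (10, 2, 10), (7, 9, 2)]
    )
    def test_matches_exact_enumeration_oracle(self, counts):
        assert hwe_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)

    def test_balanced_table_is_unremarkable(self):
        assert hwe_test(25, 50, 25) > 0.5

    def test_enumeration_probabilities_sum_to_one(self):
        for n_minor, n_total in [(1, 5), (20, 50), (37, 40), (0, 10)]:
            _, probs = hwe_het_count_probs(n_minor, n_total)
            assert abs(probs.sum() - 1.0) < 1e-12

    def test_empty_table_is_invalid(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestQcFilter:
    def test_monomorphic_snps_removed_as_maf_failures(self):
        ds = make_dataset(np.zeros((20, 4), dtype=np.int8))
        kept, report = qc_filter(ds, maf_min=0.01)
        assert kept.n_snps == 0
        assert report.n_removed_maf == 4
        assert report.n_removed_call_rate == 0

    def test_low_call_rate_removed_first(self):
        dosages = np.tile([0, 1, 2, 1, 0, 1, 2, 1, 0, 1], (2, 1)).T.astype(np.int8)
        dosages[0, 0] = -1  # 10% missing at SNP 0
        ds = make_dataset(dosages)
        kept, report = qc_filter(ds, call_rate_min=0.95)
        assert report.n_removed_call_rate == 1
        assert kept.n_snps == 1

    def test_survivors_match_independent_predicate_oracle(self):
        rng = np.random.default_rng(7)
        n, m = 120, 1000
        dosages = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        # plant violations: missingness, monomorphism, extreme HWE departure
        for j in rng.choice(m, 60, replace=False):
            dosages[rng.choice(n, 10, replace=False), j] = -1
        for j in rng.choice(m, 40, replace=False):
            dosages[:, j] = 0
        for j in rng.choice(m, 40, replace=False):
            dosages[:, j] = np.where(np.arange(n) % 2 == 0, 0, 2)  # no hets
        ds = make_dataset(dosages)
        kept, report = qc_filter(ds, call_rate_min=0.95, maf_min=0.01, hwe_alpha=1e-6)

        survivors = set()
        for j in range(m):
            col = dosages[:, j]
            obs = col[col >= 0]
            if len(obs) / n <= 0.95:
                continue
            freq = obs.sum() / (2 * len(obs))
            if min(freq, 1 - freq) < 0.01:
                continue
            if hwe_oracle(int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())) < 1e-6:
                continue
            survivors.add(f"rs{j}")
        assert set(kept.snp_ids()) == survivors
        assert report.n_output_snps == len(survivors)

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        dosages = rng.integers(0, 3, size=(60, 50)).astype(np.int8)
        ds = make_dataset(dosages)
        once, _ = qc_filter(ds)
        twice, report = qc_filter(once)
        assert report.n_output_snps == once.n_snps
        assert once.equals(twice)
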