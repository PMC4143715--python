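"""Genotype I/O, MAF, exact Hardy-Weinberg test, and QC filtering."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedlmm import (
    GenotypeFormatError,
    GenotypeMatrix,
    apply_qc,
    hwe_chisq_p,
    hwe_exact_p,
    minor_allele_frequency,
    read_ped_map,
    write_ped_map,
)


def hwe_exact_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact-rational enumeration of the conditional HWE test.

    P(h | allele counts) = [ n! / (n11! h! n22!) * 2^h ] / [ (2n)! / (na! nb!) ]
    summed over heterozygote counts no more probable than observed.
    Integer arithmetic throughout — independent of the log-factorial path.
    """
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    nb = 2 * n_hom2 + n_het
    if na == 0 or nb == 0:
        return 1.0
    denom = comb(2 * n, na)

    def weight(h: int) -> Fraction:
        n1 = (na - h) // 2
        n2 = (nb - h) // 2
        mult = Fraction(
            comb(n, n1) * comb(n - n1, h) * (2 ** h), denom
        )
        return mult

    hs = range(na % 2, min(na, nb) + 1, 2)
    probs = {h: weight(h) for h in hs}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


class TestReadPedMap:
    def _write(self, tmp_path, ped_text, map_text):
        ped = tmp_path / "x.ped"
        mp = tmp_path / "x.map"
        ped.write_text(ped_text)
        mp.write_text(map_text)
        return ped, mp

    def test_minor_allele_coding(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "F1 s1 0 0 1 -9 A A\nF1 s2 0 0 2 -9 A G\n",
            "3 snp1 0 1000\n",
        )
        g = read_ped_map(ped, mp)
        assert g.snps.loc[0, "a1"] == "G"  # minor
        np.testing.assert_array_equal(g.dosage[:, 0], [0.0, 1.0])

    def test_missing_pair_is_nan(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "F1 s1 0 0 1 -9 0 0\nF1 s2 0 0 2 -9 A G\n",
            "3 snp1 0 1000\n",
        )
        g = read_ped_map(ped, mp)
        assert np.isnan(g.dosage[0, 0])

    def test_column_count_mismatch(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "F1 s1 0 0 1 -9 A A C C\n",
            "3 snp1 0 1000\n3 snp2 0 2000\n3 snp3 0 3000\n",
        )
        with pytest.raises(GenotypeFormatError, match="columns"):
            read_ped_map(ped, mp)

    def test_triallelic_snp_named(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "F1 s1 0 0 1 -9 A C\nF1 s2 0 0 1 -9 A T\n",
            "3 badsnp 0 1000\n",
        )
        with pytest.raises(GenotypeFormatError, match="badsnp"):
            read_ped_map(ped, mp)

    def test_roundtrip(self, tmp_path):
        ped, mp = self._write(
            tmp_path,
            "F1 s1 0 0 1 -9 A A G G\nF1 s2 0 0 2 -9 A G 0 0\nF1 s3 0 0 1 -9 G G G T\n",
            "3 snp1 0 100\n3 snp2 0 200\n",
        )
        g = read_ped_map(ped, mp)
        write_ped_map(g, tmp_path / "y.ped", tmp_path / "y.map")
        g2 = read_ped_map(tmp_path / "y.ped", tmp_path / "y.map")
        np.testing.assert_array_equal(
            np.nan_to_num(g.dosage, nan=-1), np.nan_to_num(g2.dosage, nan=-1)
        )


class TestMAF:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            ([1, 1, 1, 1], 0.5),        # all heterozygotes
            ([0, 0, 0, 0], 0.0),        # monomorphic
            ([2, 1, 0, np.nan], 0.5),   # 3 / (2*3)
            ([2, 2, 2, 1], 0.125),      # folded: min(p, 1-p)
        ],
    )
    def test_values(self, dosages, expected):
        assert minor_allele_frequency(np.array(dosages, float)) == pytest.approx(expected)

    def test_all_missing_is_nan(self):
        assert np.isnan(minor_allele_frequency(np.array([np.nan, np.nan])))


class TestHWE:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(5, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 7) == 1.0

    def test_two_homs_no_hets(self):
        # counts (1, 0, 1): attainable het counts {0, 2};
        # P(h=2) = 2^2*2!/ (0!2!0!) / C(4,2) = wrong-order check done via oracle
        assert hwe_exact_p(1, 0, 1) == pytest.approx(hwe_exact_oracle(1, 0, 1))
        # by hand: P(h=0) = 1/3, P(h=2) = 2/3 -> observed h=0 -> p = 1/3
        assert hwe_exact_p(1, 0, 1) == pytest.approx(1.0 / 3.0)

    def test_matches_enumeration_oracle_all_small_totals(self):
        """Full agreement with exact-rational enumeration for every
        genotype configuration with total <= 25."""
        for n in range(1, 26):
            for n1 in range(n + 1):
                for h in range(n - n1 + 1):
                    n2 = n - n1 - h
                    assert hwe_exact_p(n1, h, n2) == pytest.approx(
                        hwe_exact_oracle(n1, h, n2), rel=1e-9
                    ), (n1, h, n2)

    @settings(max_examples=200, deadline=None)
    @given(
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=0, max_value=50),
    )
    def test_oracle_agreement_and_symmetry_up_to_50(self, n1, h, n2):
        if n1 + h + n2 == 0:
            return
        p = hwe_exact_p(n1, h, n2)
        assert 0.0 < p <= 1.0
        assert p == hwe_exact_p(n2, h, n1)  # homozygote-swap invariance
        assert p == pytest.approx(hwe_exact_oracle(n1, h, n2), rel=1e-9)

    def test_chisq_agrees_at_large_counts(self):
        # large balanced counts: both tests give large p under equilibrium
        assert hwe_chisq_p(360, 480, 160) > 0.5
        assert hwe_exact_p(360, 480, 160) > 0.5


def _qc_fixture():
    """10 SNPs x 100 samples: one MAF failure, one call-rate failure,
    one HWE failure, 7 clean SNPs (counts chosen by direct computation
    of each statistic)."""
    n = 100
    cols = []
    # snp0: MAF 0.005 (one het among 100) -> maf fail
    c = np.zeros(n); c[0] = 1
    cols.append(c)
    # snp1: call rate 0.80 (20 missing), MAF 0.3 on called, HW proportions
    c = np.concatenate([np.full(20, np.nan),
                        np.repeat([0.0, 1.0, 2.0], [39, 34, 7])])
    cols.append(c)
    # snp2: extreme het deficit -> HWE p << 1e-6 (50/0/50)
    cols.append(np.repeat([0.0, 2.0], [50, 50]))
    # 7 clean SNPs at HW proportions, MAF 0.3
    for _ in range(7):
        cols.append(np.repeat([0.0, 1.0, 2.0], [49, 42, 9]))
    dosage = np.column_stack(cols)
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(10)],
            "chrom": "3",
            "position": np.arange(10) * 100 + 1,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"i{i}" for i in range(n)], snps=snps, dosage=dosage
    )


class TestApplyQC:
    def test_fixture_filtering(self):
        g = _qc_fixture()
        filtered, report = apply_qc(g)
        assert filtered.n_snps == 7
        by_id = report.snps.set_index("snp_id")
        assert by_id.loc["s0", "fail_reasons"] == "maf"
        assert by_id.loc["s1", "fail_reasons"] == "call_rate"
        assert by_id.loc["s2", "fail_reasons"] == "hwe"
        assert (by_id.loc["s3":"s9", "fail_reasons"] == "").all()
        assert report.n_snps_retained == 7
        assert bool(by_id["passed"].eq(by_id["fail_reasons"] == "").all())

    def test_sample_exclusion_precedes_snp_stats(self):
        g = _qc_fixture()
        # one sample missing 60% of genotypes
        g.dosage[5, :6] = np.nan
        filtered, report = apply_qc(g)
        assert report.samples.loc[5, "excluded"]
        assert "i5" not in filtered.sample_ids
        # SNP statistics computed on the 99 remaining samples
        assert report.snps["call_rate"].max() <= 1.0

    def test_noop_thresholds_identity(self):
        g = _qc_fixture()
        filtered, _ = apply_qc(
            g, maf_min=0.0, call_rate_min=0.0, hwe_p_min=0.0, sample_missing_max=1.0
        )
        assert filtered.n_snps == g.n_snps
        assert filtered.sample_ids == g.sample_ids

    def test_idempotent(self):
        g = _qc_fixture()
        once, _ = apply_qc(g)
        twice, rep2 = apply_qc(once)
        assert twice.n_snps == once.n_snps
        assert twice.sample_ids == once.sample_ids
        np.testing.assert_array_equal(
            np.nan_to_num(twice.dosage, nan=-1), np.nan_to_num(once.dosage, nan=-1)
        )

    def test_retained_snps_satisfy_thresholds(self):
        g = _qc_fixture()
        _, report = apply_qc(g)
        kept = report.snps[report.snps["passed"]]
        assert (kept["maf"] >= 0.01).all()
        assert (kept["call_rate"] >= 0.90).all()
        assert (kept["hwe_p"] > 1e-6).all()

    def test_empty_result_warns(self):
        g = _qc_fixture()
        with pytest.warns(RuntimeWarning, match="every SNP"):
            apply_qc(g, maf_min=0.6)

    def test_recode_keeps_maf_below_half(self):
        # counted allele at frequency 0.75 must be flipped during QC
        n = 40
        dosage = np.repeat([2.0, 1.0], [25, 15])[:, None]
        snps = pd.DataFrame(
            {"snp_id": ["s"], "chrom": "1", "position": [1], "a1": "A", "a2": "G"}
        )
        g = GenotypeMatrix([f"i{i}" for i in range(n)], snps, dosage)
        filtered, report = apply_qc(g, hwe_p_min=0.0)
        assert report.snps.loc[0, "maf"] <= 0.5
        assert filtered.snps.loc[0, "a1"] == "G"
        np.testing.assert_array_equal(
            filtered.dosage[:, 0], 2.0 - dosage[:, 0]
        )
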