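"""Triad I/O, X-linked Mendelian checks, MAF, HWE and the QC cascade."""

import logging
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xpoo import (CONSISTENT, FEMALE, INCONSISTENT, MALE, MISSING, UNKNOWN,
                  apply_qc, check_triad_consistency, compute_maf,
                  count_mendelian_errors, hwe_exact_test, read_triads,
                  read_triads_tsv, write_triads_tsv)
from xpoo.triad_data import ParseError

from conftest import make_dataset, make_triad, write_ped_map

MAP2 = ["23 rs1 0 1000", "23 rs2 0 2000"]


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestReadTriads:
    def test_round_trip_one_triad(self, tmp_path):
        ped, map_ = write_ped_map(tmp_path, [
            "fam1 dad 0 0 1 1 A A G G",
            "fam1 mum 0 0 2 1 A G A G",
            "fam1 kid dad mum 2 2 A G G G",
        ], MAP2)
        ds = read_triads(ped, map_)
        assert ds.n_triads == 1 and ds.n_snps == 2
        t = ds.triads[0]
        assert t.child_sex == FEMALE
        # rs1: variant = minor allele G; rs2: variant = minor allele A
        assert list(t.mother_dose) == [1, 1]
        assert list(t.father_dose) == [0, 0]
        assert list(t.child_dose) == [1, 0]

    def test_heterozygous_male_child_set_missing(self, tmp_path, caplog):
        ped, map_ = write_ped_map(tmp_path, [
            "fam1 dad 0 0 1 1 A A A A",
            "fam1 mum 0 0 2 1 A G A G",
            "fam1 kid dad mum 1 2 A G A A",
        ], MAP2)
        with caplog.at_level(logging.WARNING, logger="xpoo"):
            ds = read_triads(ped, map_)
        assert ds.triads[0].child_dose[0] == MISSING
        assert any("heterozygous male" in r.message for r in caplog.records)

    def test_missing_code_zero(self, tmp_path):
        ped, map_ = write_ped_map(tmp_path, [
            "fam1 dad 0 0 1 1 A A G G",
            "fam1 mum 0 0 2 1 0 0 A G",
            "fam1 kid dad mum 2 2 A G G G",
        ], MAP2)
        ds = read_triads(ped, map_)
        assert ds.triads[0].mother_dose[0] == MISSING

    def test_malformed_line_reports_line_number(self, tmp_path):
        ped, map_ = write_ped_map(tmp_path, [
            "fam1 dad 0 0 1 1 A A G G",
            "fam1 mum 0 0 2 1 A G",
            "fam1 kid dad mum 2 2 A G G G",
        ], MAP2)
        with pytest.raises(ParseError, match=":2"):
            read_triads(ped, map_)

    def test_unknown_child_sex_rejected(self, tmp_path):
        ped, map_ = write_ped_map(tmp_path, [
            "fam1 dad 0 0 1 1 A A G G",
            "fam1 mum 0 0 2 1 A G A G",
            "fam1 kid dad mum 0 2 A G G G",
        ], MAP2)
        with pytest.raises(ParseError, match="sex"):
            read_triads(ped, map_)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        ped, map_ = write_ped_map(tmp_path, [
            "fam1 dad 0 0 1 1 A A G G",
            "fam1 mum 0 0 2 1 A G A G",
            "fam1 kid dad mum 2 2 A G G G",
        ], ["23 rs1 0 1000", "23 rs1 0 2000"])
        with pytest.raises(ParseError, match="duplicate"):
            read_triads(ped, map_)

    def test_no_affected_child_rejected(self, tmp_path):
        ped, map_ = write_ped_map(tmp_path, [
            "fam1 dad 0 0 1 1 A A G G",
            "fam1 mum 0 0 2 1 A G A G",
            "fam1 kid dad mum 2 1 A G G G",
        ], MAP2)
        with pytest.raises(ParseError, match="affected"):
            read_triads(ped, map_)

    def test_tsv_round_trip(self, tmp_path, clean_dataset):
        path = tmp_path / "triads.tsv"
        write_triads_tsv(clean_dataset, path)
        ds2 = read_triads_tsv(path)
        m1, f1, c1, g1 = clean_dataset.dose_matrices()
        m2, f2, c2, g2 = ds2.dose_matrices()
        for a, b in ((m1, m2), (f1, f2), (c1, c2), (g1, g2)):
            assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def _consistency_oracle(m, f, c, sex):
    """Allele-level brute force: enumerate the mother's allele pairs and the
    child's possible transmissions."""
    def mother_pairs(dose):
        return {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[dose]

    for a1, a2 in mother_pairs(m):
        if sex == MALE:
            if c in (a1, a2):
                return CONSISTENT
        else:
            for maternal in (a1, a2):
                if maternal + f == c:
                    return CONSISTENT
    return INCONSISTENT


@pytest.mark.parametrize("m,f,c,sex,expect", [
    (0, 0, 1, MALE, INCONSISTENT),   # boy variant, mother has none
    (0, 1, 0, FEMALE, INCONSISTENT),  # girl lacks obligate paternal variant
    (1, 0, 1, FEMALE, CONSISTENT),
    (2, 0, 0, FEMALE, INCONSISTENT),  # girl ref-only, mother variant-only
    (2, MISSING, 0, MALE, INCONSISTENT),
    (MISSING, 0, 1, MALE, UNKNOWN),
    (1, MISSING, 2, FEMALE, UNKNOWN),
    (MISSING, MISSING, MISSING, FEMALE, UNKNOWN),  # no data, no verdict
])
def test_consistency_examples(m, f, c, sex, expect):
    assert check_triad_consistency(m, f, c, sex) == expect


def test_consistency_matches_allele_level_enumeration():
    for sex in (FEMALE, MALE):
        c_hi = 2 if sex == FEMALE else 1
        for m in range(3):
            for f in range(2):
                for c in range(c_hi + 1):
                    assert check_triad_consistency(m, f, c, sex) == \
                        _consistency_oracle(m, f, c, sex), (m, f, c, sex)


def test_consistency_symmetric_under_allele_relabeling():
    for sex in (FEMALE, MALE):
        c_hi = 2 if sex == FEMALE else 1
        for m in range(3):
            for f in range(2):
                for c in range(c_hi + 1):
                    flipped = check_triad_consistency(2 - m, 1 - f, c_hi - c, sex)
                    assert check_triad_consistency(m, f, c, sex) == flipped


class TestMendelianCount:
    def test_clean_dataset_zero(self, clean_dataset):
        assert count_mendelian_errors(clean_dataset, 0) == 0

    def test_three_planted_inconsistencies(self, clean_dataset):
        triads = list(clean_dataset.triads) + [
            make_triad("bad1", MALE, [0], [0], [1]),
            make_triad("bad2", FEMALE, [1], [1], [0]),
            make_triad("bad3", FEMALE, [0], [0], [2]),
        ]
        ds = make_dataset(triads)
        assert count_mendelian_errors(ds, 0) == 3
        # brute-force re-check
        brute = sum(
            check_triad_consistency(int(t.mother_dose[0]), int(t.father_dose[0]),
                                    int(t.child_dose[0]), t.child_sex) == INCONSISTENT
            for t in ds.triads)
        assert brute == 3


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

class TestMaf:
    def test_monomorphic_variant_only(self):
        ds = make_dataset([
            make_triad("a", FEMALE, [2], [MISSING], [MISSING]),
            make_triad("b", FEMALE, [2], [MISSING], [MISSING]),
            make_triad("c", FEMALE, [MISSING], [1], [MISSING]),
        ])
        assert compute_maf(ds, 0) == 0.0  # 5 of 5 alleles variant

    def test_single_het_mother(self):
        ds = make_dataset([make_triad("a", FEMALE, [1], [MISSING], [MISSING])])
        assert compute_maf(ds, 0) == 0.5

    def test_hand_tallied_mixture(self):
        # mothers contribute 2+1+1+1 = 5 variant of 8 alleles, fathers
        # 0+1+0+1 = 2 of 4, girls 1+2 = 3 of 4, boys 0+1 = 1 of 2:
        # freq 11/18 -> maf 7/18
        triads = [
            make_triad("t1", FEMALE, [2], [0], [1]),
            make_triad("t2", FEMALE, [1], [1], [2]),
            make_triad("t3", MALE, [1], [0], [0]),
            make_triad("t4", MALE, [1], [1], [1]),
        ]
        ds = make_dataset(triads)
        assert compute_maf(ds, 0) == pytest.approx(7 / 18)

    def test_all_missing_errors(self):
        ds = make_dataset([make_triad("a", FEMALE, [MISSING], [MISSING], [MISSING])])
        with pytest.raises(ValueError, match="missing"):
            compute_maf(ds, 0)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def _hwe_oracle(n_aa, n_ab, n_bb):
    """Exact-test p by full enumeration with rational arithmetic."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    rare = min(na, nb)
    if rare == 0:
        return 1.0
    total = Fraction(0)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        w = Fraction(
            comb(n, (na - h) // 2) * comb(n - (na - h) // 2, h) * 2 ** h)
        probs[h] = w
        total += w
    probs = {h: w / total for h, w in probs.items()}
    obs = probs[n_ab]
    return float(sum(w for w in probs.values() if w <= obs))


class TestHwe:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test((50, 0, 0)) == 1.0

    def test_two_individuals_enumeration(self):
        assert hwe_exact_test((1, 0, 1)) == pytest.approx(_hwe_oracle(1, 0, 1))
        assert _hwe_oracle(1, 0, 1) == pytest.approx(1 / 3)

    def test_perfect_hwe_100(self):
        assert hwe_exact_test((25, 50, 25)) == pytest.approx(_hwe_oracle(25, 50, 25))

    @given(st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
           .filter(lambda t: sum(t) > 0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(counts) == pytest.approx(_hwe_oracle(*counts), rel=1e-9)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test((-1, 2, 3))


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

class TestApplyQc:
    def test_clean_fixture_untouched(self, clean_dataset):
        ds, report = apply_qc(clean_dataset, maf_min=0.01)
        assert report.n_individuals_removed == 0
        assert report.n_snps_removed == 0
        assert ds.n_triads == clean_dataset.n_triads
        assert ds.n_snps == clean_dataset.n_snps

    def test_individual_over_missingness_threshold_removed(self):
        # 10 SNPs; one mother missing 2/10 = 20% > 10%
        n_snps = 10
        triads = []
        for i in range(12):
            m = [1] * n_snps
            if i == 0:
                m[0] = m[1] = MISSING
            triads.append(make_triad(f"t{i}", FEMALE, m, [0] * n_snps, [1] * n_snps))
        ds = make_dataset(triads, n_snps=n_snps)
        _, report = apply_qc(ds, snp_miss_max=1.0)
        removed = [(t, member) for t, member, _ in report.individuals_removed]
        assert removed == [("t0", "mother")]

    def test_low_maf_snp_removed(self):
        # SNP2 has 1 variant allele among 200 -> MAF 0.005 < 0.01
        triads = []
        for i in range(50):
            m2 = 1 if i == 0 else 0
            c2 = 1 if i == 0 else 0
            triads.append(make_triad(f"t{i}", FEMALE, [1, m2], [0, 0], [1, c2]))
        ds = make_dataset(triads, n_snps=2)
        clean, report = apply_qc(ds)
        assert [s for s, _ in report.snps_removed] == ["rs2"]
        assert clean.n_snps == 1

    def test_mendel_threshold_flags_snp(self):
        # 31 planted errors at one SNP of 40+ triads -> SNP excluded
        triads = [make_triad(f"bad{i}", MALE, [0], [0], [1]) for i in range(31)]
        triads += [make_triad(f"ok{i}", FEMALE, [1], [1], [1]) for i in range(120)]
        ds = make_dataset(triads)
        with pytest.raises(ValueError, match="review"):
            apply_qc(ds)  # the only SNP is dropped -> error advising review
        triads2 = [make_triad(f"{t.triad_id}x", t.child_sex,
                              [t.mother_dose[0], 1], [t.father_dose[0], 1],
                              [t.child_dose[0], 1]) for t in ds.triads]
        ds2 = make_dataset(triads2, n_snps=2)
        clean, report = apply_qc(ds2, snp_miss_max=1.0, maf_min=0.0)
        assert ("rs1", "31 Mendelian errors > 30") in report.snps_removed
        assert clean.n_snps == 1

    def test_inconsistent_triads_masked_not_removed(self):
        triads = [make_triad("bad", MALE, [0, 1], [0, 0], [1, 1])]
        triads += [make_triad(f"ok{i}", FEMALE, [1, 1], [1, 0], [1, 1])
                   for i in range(30)]
        ds = make_dataset(triads, n_snps=2)
        clean, report = apply_qc(ds, snp_miss_max=1.0)
        assert clean.n_triads == 31  # masked, not dropped
        bad = [t for t in clean.triads if t.triad_id == "bad"][0]
        assert bad.child_dose[0] == MISSING and bad.child_dose[1] != MISSING
        assert report.mendelian_errors["rs1"] == 1

    def test_idempotent(self, clean_dataset):
        triads = list(clean_dataset.triads) + [
            make_triad("bad", MALE, [0], [0], [1])]
        ds = make_dataset(triads)
        once, rep1 = apply_qc(ds, snp_miss_max=1.0)
        twice, rep2 = apply_qc(once, snp_miss_max=1.0)
        assert rep2.n_individuals_removed == 0
        assert rep2.n_snps_removed == 0
        m1, f1, c1, _ = once.dose_matrices()
        m2, f2, c2, _ = twice.dose_matrices()
        assert np.array_equal(m1, m2) and np.array_equal(f1, f2) \
            and np.array_equal(c1, c2)

    def test_qc_report_roundtrip(self, tmp_path, clean_dataset):
        _, report = apply_qc(clean_dataset)
        out = tmp_path / "qc.tsv"
        report.write(out)
        assert out.exists() and out.with_suffix(".tsv.log").exists()
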