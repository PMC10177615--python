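"""Genotype/phenotype I/O, marker QC and the Hardy-Weinberg exact test."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmlm import (
    GenotypeMatrix,
    PhenotypeTable,
    QCThresholds,
    apply_marker_qc,
    assign_breed_means,
    describe_phenotypes,
    heterozygosity_profiles,
    hwe_exact_pvalue,
    impute_missing_mean,
    marker_stats,
    read_phenotypes,
    read_vcf,
    write_phenotypes,
)


def hwe_oracle(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact-arithmetic enumeration of the conditional heterozygote distribution."""
    n = n_homref + n_het + n_homalt
    rare = 2 * min(n_homref, n_homalt) + n_het
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common),
        )
    total = sum(probs.values())
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_pvalue(10, 0, 0) == 1.0

    def test_small_case_matches_enumeration(self):
        # 6 diploids, 6 minor alleles: heterozygote counts {0, 2, 4, 6}
        assert hwe_exact_pvalue(2, 2, 2) == pytest.approx(hwe_oracle(2, 2, 2), rel=1e-12)

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_oracle_for_all_small_counts(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_pvalue(a, h, b) == pytest.approx(hwe_oracle(a, h, b), rel=1e-10)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_under_allele_swap(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_pvalue(a, h, b) == hwe_exact_pvalue(b, h, a)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)


class TestReadVcf:
    def test_dosage_coding_and_multiallelic_skip(self, vcf_file):
        g, markers = read_vcf(vcf_file)
        assert g.sample_ids == ["S1", "S2", "S3"]
        # rs3 is multiallelic and skipped -> 4 retained columns
        assert list(markers["id"]) == ["rs1", "rs2", "rs4", "rs5"]
        np.testing.assert_array_equal(g.codes[:, 0], [0, 1, 2])
        assert np.isnan(g.codes[0, 2])  # ./. at rs4
        np.testing.assert_array_equal(g.codes[:, 3], [2, 2, 0])

    def test_empty_vcf_preserves_samples(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
        )
        g, markers = read_vcf(path)
        assert g.sample_ids == ["A", "B"]
        assert g.n_markers == 0 and markers.empty

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_vcf(tmp_path / "nope.vcf")


class TestMarkerQC:
    def brute_force_survivors(self, g, thr):
        keep = []
        for j in range(g.n_markers):
            col = g.codes[:, j]
            obs = col[~np.isnan(col)]
            p = obs.sum() / (2 * len(obs))
            maf = min(p, 1 - p)
            miss = 1 - len(obs) / len(col)
            hwe = hwe_oracle(
                int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())
            )
            if maf >= thr.maf_min and miss <= thr.missing_max and hwe >= thr.hwe_p_min:
                keep.append(j)
        return keep

    def test_five_marker_toy_matches_brute_force(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(40, 5)).astype(float)
        codes[:30, 1] = 0.0  # low maf
        codes[:10, 2] = np.nan  # 25% missing
        codes[:, 3] = np.repeat([0.0, 2.0], 20)  # extreme HWE departure
        g = GenotypeMatrix([f"s{i}" for i in range(40)], codes)
        markers = pd.DataFrame(
            {"id": [f"m{j}" for j in range(5)], "chrom": "1",
             "pos": range(1, 6), "ref": "A", "alt": "G"}
        )
        thr = QCThresholds(maf_min=0.05, missing_max=0.05, hwe_p_min=1e-6)
        g2, m2, report = apply_marker_qc(g, markers, thr)
        expect = self.brute_force_survivors(g, thr)
        assert [markers.loc[j, "id"] for j in expect] == list(m2["id"])
        assert report["n_retained"] + report["n_removed"] == report["n_input"]

    def test_low_maf_marker_removed(self):
        codes = np.column_stack(
            [np.r_[[1.0], np.zeros(39)], np.r_[np.ones(20), np.zeros(20)]]
        )  # maf 0.0125 and 0.25
        g = GenotypeMatrix([f"s{i}" for i in range(40)], codes)
        markers = pd.DataFrame({"id": ["lo", "hi"], "chrom": "1", "pos": [1, 2],
                                "ref": "A", "alt": "G"})
        _, kept, _ = apply_marker_qc(g, markers, QCThresholds(maf_min=0.05))
        assert list(kept["id"]) == ["hi"]

    def test_monomorphic_removed_at_any_positive_floor(self):
        codes = np.column_stack([np.zeros(10), np.r_[np.ones(5), np.zeros(5)]])
        g = GenotypeMatrix([f"s{i}" for i in range(10)], codes)
        markers = pd.DataFrame({"id": ["mono", "poly"], "chrom": "1",
                                "pos": [1, 2], "ref": "A", "alt": "G"})
        _, kept, _ = apply_marker_qc(g, markers, QCThresholds(maf_min=1e-9))
        assert list(kept["id"]) == ["poly"]

    def test_qc_idempotent(self, structured_sim):
        g, markers, *_ = structured_sim
        thr = QCThresholds()
        g1, m1, _ = apply_marker_qc(g, markers, thr)
        g2, m2, rep2 = apply_marker_qc(g1, m1, thr)
        assert rep2["n_removed"] == 0
        np.testing.assert_array_equal(g1.codes, g2.codes)

    def test_empty_matrix_rejected(self):
        g = GenotypeMatrix(["a"], np.empty((1, 0)))
        with pytest.raises(ValueError):
            apply_marker_qc(g, pd.DataFrame(), QCThresholds())


class TestImputation:
    def test_column_mean_fills_missing(self):
        g = GenotypeMatrix(["a", "b", "c"], np.array([[0.0], [2.0], [np.nan]]))
        out = impute_missing_mean(g)
        np.testing.assert_allclose(out.codes[:, 0], [0.0, 2.0, 1.0])

    def test_complete_matrix_unchanged(self, structured_sim):
        g = structured_sim[0]
        np.testing.assert_array_equal(impute_missing_mean(g).codes, g.codes)

    def test_toy_matches_hand_means(self, toy_genotypes):
        out = impute_missing_mean(toy_genotypes)
        assert out.codes[1, 1] == pytest.approx((1 + 1 + 2) / 3)
        assert out.codes[2, 2] == pytest.approx((2 + 0 + 2) / 3)

    def test_allele_frequency_preserved_on_complete_markers(self, toy_genotypes):
        before = marker_stats(toy_genotypes)
        after = marker_stats(impute_missing_mean(toy_genotypes))
        # marker 0 was complete; its maf is untouched
        assert after.loc[0, "maf"] == pytest.approx(before.loc[0, "maf"])

    def test_fully_missing_marker_rejected(self):
        g = GenotypeMatrix(["a", "b"], np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValueError):
            impute_missing_mean(g)


class TestHeterozygosity:
    def test_extremes(self):
        g = GenotypeMatrix(
            ["het", "hom"], np.array([[1.0, 1.0, 1.0], [0.0, 2.0, 0.0]])
        )
        per_ind, per_marker = heterozygosity_profiles(g)
        np.testing.assert_allclose(per_ind, [1.0, 0.0])
        np.testing.assert_allclose(per_marker, [0.5, 0.5, 0.5])

    def test_toy_counts(self, toy_genotypes):
        per_ind, per_marker = heterozygosity_profiles(toy_genotypes)
        np.testing.assert_allclose(per_ind, [1 / 3, 0.0, 1 / 2, 0.0])
        np.testing.assert_allclose(per_marker, [0.0, 2 / 3, 0.0])


class TestPhenotypes:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            rng.normal(120, 15, size=(94, 5)),
            index=[f"yak{i:03d}" for i in range(94)],
            columns=["BH", "BL", "BW", "CC", "CCB"],
        )
        table = PhenotypeTable(data)
        path = tmp_path / "pheno.tsv"
        write_phenotypes(path, table)
        back = read_phenotypes(path)
        pd.testing.assert_frame_equal(back.data, table.data, check_names=False)

    def test_na_cells_become_missing(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\tBH\ns1\t120.5\ns2\tNA\ns3\toops\n")
        table = read_phenotypes(path)
        assert table.data.loc["s1", "BH"] == 120.5
        assert np.isnan(table.data.loc["s2", "BH"])
        assert np.isnan(table.data.loc["s3", "BH"])

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\tBH\ns1\t1\ns1\t2\n")
        with pytest.raises(ValueError):
            read_phenotypes(path)

    def test_breed_means_two_breeds(self):
        table = PhenotypeTable(
            pd.DataFrame({"BH": [10.0, 20.0, 30.0]}, index=["a", "b", "c"])
        )
        out = assign_breed_means(table, {"a": "x", "b": "x", "c": "y"})
        np.testing.assert_allclose(out.data["BH"], [15.0, 15.0, 30.0])

    def test_breed_means_with_missing_value(self):
        table = PhenotypeTable(
            pd.DataFrame(
                {"BH": [10.0, np.nan, 30.0, 40.0, np.nan, np.nan]},
                index=list("abcdef"),
            )
        )
        breed = {"a": "p1", "b": "p1", "c": "p2", "d": "p2", "e": "p2", "f": "p3"}
        out = assign_breed_means(table, breed)
        np.testing.assert_allclose(out.data["BH"][:5], [10, 10, 35, 35, 35])
        assert np.isnan(out.data.loc["f", "BH"])  # all-missing breed stays missing

    def test_unmapped_sample_rejected(self):
        table = PhenotypeTable(pd.DataFrame({"BH": [1.0]}, index=["a"]))
        with pytest.raises(KeyError):
            assign_breed_means(table, {})


class TestDescribe:
    def test_se_from_sd_and_n(self):
        # a 94-sample trait standardised to SD exactly 23.2648
        rng = np.random.default_rng(7)
        v = rng.normal(size=94)
        v = (v - v.mean()) / v.std(ddof=1) * 23.2648 + 168.8
        table = PhenotypeTable(pd.DataFrame({"CC": v}, index=[f"s{i}" for i in range(94)]))
        stats = describe_phenotypes(table)
        assert stats.loc["CC", "SE"] == pytest.approx(2.39958, abs=5e-6)

    def test_toy_vector(self):
        table = PhenotypeTable(
            pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        )
        row = describe_phenotypes(table).loc["t"]
        assert row["Mean"] == 2.5
        assert row["SD"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert row["SE"] == pytest.approx(row["SD"] / 2.0)
        assert row["CV"] == pytest.approx(100 * row["SD"] / 2.5)
        assert row["Max"] == 4.0 and row["Min"] == 1.0

    def test_constant_trait(self):
        table = PhenotypeTable(pd.DataFrame({"t": [5.0, 5.0, 5.0]}, index=list("abc")))
        row = describe_phenotypes(table).loc["t"]
        assert row["SD"] == 0.0 and row["CV"] == 0.0

    def test_single_value_rejected(self):
        table = PhenotypeTable(pd.DataFrame({"t": [5.0, np.nan]}, index=list("ab")))
        with pytest.raises(ValueError):
            describe_phenotypes(table)
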