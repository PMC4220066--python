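"""Genotype IO round-trips and the call-rate / MAF / HWE filter chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crosspred as cp
from conftest import random_genotypes
from crosspred.qc import ParseError, QCError


def _with_missing(rng, gm, rate):
    vals = gm.values.copy()
    vals[rng.random(vals.shape) < rate] = np.nan
    return cp.GenotypeMatrix(vals, gm.sample_ids, gm.snp_ids, gm.population_labels)


class TestIO:
    @pytest.mark.parametrize("fmt", ["matrix", "ped"])
    def test_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        gm = _with_missing(rng, random_genotypes(rng, 12, 30, labels=["X"] * 6 + ["Y"] * 6), 0.1)
        path = tmp_path / ("geno.tsv" if fmt == "matrix" else "geno")
        cp.write_genotypes(gm, path, fmt=fmt)
        back = cp.read_genotypes(path, fmt=fmt)
        np.testing.assert_array_equal(gm.values, back.values)
        assert back.sample_ids == gm.sample_ids
        assert back.snp_ids == gm.snp_ids
        assert back.population_labels == gm.population_labels

    def test_matrix_shape(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "animal_id\tpopulation\ts1\ts2\n"
            "a1\tP\t0\t2\n"
            "a2\tP\t1\tNA\n"
        )
        gm = cp.read_genotypes(path)
        assert gm.values.shape == (2, 2)
        assert np.isnan(gm.values[1, 1])

    def test_bad_code_names_line(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "animal_id\tpopulation\ts1\n" "a1\tP\t0\n" "a2\tP\t3\n"
        )
        with pytest.raises(ParseError, match=":3"):
            cp.read_genotypes(path)

    def test_inconsistent_columns(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("animal_id\tpopulation\ts1\ts2\n" "a1\tP\t0\n")
        with pytest.raises(ParseError, match=":2"):
            cp.read_genotypes(path)


class TestStatistics:
    def test_call_rate(self):
        vals = np.zeros((10, 2))
        vals[0, 1] = np.nan
        gm = cp.GenotypeMatrix(vals, [f"a{i}" for i in range(10)], ["s1", "s2"], ["P"] * 10)
        np.testing.assert_allclose(cp.call_rate(gm), [1.0, 0.9])

    def test_call_rate_under_random_mask(self):
        rng = np.random.default_rng(1)
        gm = _with_missing(rng, random_genotypes(rng, 60, 10000), 0.03)
        assert abs(cp.call_rate(gm).mean() - 0.97) < 0.005

    def test_maf_counts(self):
        vals = np.array([[0.0], [1.0], [2.0], [1.0]])
        gm = cp.GenotypeMatrix(vals, list("abcd"), ["s"], ["P"] * 4)
        assert cp.maf_per_population(gm).loc["s", "P"] == 0.5

    def test_maf_monomorphic(self):
        gm = cp.GenotypeMatrix(np.zeros((4, 1)), list("abcd"), ["s"], ["P"] * 4)
        assert cp.maf_per_population(gm).loc["s", "P"] == 0.0

    def test_hwe_hand_values(self):
        v50 = np.array([[0.0]] * 50 + [[2.0]] * 50)
        gm = cp.GenotypeMatrix(v50, [str(i) for i in range(100)], ["s"], ["P"] * 100)
        np.testing.assert_allclose(cp.hwe_chisq(gm), [100.0])
        v_hw = np.array([[0.0]] * 25 + [[1.0]] * 50 + [[2.0]] * 25)
        gm = cp.GenotypeMatrix(v_hw, [str(i) for i in range(100)], ["s"], ["P"] * 100)
        np.testing.assert_allclose(cp.hwe_chisq(gm), [0.0])

    def test_hwe_monomorphic_convention(self):
        gm = cp.GenotypeMatrix(np.zeros((30, 1)), [str(i) for i in range(30)], ["s"], ["P"] * 30)
        np.testing.assert_allclose(cp.hwe_chisq(gm), [0.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        n0=st.integers(0, 40), n1=st.integers(0, 40), n2=st.integers(0, 40)
    )
    def test_hwe_matches_bruteforce(self, n0, n1, n2):
        n = n0 + n1 + n2
        if n == 0:
            return
        vals = np.array([[0.0]] * n0 + [[1.0]] * n1 + [[2.0]] * n2)
        gm = cp.GenotypeMatrix(vals, [str(i) for i in range(n)], ["s"], ["P"] * n)
        p = (2 * n2 + n1) / (2 * n)
        if p in (0.0, 1.0):
            expected = 0.0
        else:
            exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
            expected = float((((np.array([n0, n1, n2]) - exp) ** 2) / exp).sum())
        np.testing.assert_allclose(cp.hwe_chisq(gm), [expected], atol=1e-10)


class TestApplyQC:
    def test_lenient_thresholds_remove_nothing(self, clean_genotypes):
        # on already-clean data, lenient thresholds leave every SNP in place
        again, report = cp.apply_qc(clean_genotypes, 0.0, 0.0, np.inf)
        assert report.n_after == report.n_before
        assert again.n_snps == clean_genotypes.n_snps

    def test_attribution_and_order(self):
        # five SNPs: ok / low call rate / low MAF in one pop / extreme HWE / ok
        rng = np.random.default_rng(2)
        n = 200
        labels = ["P1"] * 100 + ["P2"] * 100
        ok1 = rng.binomial(2, 0.4, n).astype(float)
        low_cr = ok1.copy()
        low_cr[rng.choice(n, 20, replace=False)] = np.nan
        low_maf = np.concatenate([np.zeros(100), rng.binomial(2, 0.4, 100)]).astype(float)
        bad_hwe = np.array([0.0, 2.0] * 100)  # no heterozygotes at p=0.5
        ok2 = rng.binomial(2, 0.3, n).astype(float)
        vals = np.column_stack([ok1, low_cr, low_maf, bad_hwe, ok2])
        gm = cp.GenotypeMatrix(vals, [f"a{i}" for i in range(n)],
                               ["keep1", "cr", "maf", "hwe", "keep2"], labels)
        cleaned, report = cp.apply_qc(gm, 0.95, 0.01, 150.0)
        assert cleaned.snp_ids == ["keep1", "keep2"]
        assert report.removed["call_rate"] == ["cr"]
        assert report.removed["maf"] == ["maf"]
        assert report.removed["hwe"] == ["hwe"]
        assert report.reconciles()

    def test_idempotent(self, small_study):
        cleaned, _ = cp.apply_qc(small_study.genotypes)
        again, report2 = cp.apply_qc(cleaned)
        assert report2.n_before == report2.n_after
        assert again.snp_ids == cleaned.snp_ids

    def test_removed_count_matches_bruteforce(self, small_study):
        gm = small_study.genotypes
        _, report = cp.apply_qc(gm)
        cr = cp.call_rate(gm)
        maf = cp.maf_per_population(gm).to_numpy()
        chi = cp.hwe_chisq(gm)
        keep = (cr > 0.95) & ((maf > 0.01) & ~np.isnan(maf)).all(axis=1) & (chi < 600)
        assert report.n_after == int(keep.sum())
        assert report.n_before == report.n_after + sum(
            len(v) for v in report.removed.values()
        )

    def test_all_removed_raises(self):
        gm = cp.GenotypeMatrix(np.zeros((10, 2)), [str(i) for i in range(10)],
                               ["s1", "s2"], ["P"] * 10)
        with pytest.raises(QCError):
            cp.apply_qc(gm)  # monomorphic SNPs fail the MAF filter


class TestImputation:
    def test_mean_imputation(self):
        vals = np.array([[0.0], [2.0], [np.nan]])
        gm = cp.GenotypeMatrix(vals, list("abc"), ["s"], ["P"] * 3)
        out = cp.impute_missing(gm)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 2.0, 1.0])

    def test_identity_when_complete(self, clean_genotypes):
        complete = cp.impute_missing(clean_genotypes)
        again = cp.impute_missing(complete)
        assert again is complete

    def test_column_means_preserved(self, small_study):
        gm = small_study.genotypes
        out = cp.impute_missing(gm)
        np.testing.assert_allclose(
            out.values.mean(axis=0), np.nanmean(gm.values, axis=0), atol=1e-12
        )

    def test_all_missing_snp_raises(self):
        vals = np.full((4, 1), np.nan)
        gm = cp.GenotypeMatrix(vals, list("abcd"), ["s"], ["P"] * 4)
        with pytest.raises(QCError):
            cp.impute_missing(gm)
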