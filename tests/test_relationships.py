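"""A-matrix recursion, VanRaden G, Yang-style blending, summaries."""

import numpy as np
import pandas as pd
import pytest

import crosspred as cp
from conftest import random_genotypes
from crosspred.relationships import PedigreeError
from crosspred.simulate import gene_drop


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id"])


class TestPedigree:
    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            cp.PedigreeTable(ped_frame([("a", "b", None), ("b", "a", None)]))

    def test_unknown_parent_rejected(self):
        with pytest.raises(PedigreeError, match="unknown parent"):
            cp.PedigreeTable(ped_frame([("a", "ghost", None)]))

    def test_sorted_parents_first(self):
        ped = cp.PedigreeTable(
            ped_frame([("o", "s", "d"), ("s", None, None), ("d", None, None)])
        )
        order = ped.animal_ids
        assert order.index("s") < order.index("o")
        assert order.index("d") < order.index("o")


class TestComputeA:
    def test_textbook_trio(self):
        ped = cp.PedigreeTable(
            ped_frame([("1", None, None), ("2", None, None), ("3", "1", "2")])
        )
        A = cp.compute_A(ped)
        expected = np.array([[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]])
        np.testing.assert_allclose(A.to_numpy(), expected)

    def test_founders_identity(self):
        ped = cp.PedigreeTable(ped_frame([(str(i), None, None) for i in range(6)]))
        np.testing.assert_allclose(cp.compute_A(ped).to_numpy(), np.eye(6))

    def test_inbred_offspring_of_full_sibs(self):
        # full sibs are related 0.5, so their offspring has F = 0.25
        ped = cp.PedigreeTable(
            ped_frame(
                [("s", None, None), ("d", None, None),
                 ("x", "s", "d"), ("y", "s", "d"), ("z", "x", "y")]
            )
        )
        A = cp.compute_A(ped)
        assert A.loc["x", "y"] == 0.5
        assert A.loc["z", "z"] == 1.25

    def test_matches_gene_drop_expectation(self):
        # Monte-Carlo oracle: realized relationships over many independent SNPs
        # converge to the tabular A (founder allele frequency 0.5 means
        # cov((g_i-1),(g_j-1)) = A_ij / 2 per SNP)
        rows = [
            ("f1", None, None, "P"), ("f2", None, None, "P"),
            ("f3", None, None, "P"), ("f4", None, None, "P"),
            ("m1", "f1", "f2", "P"), ("m2", "f3", "f4", "P"),
            ("o1", "m1", "m2", "P"), ("o2", "m1", "m2", "P"),
        ]
        ped = cp.PedigreeTable(
            pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "population"])
        )
        A = cp.compute_A(ped)
        gm = gene_drop(ped, np.full((1, 40000), 0.5), seed=17)
        dev = gm.values - 1.0
        emp = (dev @ dev.T) / dev.shape[1] / 0.5
        ids = ped.animal_ids
        emp = pd.DataFrame(emp, index=ids, columns=ids)
        for i in ids:
            for j in ids:
                if i != j:
                    assert abs(emp.loc[i, j] - A.loc[i, j]) < 0.05


class TestVanRadenG:
    def test_hand_example(self):
        gm = cp.GenotypeMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]),
                               ["a", "b"], ["s1", "s2"], ["P", "P"])
        G, freqs = cp.compute_G_vr(gm)
        np.testing.assert_allclose(G.to_numpy(), [[2.0, -2.0], [-2.0, 2.0]])
        np.testing.assert_allclose(freqs.to_numpy(), [0.5, 0.5])

    def test_duplicate_animals_identical_rows(self):
        rng = np.random.default_rng(3)
        gm = random_genotypes(rng, 10, 50)
        vals = np.vstack([gm.values, gm.values[0]])
        dup = cp.GenotypeMatrix(vals, gm.sample_ids + ["dup"], gm.snp_ids,
                                gm.population_labels + ["P"])
        G, _ = cp.compute_G_vr(dup)
        np.testing.assert_allclose(G.loc["a0"].to_numpy(), G.loc["dup"].to_numpy())

    def test_row_sums_zero(self):
        rng = np.random.default_rng(4)
        G, _ = cp.compute_G_vr(random_genotypes(rng, 15, 80))
        np.testing.assert_allclose(G.to_numpy().sum(axis=1), 0.0, atol=1e-10)

    def test_matches_independent_scaling(self):
        rng = np.random.default_rng(5)
        gm = random_genotypes(rng, 12, 60)
        G, _ = cp.compute_G_vr(gm)
        X = gm.values
        p = X.mean(axis=0) / 2
        Z = X - 2 * p
        c = 2 * np.sum(p * (1 - p))
        np.testing.assert_allclose(G.to_numpy(), Z @ Z.T / c, atol=1e-12)

    def test_monomorphic_only_raises(self):
        gm = cp.GenotypeMatrix(np.full((5, 3), 2.0), list("abcde"),
                               ["s1", "s2", "s3"], ["P"] * 5)
        with pytest.raises(ValueError, match="monomorphic"):
            cp.compute_G_vr(gm)


class TestBlend:
    @staticmethod
    def _fixture(n=40, seed=6):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((n, n)) * 0.05
        A = base @ base.T + np.eye(n)
        ids = [f"a{i}" for i in range(n)]
        return pd.DataFrame(A, index=ids, columns=ids), rng

    def test_identical_matrices_give_b_one(self):
        A, _ = self._fixture()
        est = cp.estimate_blend_b(A, A, n_bins=5)
        assert (est.per_bin["b"] == 1.0).all()
        assert est.scalar == 1.0

    def test_pure_noise_gives_b_near_zero(self):
        A, rng = self._fixture()
        noise = rng.standard_normal(A.shape) * 20
        noise = (noise + noise.T) / 2
        G = A + pd.DataFrame(noise, index=A.index, columns=A.columns)
        est = cp.estimate_blend_b(G, A, n_bins=5)
        assert est.scalar < 0.05

    def test_more_markers_increase_b(self, small_study):
        geno = cp.impute_missing(small_study.genotypes)
        A = cp.compute_A(small_study.pedigree, subset=geno.sample_ids)
        G_half, _ = cp.compute_G_vr(geno.subset(snp_ids=geno.snp_ids[:150]))
        G_full, _ = cp.compute_G_vr(geno)
        b_half = cp.estimate_blend_b(G_half, A).scalar
        b_full = cp.estimate_blend_b(G_full, A).scalar
        assert b_full > b_half

    def test_blend_endpoints_and_affinity(self):
        A, rng = self._fixture()
        G = A + pd.DataFrame(
            0.1 * np.eye(len(A)), index=A.index, columns=A.columns
        )
        pd.testing.assert_frame_equal(cp.blend_G(G, A, 1.0), G)
        pd.testing.assert_frame_equal(cp.blend_G(G, A, 0.0), A)
        for b in (0.25, 0.5, 0.99):
            expected = b * G.to_numpy() + (1 - b) * A.to_numpy()
            np.testing.assert_allclose(cp.blend_G(G, A, b).to_numpy(), expected)

    def test_invalid_b(self):
        A, _ = self._fixture(n=5)
        with pytest.raises(ValueError):
            cp.blend_G(A, A, 1.5)


class TestRelationshipSummary:
    def test_block_constant(self):
        labels = ["A"] * 3 + ["B"] * 3
        M = np.full((6, 6), 0.1)
        M[:3, :3] = 0.4
        M[3:, 3:] = 0.4
        np.fill_diagonal(M, 1.0)
        df = pd.DataFrame(M, index=list("abcdef"), columns=list("abcdef"))
        s = cp.relationship_summary(df, labels).set_index(["population", "scope"])
        assert s.loc[("A", "within"), "mean"] == pytest.approx(0.4)
        assert s.loc[("A", "within"), "sd"] == pytest.approx(0.0, abs=1e-12)
        assert s.loc[("A", "between"), "mean"] == pytest.approx(0.1)
        assert s.loc[("B", "between"), "sd"] == pytest.approx(0.0, abs=1e-12)

    def test_identity_matrix(self):
        df = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        s = cp.relationship_summary(df, ["A", "A", "B", "B"])
        assert (s["mean"] == 0).all()

    def test_singleton_population_missing(self):
        df = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        s = cp.relationship_summary(df, ["A", "A", "B"]).set_index(
            ["population", "scope"]
        )
        assert np.isnan(s.loc[("B", "within"), "mean"])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        n = 12
        M = rng.standard_normal((n, n))
        M = (M + M.T) / 2
        ids = [f"a{i}" for i in range(n)]
        labels = ["A"] * 5 + ["B"] * 7
        df = pd.DataFrame(M, index=ids, columns=ids)
        s1 = cp.relationship_summary(df, labels)
        perm = rng.permutation(n)
        df2 = df.iloc[perm, perm]
        labels2 = [labels[i] for i in perm]
        s2 = cp.relationship_summary(df2, labels2)
        merged = s1.merge(s2, on=["population", "scope"], suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["mean_1"], merged["mean_2"])
        np.testing.assert_allclose(merged["sd_1"], merged["sd_2"])
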