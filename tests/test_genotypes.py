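import math

import numpy as np
import pandas as pd
import pytest

from singlestep.genotypes import (GenotypeData, GenotypeError,
                                  allele_frequencies, blend_tune_g,
                                  center_dosages, hwe_exact_test, impute_mean,
                                  inverse_spd, qc_filter, read_plink_text,
                                  vanraden_g, write_plink_text)


def make_geno(dosages, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    markers = pd.DataFrame({
        "chrom": chrom or ["1"] * m,
        "snp_id": [f"s{j}" for j in range(m)],
        "cm": np.arange(m, dtype=float),
        "bp": np.arange(1, m + 1) * 1000,
        "a1": "A", "a2": "B"})
    return GenotypeData(dosages=dosages, markers=markers,
                        animal_ids=list(range(1, dosages.shape[0] + 1)))


class TestPlinkIO:
    def test_minor_allele_counted(self, tmp_path):
        (tmp_path / "t.map").write_text("1\ts1\t0\t100\n")
        (tmp_path / "t.ped").write_text(
            "1 1 0 0 0 -9 A A\n2 2 0 0 0 -9 A G\n3 3 0 0 0 -9 A A\n")
        g = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        # G is minor (1 of 6 alleles): dosage counts G
        assert g.markers["a1"][0] == "G"
        np.testing.assert_array_equal(g.dosages[:, 0], [0, 1, 0])

    def test_tie_broken_lexicographically(self, tmp_path):
        (tmp_path / "t.map").write_text("1\ts1\t0\t100\n")
        (tmp_path / "t.ped").write_text("1 1 0 0 0 -9 A G\n2 2 0 0 0 -9 G A\n")
        g = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        assert g.markers["a1"][0] == "A"

    def test_zero_zero_is_missing(self, tmp_path):
        (tmp_path / "t.map").write_text("1\ts1\t0\t100\n")
        (tmp_path / "t.ped").write_text("1 1 0 0 0 -9 0 0\n2 2 0 0 0 -9 A G\n")
        g = read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")
        assert np.isnan(g.dosages[0, 0])

    def test_ragged_line_reports_number(self, tmp_path):
        (tmp_path / "t.map").write_text("1\ts1\t0\t100\n1\ts2\t0\t200\n")
        (tmp_path / "t.ped").write_text(
            "1 1 0 0 0 -9 A A G G\n2 2 0 0 0 -9 A A\n")
        with pytest.raises(GenotypeError, match="line 2"):
            read_plink_text(tmp_path / "t.ped", tmp_path / "t.map")

    def test_roundtrip_with_missing(self, tmp_path):
        g = make_geno([[0, 1, np.nan], [2, np.nan, 1], [1, 2, 0]])
        write_plink_text(g, tmp_path / "o.ped", tmp_path / "o.map")
        assert "0 0" in (tmp_path / "o.ped").read_text()
        back = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map",
                               counted_alleles=list(g.markers["a1"]))
        np.testing.assert_array_equal(np.isnan(back.dosages),
                                      np.isnan(g.dosages))
        np.testing.assert_array_equal(back.dosages[~np.isnan(g.dosages)],
                                      g.dosages[~np.isnan(g.dosages)])


class TestAlleleStats:
    def test_frequency_examples(self):
        g = make_geno(np.array([[0], [1], [2], [2]]))
        assert allele_frequencies(g)[0] == pytest.approx(0.625)
        g = make_geno(np.array([[2], [2], [2]]))
        assert allele_frequencies(g)[0] == 1.0
        g = make_geno(np.array([[1], [np.nan], [1]]))
        assert allele_frequencies(g)[0] == pytest.approx(0.5)


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exhaustive enumeration over all heterozygote counts."""
    from fractions import Fraction
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_A = 2 * n - n_a
    n_rare = min(n_A, n_a)
    def weight(h):
        hom_r = (n_rare - h) // 2
        hom_c = n - hom_r - h
        return (Fraction(math.factorial(n),
                         math.factorial(hom_r) * math.factorial(h)
                         * math.factorial(hom_c)) * 2 ** h)
    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= obs))


class TestHweExact:
    def test_two_individuals_all_het(self):
        # 2 A and 2 a alleles: configurations het ∈ {0, 2}; p = 1
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(7, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(25, 50, 25), (40, 20, 40),
                                        (5, 90, 5), (57, 14, 50), (1, 0, 1)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-10)

    def test_super_uniform_under_null(self):
        # rejection rate at alpha=0.05 must not exceed 0.06 under HWE
        rng = np.random.default_rng(0)
        n, sims = 100, 10_000
        rejections = 0
        for _ in range(sims):
            p = rng.uniform(0.1, 0.9)
            g = rng.binomial(1, p, size=(n, 2)).sum(axis=1)
            pval = hwe_exact_test(int((g == 2).sum()), int((g == 1).sum()),
                                  int((g == 0).sum()))
            rejections += pval < 0.05
        assert rejections / sims <= 0.06


class TestHweProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_p_value_in_unit_interval(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        p = hwe_exact_test(aa, ab, bb)
        assert 0.0 < p <= 1.0


class TestQcFilter:
    def test_low_call_rate_removed_first(self):
        d = np.ones((10, 2))
        d[:, 1] = [0, 1, 2, 1, 0, 1, 2, 1, 0, 1]
        d[:2, 0] = np.nan  # 8/10 = 0.8 < 0.9 → call-rate removal
        d[2:, 0] = [0, 1, 2, 1, 0, 1, 2, 1]
        g = make_geno(d)
        out, rep = qc_filter(g)
        assert rep.removed_call_rate == 1
        assert out.n_snps == 1

    def test_low_maf_removed(self):
        n = 200
        d = np.zeros((n, 2))
        d[:, 0] = np.concatenate([[1], np.zeros(n - 1)])    # MAF 0.0025
        d[:, 1] = np.tile([0, 1, 2, 1], n // 4)
        g = make_geno(d)
        out, rep = qc_filter(g)
        assert rep.removed_maf == 1
        assert list(out.markers["snp_id"]) == ["s1"]

    def test_hwe_failure_removed(self):
        # all heterozygotes: grossly out of equilibrium
        n = 200
        d = np.column_stack([np.ones(n), np.tile([0, 1, 2, 1], n // 4)])
        g = make_geno(d)
        out, rep = qc_filter(g)
        assert rep.removed_hwe == 1

    def test_clean_data_untouched_and_idempotent(self, small_dataset):
        cfg, ped, geno, phen, truth = small_dataset
        once, rep1 = qc_filter(geno)
        twice, rep2 = qc_filter(once)
        assert rep2.n_snps_before == rep2.n_snps_after
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        assert rep1.n_snps_after == rep1.n_snps_before - (
            rep1.removed_call_rate + rep1.removed_maf + rep1.removed_hwe)

    def test_all_filtered_raises(self):
        g = make_geno(np.full((10, 1), np.nan))
        with pytest.raises(GenotypeError):
            qc_filter(g)


class TestImputeAndG:
    def test_impute_fills_two_p(self):
        g = make_geno(np.array([[0.0], [np.nan], [2.0]]))
        out = impute_mean(g)
        np.testing.assert_array_equal(out[:, 0], [0, 1, 2])

    def test_impute_preserves_column_mean(self):
        g = make_geno(np.array([[0, 1], [np.nan, 1], [2, np.nan], [1, 0]]))
        out = impute_mean(g)
        np.testing.assert_allclose(out.mean(axis=0),
                                   np.nanmean(g.dosages, axis=0))

    def test_single_snp_hand_algebra(self):
        # p=0.5, dosages [0,2]: W=[-1,1], denom 0.5 → G = [[2,-2],[-2,2]]
        gm = vanraden_g(np.array([[0.0], [2.0]]), np.array([0.5]))
        np.testing.assert_allclose(gm.G, [[2, -2], [-2, 2]])

    def test_centered_columns_sum_to_zero(self, small_dataset):
        cfg, ped, geno, phen, truth = small_dataset
        g2, _ = qc_filter(geno)
        dos = impute_mean(g2)
        p = dos.mean(axis=0) / 2
        W = center_dosages(dos, p)
        np.testing.assert_allclose(W.sum(axis=0), 0.0, atol=1e-8)

    def test_mean_diagonal_near_one_in_hwe(self):
        rng = np.random.default_rng(1)
        n, m = 200, 5000
        p = rng.uniform(0.1, 0.9, size=m)
        dos = rng.binomial(2, p, size=(n, m)).astype(float)
        gm = vanraden_g(dos, dos.mean(axis=0) / 2)
        assert abs(np.diag(gm.G).mean() - 1.0) < 0.05

    def test_duplicate_animals_duplicate_rows(self):
        dos = np.array([[0.0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 1, 1]])
        gm = vanraden_g(dos, np.array([0.4, 0.5, 0.6]))
        np.testing.assert_allclose(gm.G[0], gm.G[1])
        np.testing.assert_allclose(gm.G[:, 0], gm.G[:, 1])

    def test_monomorphic_rejected(self):
        with pytest.raises(GenotypeError):
            vanraden_g(np.array([[2.0], [2.0]]), np.array([1.0]))


class TestBlendTune:
    def test_a22_fixed_point(self):
        rng = np.random.default_rng(2)
        B = rng.normal(size=(10, 10))
        A22 = B @ B.T / 10 + np.eye(10)
        G_star, params = blend_tune_g(A22.copy(), A22)
        np.testing.assert_allclose(G_star, A22, atol=1e-10)

    def test_blend_one_pretuned_identity(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(8, 8))
        G = B @ B.T / 8
        G_star, _ = blend_tune_g(G, np.eye(8), blend_w=1.0, tune=False)
        np.testing.assert_array_equal(G_star, G)

    def test_result_positive_definite(self):
        rng = np.random.default_rng(4)
        n, m = 40, 20
        dos = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        gm = vanraden_g(dos, dos.mean(axis=0) / 2)   # rank-deficient: n > m
        A22 = np.eye(n) + 0.05
        G_star, _ = blend_tune_g(gm.G, A22)
        assert np.linalg.eigvalsh(G_star).min() > 0
        inverse_spd(G_star)   # must factor

    def test_invalid_weight_rejected(self):
        with pytest.raises(GenotypeError):
            blend_tune_g(np.eye(2), np.eye(2), blend_w=0.0)
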