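import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from singlestep.mixed_model import (ModelError, ai_reml, build_design,
                                    h_inverse, heritability,
                                    reml_loglik_dense, solve_mme)
from singlestep.pedigree import a22, a_inverse, a_matrix, sort_pedigree
from conftest import random_pedigree


def pedigree_model(n=150, seed=3, h2=0.4, var_p=10.0):
    """Random pedigree + phenotypes drawn from the exact animal model."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(n, seed=seed)
    A = a_matrix(ped)
    sa, se = h2 * var_p, (1 - h2) * var_p
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    a = L @ rng.normal(size=n) * np.sqrt(sa)
    phen = pd.DataFrame({
        "id": list(ped.ids),
        "hys": rng.choice(["h1", "h2", "h3"], n),
        "sex": rng.choice(["M", "F"], n),
    })
    dm0 = build_design(phen.assign(trait=0.0), ped)
    beta = np.linspace(1.0, 2.0, dm0.X.shape[1])
    phen["trait"] = dm0.X @ beta + a + rng.normal(size=n) * np.sqrt(se)
    return ped, phen, A, (sa, se)


class TestBuildDesign:
    def test_dummy_coding_column_count(self):
        ped = sort_pedigree([(i, 0, 0) for i in range(1, 5)])
        phen = pd.DataFrame({"id": [1, 2, 3, 4],
                             "hys": ["a", "a", "b", "b"],
                             "sex": ["M", "F", "M", "F"],
                             "trait": [1.0, 2, 3, 4]})
        dm = build_design(phen, ped)
        assert dm.X.shape[1] == 3            # intercept + 1 HYS + 1 sex
        assert dm.fixed_names[0] == "intercept"

    def test_z_is_row_selection(self):
        ped = sort_pedigree([(i, 0, 0) for i in range(1, 4)])
        phen = pd.DataFrame({"id": [3, 1], "hys": ["a", "a"],
                             "sex": ["M", "F"], "trait": [1.0, 2.0]})
        dm = build_design(phen, ped)
        Z = dm.Z.toarray()
        assert Z[0, ped.id_index[3]] == 1 and Z[1, ped.id_index[1]] == 1
        assert Z.sum() == 2

    def test_repeated_records_share_column(self):
        ped = sort_pedigree([(1, 0, 0), (2, 0, 0)])
        phen = pd.DataFrame({"id": [1, 1], "hys": ["a", "b"],
                             "sex": ["M", "M"], "trait": [1.0, 2.0]})
        dm = build_design(phen, ped, fixed=("hys",))
        Z = dm.Z.toarray()
        np.testing.assert_array_equal(Z[0], Z[1])

    def test_unknown_animal_rejected(self):
        ped = sort_pedigree([(1, 0, 0)])
        phen = pd.DataFrame({"id": [9], "hys": ["a"], "sex": ["M"],
                             "trait": [1.0]})
        with pytest.raises(ModelError, match="9"):
            build_design(phen, ped)


class TestHInverse:
    def test_no_genotyped_animals_is_a_inverse(self):
        ped = random_pedigree(50, seed=1)
        Ai = a_inverse(ped)
        Hi = h_inverse(Ai, np.empty((0, 0)), np.empty((0, 0)),
                       np.array([], dtype=int))
        assert (Hi != Ai.tocsr()).nnz == 0

    def test_gstar_equal_a22_vanishes(self):
        ped = random_pedigree(60, seed=2)
        ids = list(ped.ids[-20:])
        A22, A22i = a22(ped, ids)
        Ai = a_inverse(ped)
        Hi = h_inverse(Ai, A22i, np.linalg.inv(A22), ped.indices_of(ids))
        np.testing.assert_allclose(Hi.toarray(), Ai.toarray(), atol=1e-8)

    def test_blockwise_matches_dense_inverse(self):
        # H defined blockwise: H22 = G*, H rebuilt densely and inverted
        ped = random_pedigree(100, seed=4)
        ids = list(ped.ids[-30:])
        idx = ped.indices_of(ids)
        A = a_matrix(ped)
        A22 = A[np.ix_(idx, idx)]
        rng = np.random.default_rng(0)
        B = rng.normal(size=(30, 30))
        G_star = A22 + 0.1 * (B @ B.T) / 30
        # dense H: A with genotyped block replaced via conditional formula
        A12 = np.delete(np.delete(A, idx, axis=0), [], axis=1)[:, idx]
        mask = np.ones(100, dtype=bool)
        mask[idx] = False
        A11 = A[np.ix_(mask, mask)]
        A12 = A[np.ix_(mask, idx)]
        A22i = np.linalg.inv(A22)
        H11 = A11 + A12 @ A22i @ (G_star - A22) @ A22i @ A12.T
        H12 = A12 @ A22i @ G_star
        H = np.zeros((100, 100))
        H[np.ix_(mask, mask)] = H11
        H[np.ix_(mask, idx)] = H12
        H[np.ix_(idx, mask)] = H12.T
        H[np.ix_(idx, idx)] = G_star
        Hi_dense = np.linalg.inv(H)
        Hi = h_inverse(a_inverse(ped), A22i, np.linalg.inv(G_star), idx)
        np.testing.assert_allclose(Hi.toarray(), Hi_dense, atol=1e-6)

    def test_asymmetric_input_rejected(self):
        ped = random_pedigree(20, seed=5)
        M = np.eye(5)
        M[0, 1] = 0.5
        with pytest.raises(ModelError, match="symmetric"):
            h_inverse(a_inverse(ped), M, np.eye(5),
                      ped.indices_of(list(ped.ids[-5:])))


class TestSolveMme:
    def test_scalar_shrinkage(self):
        # one animal, one record, known mean zero: â = y·σ²ₐ/(σ²ₐ+σ²ₑ)
        ped = sort_pedigree([(1, 0, 0)])
        y = np.array([3.0])
        from singlestep.mixed_model import DesignMatrices
        dm = DesignMatrices(y=y, X=np.zeros((1, 0)), Z=sp.eye(1, format="csr"),
                            fixed_names=[], record_ids=[1])
        sol = solve_mme(dm, sp.eye(1, format="csr"), 2.0, 3.0)
        assert sol.a_hat[0] == pytest.approx(3.0 * 2.0 / 5.0)

    def test_vanishing_additive_variance_shrinks_to_zero(self):
        ped, phen, A, _ = pedigree_model(60, seed=7)
        dm = build_design(phen, ped)
        sol = solve_mme(dm, a_inverse(ped), 1e-8, 1.0)
        assert np.abs(sol.a_hat).max() < 1e-4

    def test_matches_dense_normal_equations(self):
        ped, phen, A, (sa, se) = pedigree_model(300, seed=8)
        dm = build_design(phen, ped)
        sol = solve_mme(dm, a_inverse(ped), sa, se)
        X, Z, y = dm.X, dm.Z.toarray(), dm.y
        lam = se / sa
        C = np.block([[X.T @ X, X.T @ Z],
                      [Z.T @ X, Z.T @ Z + lam * np.linalg.inv(A)]])
        sol_dense = np.linalg.solve(C, np.concatenate([X.T @ y, Z.T @ y]))
        p = X.shape[1]
        assert np.abs(sol.b_hat - sol_dense[:p]).max() < 1e-6
        assert np.abs(sol.a_hat - sol_dense[p:]).max() < 1e-6

    def test_residual_orthogonal_to_fixed_effects(self):
        ped, phen, A, (sa, se) = pedigree_model(100, seed=9)
        dm = build_design(phen, ped)
        sol = solve_mme(dm, a_inverse(ped), sa, se)
        # MME first block: Xᵀ(y − Xb̂ − Zâ) = 0
        np.testing.assert_allclose(dm.X.T @ sol.residuals, 0.0, atol=1e-8)

    def test_unrecorded_progenyless_animal_gets_parent_average(self):
        recs = [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)]
        ped = sort_pedigree(recs)
        rng = np.random.default_rng(10)
        phen = pd.DataFrame({"id": [1, 2, 3, 4],
                             "hys": ["a"] * 4, "sex": ["M"] * 4,
                             "trait": rng.normal(size=4)})
        dm = build_design(phen, ped, fixed=())
        sol = solve_mme(dm, a_inverse(ped), 1.0, 1.0)
        i5 = ped.id_index[5]
        pa = 0.5 * (sol.a_hat[ped.id_index[3]] + sol.a_hat[ped.id_index[4]])
        assert sol.a_hat[i5] == pytest.approx(pa, abs=1e-10)


class TestAiReml:
    def test_recovers_components_on_exact_model_data(self):
        ped, phen, A, (sa, se) = pedigree_model(400, seed=11, h2=0.4)
        dm = build_design(phen, ped)
        vc = ai_reml(dm, a_inverse(ped))
        assert vc.converged
        assert vc.h2 == pytest.approx(0.4, abs=0.2)   # single replicate
        # internal likelihood equals the dense-V oracle at the optimum
        vc1 = ai_reml(dm, a_inverse(ped), start=(vc.sigma_a2, vc.sigma_e2),
                      max_iter=1)
        dense = reml_loglik_dense(dm.y, dm.X, A, vc.sigma_a2, vc.sigma_e2,
                                  dm.Z)
        assert vc1.log_likelihoods[0] == pytest.approx(dense, abs=1e-6)

    def test_null_heritability_hits_boundary(self):
        rng = np.random.default_rng(12)
        ped = random_pedigree(600, seed=12)
        phen = pd.DataFrame({"id": list(ped.ids), "hys": "h1", "sex": "M",
                             "trait": rng.normal(size=600)})
        dm = build_design(phen, ped, fixed=())
        vc = ai_reml(dm, a_inverse(ped))
        assert vc.h2 < 0.05

    def test_em_fallback_likelihood_nondecreasing(self):
        ped, phen, A, _ = pedigree_model(120, seed=13)
        dm = build_design(phen, ped)
        # pathological start forces early EM fallbacks
        vc = ai_reml(dm, a_inverse(ped), start=(1e-4, 50.0))
        lls = vc.log_likelihoods
        drops = [b - a for a, b in zip(lls, lls[1:]) if b < a - 1e-6]
        assert not drops, f"likelihood decreased: {drops}"

    def test_mean_estimate_and_coverage_over_replicates(self):
        h2s, cover = [], 0
        for rep in range(10):
            ped, phen, A, (sa, se) = pedigree_model(600, seed=50 + rep, h2=0.5)
            dm = build_design(phen, ped)
            vc = ai_reml(dm, a_inverse(ped))
            h2s.append(vc.h2)
            if abs(vc.h2 - 0.5) <= 2 * vc.se_h2:
                cover += 1
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.05)
        assert cover >= 8


class TestHeritability:
    @pytest.mark.parametrize("sa,se,expected", [
        (66.74, 67.31, 0.50),     # fast-growth trait, single-step fit
        (59.24, 69.29, 0.46),     # same trait, pedigree-only fit
        (2.01, 6.62, 0.23),       # muscle-area trait
        (3.70, 3.81, 0.49),       # backfat trait
        (0.0, 1.0, 0.0),
    ])
    def test_ratio_at_two_decimals(self, sa, se, expected):
        assert round(heritability(sa, se), 2) == expected

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ModelError):
            heritability(0.0, 0.0)
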