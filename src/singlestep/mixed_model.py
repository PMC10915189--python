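"""Single-trait animal model: design matrices, H⁻¹, MME solving, AI-REML.

The model is y = Xb + Za + e with fixed herd-year-season and sex effects
and a single additive genetic effect a ~ N(0, σ²ₐ K), where K is either the
pedigree relationship matrix A (PBLUP) or the single-step matrix H that
combines A with the genomic relationship matrix of the genotyped subset
(ssGBLUP).  Only K⁻¹ is ever formed:

    H⁻¹ = A⁻¹ + [0 0; 0  G*⁻¹ − A₂₂⁻¹]

Variance components are estimated by average-information REML on the
mixed-model equations, with EM fallback steps whenever a Newton update
leaves the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree


class ModelError(ValueError):
    pass


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray                  # dense, full column rank
    Z: sp.csr_matrix               # records × pedigree animals
    fixed_names: list
    record_ids: list


def build_design(phen: pd.DataFrame, ped: Pedigree, trait: str = "trait",
                 fixed: tuple = ("hys", "sex")) -> DesignMatrices:
    """Incidence matrices for the animal model.

    X carries an intercept plus dummy columns for each categorical fixed
    factor with one reference level dropped (full rank, set-to-zero
    constraint); Z maps each record to its animal's pedigree slot.
    """
    missing = [a for a in phen["id"] if a not in ped.id_index]
    if missing:
        raise ModelError(f"phenotyped animals absent from pedigree: {missing[:10]}")
    y = phen[trait].to_numpy(dtype=float)
    n = len(phen)

    cols = [np.ones(n)]
    names = ["intercept"]
    for f in fixed:
        levels = pd.Categorical(phen[f].astype(str))
        counts = pd.Series(levels).value_counts()
        if (counts == 1).any():
            import warnings
            warnings.warn(f"factor {f!r} has levels with a single observation",
                          stacklevel=2)
        for lev in levels.categories[1:]:   # first level = reference
            cols.append((levels == lev).astype(float))
            names.append(f"{f}:{lev}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effect design is rank deficient "
                         "(confounded factor levels)")

    rows = np.arange(n)
    cols_z = ped.indices_of(phen["id"])
    Z = sp.csr_matrix((np.ones(n), (rows, cols_z)), shape=(n, ped.n))
    return DesignMatrices(y=y, X=X, Z=Z, fixed_names=names,
                          record_ids=list(phen["id"]))


def h_inverse(a_inv: sp.spmatrix, a22_inv: np.ndarray, g_star_inv: np.ndarray,
              genotyped_idx: np.ndarray) -> sp.csr_matrix:
    """Assemble H⁻¹ = A⁻¹ + correction on the genotyped block.

    The correction G*⁻¹ − A₂₂⁻¹ is added at the genotyped animals' rows and
    columns; outside that block H⁻¹ equals A⁻¹ exactly.
    """
    for name, M in (("a22_inv", a22_inv), ("g_star_inv", g_star_inv)):
        if not np.allclose(M, M.T, atol=1e-8):
            raise ModelError(f"{name} is not symmetric")
    corr = g_star_inv - a22_inv
    idx = np.asarray(genotyped_idx, dtype=np.int64)
    n_g = len(idx)
    if corr.shape != (n_g, n_g):
        raise ModelError("correction block does not match genotyped index set")
    rows = np.repeat(idx, n_g)
    cols = np.tile(idx, n_g)
    corr_sp = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=a_inv.shape)
    return (a_inv.tocsr() + corr_sp.tocsr()).tocsr()


@dataclass
class MMESolution:
    b_hat: np.ndarray
    a_hat: np.ndarray
    fixed_names: list
    sigma_a2: float
    sigma_e2: float
    residuals: np.ndarray
    C_inv: np.ndarray | None = field(default=None, repr=False)
    n_fixed: int = 0

    def pev(self) -> np.ndarray:
        """Prediction error variance of â (diagonal)."""
        if self.C_inv is None:
            raise ModelError("solve with return_inverse=True to obtain PEV")
        return np.diag(self.C_inv)[self.n_fixed:] * self.sigma_e2

    def caa(self, idx=None) -> np.ndarray:
        """Inverse-coefficient block for the animal effects (optionally sliced)."""
        if self.C_inv is None:
            raise ModelError("solve with return_inverse=True to obtain C blocks")
        blk = self.C_inv[self.n_fixed:, self.n_fixed:]
        if idx is None:
            return blk
        idx = np.asarray(idx)
        return blk[np.ix_(idx, idx)]


def _assemble_mme(dm: DesignMatrices, K_inv: sp.spmatrix, lam: float):
    X, Z, y = dm.X, dm.Z, dm.y
    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = (Z.T @ Z).toarray()
    C = np.block([[XtX, XtZ.toarray() if sp.issparse(XtZ) else np.asarray(XtZ)],
                  [np.asarray(XtZ.T.toarray() if sp.issparse(XtZ) else XtZ.T),
                   ZtZ + lam * K_inv.toarray()]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    return C, rhs


def solve_mme(dm: DesignMatrices, K_inv: sp.spmatrix, sigma_a2: float,
              sigma_e2: float, return_inverse: bool = False) -> MMESolution:
    """Solve Henderson's mixed-model equations.

    [XᵀX  XᵀZ; ZᵀX  ZᵀZ + λK⁻¹][b̂; â] = [Xᵀy; Zᵀy],  λ = σ²ₑ/σ²ₐ.

    A dense Cholesky factorization is used (the systems here are desk
    scale); ``return_inverse=True`` additionally materializes C⁻¹ for PEV
    and GWAS sampling variances.
    """
    if sigma_a2 <= 0 or sigma_e2 <= 0:
        raise ModelError("variances must be positive to solve the MME")
    lam = sigma_e2 / sigma_a2
    C, rhs = _assemble_mme(dm, K_inv, lam)
    p = dm.X.shape[1]
    try:
        cf = scipy.linalg.cho_factor(C)
    except scipy.linalg.LinAlgError as exc:
        raise ModelError("singular mixed-model equations "
                         "(confounded fixed-effect levels?)") from exc
    sol = scipy.linalg.cho_solve(cf, rhs)
    b_hat, a_hat = sol[:p], sol[p:]
    resid = dm.y - dm.X @ b_hat - dm.Z @ a_hat
    C_inv = scipy.linalg.cho_solve(cf, np.eye(C.shape[0])) if return_inverse else None
    return MMESolution(b_hat=b_hat, a_hat=a_hat, fixed_names=dm.fixed_names,
                       sigma_a2=sigma_a2, sigma_e2=sigma_e2, residuals=resid,
                       C_inv=C_inv, n_fixed=p)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    converged: bool
    n_iterations: int
    log_likelihoods: list = field(default_factory=list)
    cov: np.ndarray | None = None

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2


def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """h² = σ²ₐ / (σ²ₐ + σ²ₑ)."""
    tot = sigma_a2 + sigma_e2
    if tot <= 0:
        raise ModelError("total variance must be positive")
    return sigma_a2 / tot


def ai_reml(dm: DesignMatrices, K_inv: sp.spmatrix,
            start: tuple[float, float] | None = None, tol: float = 1e-8,
            max_iter: int = 200, verbose: bool = False) -> VarianceComponents:
    """Average-information REML for (σ²ₐ, σ²ₑ) on the animal model.

    Newton steps use the AI matrix (average of observed and expected
    information), computed from MME solves only; first derivatives use the
    standard trace identities tr(P) = (n − p − q + λ·tr(K⁻¹Cᵃᵃ))/σ²ₑ and
    tr(PZKZᵀ) = (q − λ·tr(K⁻¹Cᵃᵃ))/σ²ₐ.  Whenever an AI update leaves the
    parameter space the iteration falls back to an EM step, which cannot
    decrease the REML likelihood.  SE of h² by the delta method from the
    inverse AI matrix at convergence.
    """
    y, X, Z = dm.y, dm.X, dm.Z
    n, p = X.shape
    q = Z.shape[1]
    if n <= p:
        raise ModelError("need more records than fixed-effect columns")
    K_inv = K_inv.tocsr()
    var_y = float(np.var(y, ddof=1))
    if start is None:
        start = (0.5 * var_y, 0.5 * var_y)
    sa, se = float(start[0]), float(start[1])
    floor = max(1e-8 * var_y, 1e-12)

    # log|K| = −log|K⁻¹| via sparse LU, once (constant across iterations)
    lu = spla.splu(K_inv.tocsc())
    diagU = lu.U.diagonal()
    logdet_Kinv = float(np.sum(np.log(np.abs(diagU))))
    log_K = -logdet_Kinv

    XtY = X.T @ y
    ZtY = Z.T @ y

    logls: list[float] = []
    converged = False
    it = 0
    AI = np.eye(2)
    for it in range(1, max_iter + 1):
        lam = se / sa
        C, rhs = _assemble_mme(dm, K_inv, lam)
        cf = scipy.linalg.cho_factor(C)
        sol = scipy.linalg.cho_solve(cf, rhs)
        b_hat, a_hat = sol[:p], sol[p:]
        e_hat = y - X @ b_hat - Z @ a_hat

        C_inv = scipy.linalg.cho_solve(cf, np.eye(C.shape[0]))
        Caa = C_inv[p:, p:]
        T = float(K_inv.multiply(Caa).sum())         # tr(K⁻¹ Cᵃᵃ)

        # REML log-likelihood (up to the usual constant)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        yPy = float(y @ y - b_hat @ XtY - a_hat @ ZtY) / se
        logl = -0.5 * ((n - p) * np.log(se) + log_K - q * np.log(lam)
                       + logdet_C + yPy)
        logls.append(logl)

        # scores
        eZa = float(e_hat @ (Z @ a_hat))
        score_a = -0.5 * ((q - lam * T) / sa - eZa / (se * sa))
        score_e = -0.5 * ((n - p - q + lam * T) / se
                          - float(e_hat @ e_hat) / se ** 2)

        # AI matrix from working vectors f_a = Zâ/σ²ₐ, f_e = ê/σ²ₑ
        f_a = (Z @ a_hat) / sa
        f_e = e_hat / se
        Pf = []
        for f in (f_a, f_e):
            rhs_f = np.concatenate([X.T @ f, Z.T @ f])
            sol_f = scipy.linalg.cho_solve(cf, rhs_f)
            Pf.append((f - X @ sol_f[:p] - Z @ sol_f[p:]) / se)
        AI = 0.5 * np.array([[f_a @ Pf[0], f_a @ Pf[1]],
                             [f_e @ Pf[0], f_e @ Pf[1]]])
        AI = 0.5 * (AI + AI.T)

        # Newton step, EM fallback if it leaves the parameter space
        step_ok = False
        try:
            delta = np.linalg.solve(AI, np.array([score_a, score_e]))
            sa_new, se_new = sa + delta[0], se + delta[1]
            if sa_new > floor and se_new > floor and np.isfinite([sa_new, se_new]).all():
                step_ok = True
        except np.linalg.LinAlgError:
            pass
        if not step_ok:
            sa_new = (float(a_hat @ (K_inv @ a_hat)) + se * T) / q
            se_new = float(e_hat @ y) / (n - p)
            sa_new = max(sa_new, floor)
            se_new = max(se_new, floor)

        rel = max(abs(sa_new - sa) / max(sa, floor),
                  abs(se_new - se) / max(se, floor))
        sa, se = float(sa_new), float(se_new)
        if verbose:
            print(f"iter {it}: sa={sa:.6g} se={se:.6g} logl={logl:.6f} rel={rel:.2e}")
        if rel < tol:
            converged = True
            break

    h2 = heritability(sa, se)
    # delta method: var(h²) = gᵀ AI⁻¹ g with g = (σ²ₑ, −σ²ₐ)/σ⁴ₚ
    try:
        cov = np.linalg.inv(AI)
        g = np.array([se, -sa]) / (sa + se) ** 2
        se_h2 = float(np.sqrt(max(g @ cov @ g, 0.0)))
    except np.linalg.LinAlgError:
        cov, se_h2 = None, float("nan")
    return VarianceComponents(sigma_a2=sa, sigma_e2=se, h2=h2, se_h2=se_h2,
                              converged=converged, n_iterations=it,
                              log_likelihoods=logls, cov=cov)


def reml_loglik_dense(y, X, K, sigma_a2, sigma_e2, Z=None) -> float:
    """REML log-likelihood by direct dense V computation (test oracle).

    −½[log|V| + log|XᵀV⁻¹X| + yᵀPy] with V = σ²ₐ ZKZᵀ + σ²ₑ I.  Intended
    for small problems; the MME-based value in :func:`ai_reml` must agree
    up to the shared constant.
    """
    n = len(y)
    if Z is None:
        Z = np.eye(n)
    Z = Z.toarray() if sp.issparse(Z) else np.asarray(Z)
    V = sigma_a2 * (Z @ K @ Z.T) + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtVX, X.T @ Vi)
    (_, ld_V) = np.linalg.slogdet(V)
    (_, ld_X) = np.linalg.slogdet(XtVX)
    return float(-0.5 * (ld_V + ld_X + y @ P @ y))
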