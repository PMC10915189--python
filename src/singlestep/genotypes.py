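"""Genotype I/O, quality control and the genomic relationship matrix.

Reads PLINK text (.ped/.map) or a plain dosage TSV, applies SNP-level QC
(call rate < 90%, MAF < 0.01, Hardy–Weinberg exact-test p < 1e-6, in that
order — the filters and thresholds standard for commercial SNP-chip data),
mean-imputes surviving missing calls, and builds the VanRaden genomic
relationship matrix G = WWᵀ / (2Σpⱼ(1−pⱼ)), optionally tuned to the
pedigree block A₂₂ and blended for invertibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

MISSING = np.nan


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeData:
    """Animal × SNP dosages (0/1/2/NaN) plus a marker map.

    ``markers`` columns: chrom, snp_id, cm, bp, a1, a2 (a1 = counted allele).
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    animal_ids: list

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1] if self.dosages.ndim == 2 else len(self.markers)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeData":
        return GenotypeData(
            dosages=self.dosages[:, mask],
            markers=self.markers.loc[mask].reset_index(drop=True),
            animal_ids=list(self.animal_ids),
        )


@dataclass
class QCReport:
    n_snps_before: int
    n_snps_after: int
    n_animals: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_snps_before": self.n_snps_before,
            "n_snps_after": self.n_snps_after,
            "n_animals": self.n_animals,
            "removed_call_rate": self.removed_call_rate,
            "removed_maf": self.removed_maf,
            "removed_hwe": self.removed_hwe,
            **{f"threshold_{k}": v for k, v in self.thresholds.items()},
        }])


# ---------------------------------------------------------------------------
# PLINK text I/O

def read_plink_text(ped_path, map_path, counted_alleles=None) -> GenotypeData:
    """Read PLINK text .ped/.map into dosages of the minor allele.

    The counted allele per SNP is the minor allele determined from the data
    (ties broken toward the lexicographically smaller allele); "0 0" means
    missing.  Pass ``counted_alleles`` (one allele per mapped SNP, as with
    PLINK's --recode-allele) to force the coding orientation instead.
    Raises on ragged .ped lines and on .ped/.map marker-count mismatch,
    naming the offending line.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "bp"], dtype={"chrom": str})
    m = len(mp)
    animal_ids, allele_rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeError(
                    f"{ped_path}: line {ln} has {len(parts)} fields, "
                    f"expected {6 + 2 * m} for {m} mapped SNPs")
            animal_ids.append(_coerce_id(parts[1]))
            allele_rows.append(parts[6:])
    n = len(animal_ids)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else \
        np.empty((0, m, 2), dtype=object)

    dosages = np.full((n, m), MISSING)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :] if n else np.empty((0, 2), dtype=object)
        obs = col[col != "0"]
        uniq = sorted(set(obs.tolist()))
        if len(uniq) > 2:
            raise GenotypeError(f"SNP {mp['snp_id'][j]} has >2 alleles: {uniq}")
        if counted_alleles is not None:
            a1 = str(counted_alleles[j])
            others = [u for u in uniq if u != a1]
            a2 = others[0] if others else a1
        elif not uniq:
            a1, a2 = "0", "0"
        elif len(uniq) == 1:
            a1, a2 = uniq[0], uniq[0]
        else:
            c0 = int((obs == uniq[0]).sum())
            c1 = int((obs == uniq[1]).sum())
            # minor allele counted; lexicographic tie-break
            a1, a2 = (uniq[0], uniq[1]) if c0 <= c1 else (uniq[1], uniq[0])
        a1_list.append(a1)
        a2_list.append(a2)
        if n:
            miss = (col == "0").any(axis=1)
            dosages[~miss, j] = (col[~miss] == a1).sum(axis=1)
    markers = mp.copy()
    markers["a1"] = a1_list
    markers["a2"] = a2_list
    return GenotypeData(dosages=dosages, markers=markers, animal_ids=animal_ids)


def _coerce_id(v):
    try:
        return int(v)
    except (TypeError, ValueError):
        return v


def write_plink_text(g: GenotypeData, ped_path, map_path) -> None:
    """Write PLINK text files; missing dosages become "0 0"."""
    g.markers[["chrom", "snp_id", "cm", "bp"]].to_csv(
        map_path, sep="\t", header=False, index=False)
    a1 = g.markers["a1"].to_numpy()
    a2 = g.markers["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(g.animal_ids):
            fields = [str(aid), str(aid), "0", "0", "0", "-9"]
            row = g.dosages[i]
            for j in range(g.n_snps):
                d = row[j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def read_dosage_tsv(path) -> GenotypeData:
    """Read an id × SNP dosage TSV (header = SNP ids, first column = id).

    A minimal marker map is synthesized (one chromosome, unit spacing)
    unless the SNP ids encode positions elsewhere.
    """
    df = pd.read_csv(path, sep="\t")
    ids = [_coerce_id(v) for v in df.iloc[:, 0]]
    dos = df.iloc[:, 1:].to_numpy(dtype=float)
    snp_ids = list(df.columns[1:])
    markers = pd.DataFrame({
        "chrom": "1", "snp_id": snp_ids,
        "cm": np.arange(len(snp_ids), dtype=float),
        "bp": np.arange(1, len(snp_ids) + 1), "a1": "A", "a2": "B"})
    bad = ~(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0)))
    if bad.any():
        raise GenotypeError("dosage TSV contains values outside {0,1,2,NaN}")
    return GenotypeData(dosages=dos, markers=markers, animal_ids=ids)


# ---------------------------------------------------------------------------
# QC statistics

def allele_frequencies(g: GenotypeData) -> np.ndarray:
    """Counted-allele frequency p per SNP = mean dosage / 2 over observed calls.

    All-missing SNPs get NaN (frequency undefined).
    """
    with np.errstate(invalid="ignore"):
        return np.nanmean(g.dosages, axis=0) / 2.0


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy–Weinberg test p-value (Wigginton et al. 2005).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise GenotypeError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise GenotypeError("no genotyped individuals")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # possible het counts share parity with n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log unnormalized probabilities of each het count
    log_probs = np.array([_log_hwe_weight(h, n_rare, n) for h in hets])
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _log_hwe_weight(n_het: int, n_rare: int, n: int) -> float:
    # P(het = h | allele counts) ∝ n! / (hom_r! h! hom_c!) * 2^h
    hom_r = (n_rare - n_het) // 2
    hom_c = n - hom_r - n_het
    return (n_het * math.log(2.0)
            - math.lgamma(hom_r + 1) - math.lgamma(n_het + 1)
            - math.lgamma(hom_c + 1))


def hwe_pvalues(g: GenotypeData) -> np.ndarray:
    p = np.ones(g.n_snps)
    d = g.dosages
    for j in range(g.n_snps):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        n_AA = int((obs == 2).sum())
        n_Aa = int((obs == 1).sum())
        n_aa = int((obs == 0).sum())
        p[j] = hwe_exact_test(n_AA, n_Aa, n_aa)
    return p


def qc_filter(g: GenotypeData, call_rate: float = 0.90, maf: float = 0.01,
              hwe_p: float = 1e-6) -> tuple[GenotypeData, QCReport]:
    """SNP-level QC in fixed order: call rate → MAF → HWE.

    Each removed SNP is attributed to the first filter it fails; animals
    are never removed.  Raises if no SNP survives.
    """
    d = g.dosages
    n, m = d.shape
    observed = ~np.isnan(d)
    cr = observed.mean(axis=0) if n else np.zeros(m)
    fail_cr = cr < call_rate

    with np.errstate(invalid="ignore"):
        p = np.where(observed.any(axis=0), np.nanmean(d, axis=0) / 2.0, np.nan)
    maf_vec = np.minimum(p, 1.0 - p)
    fail_maf = (~fail_cr) & (np.isnan(maf_vec) | (maf_vec < maf))

    fail_hwe = np.zeros(m, dtype=bool)
    rest = ~(fail_cr | fail_maf)
    for j in np.where(rest)[0]:
        col = d[:, j]
        obs = col[~np.isnan(col)]
        pj = hwe_exact_test(int((obs == 2).sum()), int((obs == 1).sum()),
                            int((obs == 0).sum()))
        if pj < hwe_p:
            fail_hwe[j] = True

    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise GenotypeError("no SNPs survive QC; downstream analysis undefined")
    report = QCReport(
        n_snps_before=m, n_snps_after=int(keep.sum()), n_animals=n,
        removed_call_rate=int(fail_cr.sum()), removed_maf=int(fail_maf.sum()),
        removed_hwe=int(fail_hwe.sum()),
        thresholds={"call_rate": call_rate, "maf": maf, "hwe_p": hwe_p},
    )
    return g.subset_snps(keep), report


def impute_mean(g: GenotypeData) -> np.ndarray:
    """Replace missing dosages with 2p of their SNP; returns a complete matrix."""
    p = allele_frequencies(g)
    d = g.dosages.copy()
    miss = np.isnan(d)
    d[miss] = np.broadcast_to(2.0 * p, d.shape)[miss]
    return d


# ---------------------------------------------------------------------------
# genomic relationship matrix

@dataclass
class GMatrix:
    G: np.ndarray
    allele_freqs: np.ndarray
    scale: float                      # 2 Σ p(1-p), the VanRaden denominator
    blend_weight: float | None = None
    tune_alpha: float | None = None   # additive tuning offset
    tune_beta: float | None = None    # multiplicative tuning factor


def vanraden_g(dosages: np.ndarray, p: np.ndarray) -> GMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    W = M − 2p (columns centered at twice the allele frequency);
    G = WWᵀ / (2Σ pⱼ(1−pⱼ)).  Requires a complete dosage matrix and
    0 < p < 1 for every SNP.
    """
    if np.isnan(dosages).any():
        raise GenotypeError("dosage matrix has missing values; impute first")
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise GenotypeError("monomorphic SNP (p outside (0,1)); filter first")
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    if scale <= 0:
        raise GenotypeError("zero VanRaden denominator (all SNPs monomorphic)")
    W = dosages - 2.0 * p
    G = (W @ W.T) / scale
    return GMatrix(G=G, allele_freqs=p, scale=scale)


def center_dosages(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """W = M − 2p, the centered coefficient matrix used by G and the back-solve."""
    return dosages - 2.0 * np.asarray(p, dtype=float)


def blend_tune_g(G: np.ndarray, A22: np.ndarray, blend_w: float = 0.95,
                 tune: bool = True) -> tuple[np.ndarray, dict]:
    """Tune G to A₂₂ moments and blend: G* = w·(α + βG) + (1−w)·A₂₂.

    Tuning solves mean(diag G*) = mean(diag A₂₂) and mean(offdiag G*) =
    mean(offdiag A₂₂); the convex blend with A₂₂ guarantees positive
    definiteness for w ∈ (0, 1).  Returns (G*, parameters dict).
    """
    if not (0.0 < blend_w <= 1.0):
        raise GenotypeError("blend_w must be in (0, 1]")
    n = G.shape[0]
    if A22.shape != G.shape:
        raise GenotypeError("G and A22 are not conformable")
    alpha, beta = 0.0, 1.0
    if tune and n > 1:
        off = ~np.eye(n, dtype=bool)
        md_g, mo_g = float(G.diagonal().mean()), float(G[off].mean())
        md_a, mo_a = float(A22.diagonal().mean()), float(A22[off].mean())
        denom = md_g - mo_g
        if abs(denom) > 1e-12:
            beta = (md_a - mo_a) / denom
            alpha = mo_a - beta * mo_g
    G_tuned = alpha + beta * G
    G_star = blend_w * G_tuned + (1.0 - blend_w) * A22
    params = {"blend_w": blend_w, "tune_alpha": alpha, "tune_beta": beta}
    return G_star, params


def inverse_spd(M: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    cf = scipy.linalg.cho_factor(M)
    return scipy.linalg.cho_solve(cf, np.eye(M.shape[0]))
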