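"""Synthetic breeding-population generator with known ground truth.

Generates a multi-generation pedigree under random hierarchical mating,
drops founder haplotypes down the pedigree with Haldane recombination to
create linked genotypes, and simulates phenotypes under the additive animal
model y = Xb + Za + e, so that every downstream stage (kinship, REML,
ssGBLUP, GWAS back-solving, LD) can be tested against known parameter
values.  The additive variance may be split between an explicit set of QTL
(markers with allele-substitution effects) and a residual polygenic term;
the split is rescaled so that total additive variance among founders equals
``sigma_a2`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, sort_pedigree, inbreeding
from .genotypes import GenotypeData


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults describe a small pig-nucleus-like population: a few hundred
    founders, four discrete generations of random hierarchical mating with
    a female-biased sex ratio, a SNP panel with linkage on several
    chromosomes, and a moderately heritable trait with herd-year-season and
    sex fixed effects.
    """

    n_founders: int = 120
    n_generations: int = 4
    offspring_per_mating: int = 2
    prop_genotyped: float = 0.5
    n_chrom: int = 5
    snps_per_chrom: int = 400
    chrom_length_morgans: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 0
    sigma_a2: float = 66.74
    sigma_e2: float = 67.31
    n_hys_levels: int = 5
    sex_effect: float = 2.0
    seed: int = 0
    # split of sigma_a2 carried by the QTL when n_qtl > 0
    qtl_variance_share: float = 0.1
    male_fraction: float = 0.17
    hys_sd: float | None = None   # default: half the phenotypic SD

    def validate(self) -> None:
        if self.n_founders < 2:
            raise SimulationError("n_founders must be ≥ 2 (no mating possible)")
        for name in ("n_generations", "n_qtl"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be ≥ 0")
        for name in ("offspring_per_mating", "n_chrom", "snps_per_chrom",
                     "n_hys_levels"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be ≥ 1")
        if not (0.0 <= self.prop_genotyped <= 1.0):
            raise SimulationError("prop_genotyped must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise SimulationError("need sigma_a2 ≥ 0 and sigma_e2 > 0")
        if self.chrom_length_morgans <= 0:
            raise SimulationError("chrom_length_morgans must be > 0")
        if not (0.0 <= self.qtl_variance_share <= 1.0):
            raise SimulationError("qtl_variance_share must be in [0, 1]")


@dataclass
class TrueValues:
    """Ground truth retained from a simulation run."""

    breeding_values: np.ndarray     # one per pedigree record, sorted order
    qtl_positions: np.ndarray       # global marker indices
    qtl_effects: np.ndarray         # allele-substitution effects
    realized_h2: float
    sex: np.ndarray = field(default=None, repr=False)        # "M"/"F"
    generation: np.ndarray = field(default=None, repr=False)


def _rng(cfg: SimConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None
                      ) -> tuple[Pedigree, np.ndarray, np.ndarray]:
    """Random hierarchical mating over discrete generations.

    Founders (generation 0) have unknown parents.  In each later
    generation every female of the previous generation is mated to one
    randomly drawn male of that generation (sires may serve several dams)
    and produces ``offspring_per_mating`` offspring.  Sex is assigned at a
    fixed ~``male_fraction`` ratio with at least one animal of each sex per
    generation.  Returns (pedigree, sex array, generation array); the
    pedigree is in topological order by construction.
    """
    cfg.validate()
    rng = _rng(cfg) if rng is None else rng
    ids, sires, dams, sexes, gens = [], [], [], [], []

    def assign_sex(n, g):
        n_male = min(max(1, round(cfg.male_fraction * n)), n - 1) if n >= 2 else 1
        sx = np.array(["F"] * n, dtype=object)
        sx[rng.choice(n, size=n_male, replace=False)] = "M"
        return sx

    founders_sex = assign_sex(cfg.n_founders, 0)
    next_id = 1
    prev_ids, prev_sex = [], []
    for k in range(cfg.n_founders):
        ids.append(next_id); sires.append(0); dams.append(0)
        sexes.append(founders_sex[k]); gens.append(0)
        prev_ids.append(next_id); prev_sex.append(founders_sex[k])
        next_id += 1

    for g in range(1, cfg.n_generations + 1):
        males = [a for a, s in zip(prev_ids, prev_sex) if s == "M"]
        females = [a for a, s in zip(prev_ids, prev_sex) if s == "F"]
        if not males or not females:
            raise SimulationError(f"generation {g - 1} lacks one sex entirely")
        n_off = len(females) * cfg.offspring_per_mating
        off_sex = assign_sex(n_off, g)
        cur_ids, cur_sex = [], []
        j = 0
        for dam in females:
            sire = males[rng.integers(len(males))]
            for _ in range(cfg.offspring_per_mating):
                ids.append(next_id); sires.append(sire); dams.append(dam)
                sexes.append(off_sex[j]); gens.append(g)
                cur_ids.append(next_id); cur_sex.append(off_sex[j])
                next_id += 1; j += 1
        prev_ids, prev_sex = cur_ids, cur_sex

    ped = sort_pedigree(list(zip(ids, sires, dams)))
    order = ped.indices_of(ids)  # ids are already topological; map anyway
    sex = np.empty(ped.n, dtype=object)
    gen = np.empty(ped.n, dtype=np.int64)
    sex[order] = sexes
    gen[order] = gens
    return ped, sex, gen


def _marker_map(cfg: SimConfig) -> pd.DataFrame:
    """Evenly spaced markers; 1 cM ≙ 1 Mb of physical position."""
    rows = []
    for c in range(cfg.n_chrom):
        m = cfg.snps_per_chrom
        cm = np.linspace(0.0, cfg.chrom_length_morgans * 100.0, m)
        bp = np.round(cm * 1_000_000).astype(np.int64) + 1
        for j in range(m):
            rows.append((str(c + 1), f"snp{c + 1}_{j + 1}", cm[j], int(bp[j])))
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "bp"])
    df["a1"], df["a2"] = "A", "B"
    return df


def _drop_genes(ped: Pedigree, cfg: SimConfig, rng: np.random.Generator
                ) -> np.ndarray:
    """Gene dropping: returns haplotypes, shape (N, 2, m_total), alleles 0/1.

    Founder alleles are drawn per SNP at a frequency uniform in maf_range.
    Gametes recombine under the Haldane model: the switch probability
    between adjacent markers at genetic distance d Morgans is
    r = ½(1 − e^{−2d}) (Poisson crossovers, no interference).
    """
    m_chrom = cfg.snps_per_chrom
    m_total = cfg.n_chrom * m_chrom
    n = ped.n
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m_total)
    hap = np.zeros((n, 2, m_total), dtype=np.int8)

    founders = np.where(ped.is_founder())[0]
    hap[founders] = (rng.random((len(founders), 2, m_total)) < freqs).astype(np.int8)

    # per-chromosome interval recombination fractions
    d = cfg.chrom_length_morgans / max(m_chrom - 1, 1)
    r = 0.5 * (1.0 - math.exp(-2.0 * d))

    non_founders = np.where(~ped.is_founder())[0]
    for i in non_founders:
        for which, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
            if parent < 0:
                # unknown parent: fresh base-population gamete
                gam = (rng.random(m_total) < freqs).astype(np.int8)
            else:
                gam = np.empty(m_total, dtype=np.int8)
                for c in range(cfg.n_chrom):
                    sl = slice(c * m_chrom, (c + 1) * m_chrom)
                    switches = rng.random(m_chrom) < r
                    switches[0] = rng.random() < 0.5  # random start haplotype
                    src = np.cumsum(switches) % 2
                    ph = hap[parent, :, sl]
                    gam[sl] = np.where(src == 0, ph[0], ph[1])
            hap[i, which] = gam
    return hap


def simulate_genotypes(ped: Pedigree, cfg: SimConfig,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[GenotypeData, np.ndarray]:
    """Genotypes for the genotyped subset; full dosage matrix kept internally.

    Returns (GenotypeData for the genotyped animals, dosages for *all*
    pedigree animals).  The genotyped subset is the youngest
    ceil(prop_genotyped × N) animals (latest pedigree positions first),
    emulating genomic selection programs where recent cohorts are chipped.
    """
    cfg.validate()
    rng = _rng(cfg) if rng is None else rng
    hap = _drop_genes(ped, cfg, rng)
    dosages_all = hap.sum(axis=1).astype(np.int8)
    markers = _marker_map(cfg)

    n_geno = math.ceil(cfg.prop_genotyped * ped.n)
    geno_idx = np.arange(ped.n)[::-1][:n_geno][::-1]  # youngest n_geno, kept in order
    gd = GenotypeData(
        dosages=dosages_all[geno_idx].astype(np.float64),
        markers=markers,
        animal_ids=list(ped.ids[geno_idx]),
    )
    return gd, dosages_all


def simulate_phenotypes(ped: Pedigree, dosages_all: np.ndarray, cfg: SimConfig,
                        sex: np.ndarray, rng: np.random.Generator | None = None,
                        ) -> tuple[pd.DataFrame, TrueValues]:
    """Phenotypes under y = HYS + sex + a + e with known components.

    Breeding values: QTL part (dosage × effect, rescaled so its founder
    variance is qtl_variance_share × σ²ₐ) plus a polygenic part built by
    parent average + Mendelian sampling with variance
    ½σ²ₚₒₗy(1 − (F_s + F_d)/2); founders ~ N(0, σ²ₚₒₗy).
    """
    cfg.validate()
    rng = _rng(cfg) if rng is None else rng
    n = ped.n
    m_total = dosages_all.shape[1] if dosages_all.ndim == 2 else 0
    if cfg.n_qtl > m_total:
        raise SimulationError(f"n_qtl={cfg.n_qtl} exceeds marker count {m_total}")

    F = inbreeding(ped)

    # --- QTL component
    share = cfg.qtl_variance_share if cfg.n_qtl > 0 else 0.0
    qtl_pos = np.array([], dtype=np.int64)
    qtl_eff = np.array([])
    a_qtl = np.zeros(n)
    if cfg.n_qtl > 0 and cfg.sigma_a2 > 0:
        qtl_pos = np.sort(rng.choice(m_total, size=cfg.n_qtl, replace=False))
        raw_eff = rng.normal(size=cfg.n_qtl)
        founders = ped.is_founder()
        vals = dosages_all[founders][:, qtl_pos].astype(float) @ raw_eff
        v = np.var(vals)
        if v <= 0:
            raise SimulationError("QTL variance degenerate (monomorphic founders)")
        qtl_eff = raw_eff * math.sqrt(share * cfg.sigma_a2 / v)
        a_qtl = dosages_all[:, qtl_pos].astype(float) @ qtl_eff

    # --- polygenic component: parent average + Mendelian sampling
    sigma_poly = (1.0 - share) * cfg.sigma_a2
    a_poly = np.zeros(n)
    if sigma_poly > 0:
        ms = rng.normal(size=n)
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0 and d < 0:
                a_poly[i] = ms[i] * math.sqrt(sigma_poly)
            else:
                pa = 0.0
                if s >= 0:
                    pa += 0.5 * a_poly[s]
                if d >= 0:
                    pa += 0.5 * a_poly[d]
                fs = F[s] if s >= 0 else 0.0
                fd = F[d] if d >= 0 else 0.0
                if s >= 0 and d >= 0:
                    v = 0.5 * sigma_poly * (1.0 - 0.5 * (fs + fd))
                else:
                    v = 0.75 * sigma_poly  # one unknown base parent
                a_poly[i] = pa + ms[i] * math.sqrt(v)

    bv = a_qtl - a_qtl.mean() + a_poly if cfg.n_qtl > 0 else a_poly

    # --- fixed effects and residual
    hys_sd = cfg.hys_sd
    if hys_sd is None:
        hys_sd = 0.5 * math.sqrt(cfg.sigma_a2 + cfg.sigma_e2)
    hys_effects = rng.normal(0.0, hys_sd, size=cfg.n_hys_levels)
    hys = rng.integers(cfg.n_hys_levels, size=n)
    e = rng.normal(0.0, math.sqrt(cfg.sigma_e2), size=n)
    is_male = (sex == "M").astype(float)
    y = hys_effects[hys] + cfg.sex_effect * is_male + bv + e

    phen = pd.DataFrame({
        "id": ped.ids,
        "hys": [f"hys{h + 1}" for h in hys],
        "sex": sex,
        "trait": y,
    })
    denom = np.var(bv) + np.var(e)
    truth = TrueValues(
        breeding_values=bv,
        qtl_positions=qtl_pos,
        qtl_effects=qtl_eff,
        realized_h2=float(np.var(bv) / denom) if denom > 0 else 0.0,
        sex=sex,
    )
    return phen, truth


def simulate_dataset(cfg: SimConfig):
    """One-call convenience: pedigree, genotypes, phenotypes, truth.

    All randomness flows from a single generator seeded with ``cfg.seed``.
    """
    rng = _rng(cfg)
    ped, sex, gen = simulate_pedigree(cfg, rng)
    geno, dosages_all = simulate_genotypes(ped, cfg, rng)
    phen, truth = simulate_phenotypes(ped, dosages_all, cfg, sex, rng)
    truth.generation = gen
    return ped, geno, phen, truth


def write_dataset(ped: Pedigree, geno: GenotypeData, phen: pd.DataFrame,
                  truth: TrueValues, out_dir, overwrite: bool = False) -> dict:
    """Write pedigree.csv, phenotypes.csv, PLINK .ped/.map and truth.tsv.

    Refuses to overwrite an existing dataset unless ``overwrite=True``.
    Round-trips losslessly through the package readers.
    """
    from .genotypes import write_plink_text

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.csv",
        "phenotypes": out / "phenotypes.csv",
        "plink_ped": out / "genotypes.ped",
        "plink_map": out / "genotypes.map",
        "truth": out / "truth.tsv",
    }
    if not overwrite:
        clash = [str(p) for p in paths.values() if p.exists()]
        if clash:
            raise FileExistsError(f"refusing to overwrite {clash[0]} (pass overwrite=True)")

    sire_ids = np.where(ped.sire >= 0, ped.ids[np.clip(ped.sire, 0, None)], 0)
    dam_ids = np.where(ped.dam >= 0, ped.ids[np.clip(ped.dam, 0, None)], 0)
    pd.DataFrame({"id": ped.ids, "sire": sire_ids, "dam": dam_ids}).to_csv(
        paths["pedigree"], index=False)
    phen.to_csv(paths["phenotypes"], index=False)
    write_plink_text(geno, paths["plink_ped"], paths["plink_map"])
    tr = pd.DataFrame({"id": ped.ids, "true_bv": truth.breeding_values})
    tr.to_csv(paths["truth"], sep="\t", index=False)
    manifest = {k: str(v) for k, v in paths.items()}
    manifest["realized_h2"] = truth.realized_h2
    manifest["qtl_positions"] = truth.qtl_positions.tolist()
    manifest["qtl_effects"] = truth.qtl_effects.tolist()
    return manifest
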