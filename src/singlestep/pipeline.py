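"""End-to-end orchestration: QC → REML (PBLUP & ssGBLUP) → GEBV → GWAS →
thresholds → LD on the top region → annotation/enrichment.

Each stage writes its tables into a run directory with the governing
parameters recorded in a header comment and in ``run_log.json``; the slow
REML stage is cached by a content hash of its inputs and parameters, so
re-running with only downstream settings changed reuses the fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import genotypes as gt
from . import gwas as gw
from . import ld as ldmod
from . import mixed_model as mm
from . import pedigree as pedmod

log = logging.getLogger("singlestep")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    pedigree: str
    phenotypes: str
    genotypes_ped: str | None = None
    genotypes_map: str | None = None
    genes: str | None = None
    terms: str | None = None
    trait: str = "trait"
    fixed: tuple = ("hys", "sex")
    qc_call_rate: float = 0.90
    qc_maf: float = 0.01
    qc_hwe_p: float = 1e-6
    blend_w: float = 0.95
    tune: bool = True
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    ld_dprime_threshold: float = 0.8
    ld_top_n: int = 10
    seed: int = 0
    render_png: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for p in (cfg.pedigree, cfg.phenotypes, cfg.genotypes_ped,
                  cfg.genotypes_map, cfg.genes, cfg.terms):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"configured path does not exist: {p}")
        return cfg


def _param_hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, Path)) and Path(str(p)).is_file():
            h.update(Path(p).read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, params: dict) -> None:
    header = "# " + json.dumps(params, sort_keys=True, default=str) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Run the full analysis; returns the run directory.

    Deterministic given config; on stage failure partial outputs are kept
    and a PipelineError names the failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = {"config": asdict(cfg)}
    stage = "load"
    try:
        ped = pedmod.read_pedigree_csv(cfg.pedigree)
        phen = pd.read_csv(cfg.phenotypes)
        phen["id"] = [int(v) if str(v).isdigit() else v for v in phen["id"]]
        have_geno = cfg.genotypes_ped is not None and cfg.genotypes_map is not None
        geno = gt.read_plink_text(cfg.genotypes_ped, cfg.genotypes_map) \
            if have_geno else None
        if geno is not None and geno.n_animals == 0:
            have_geno, geno = False, None

        # ---------------- QC
        stage = "qc"
        if have_geno:
            geno, qc_report = gt.qc_filter(geno, cfg.qc_call_rate, cfg.qc_maf,
                                           cfg.qc_hwe_p)
            _write_table(qc_report.to_frame(), out / "qc_report.tsv",
                         qc_report.thresholds)
            run_log["qc"] = qc_report.to_frame().iloc[0].to_dict()
            log.info("QC: %d → %d SNPs", qc_report.n_snps_before,
                     qc_report.n_snps_after)
        else:
            log.info("no genotypes supplied: PBLUP only, GWAS stages skipped")
            run_log["qc"] = "skipped (no genotypes)"

        # ---------------- relationship matrices
        stage = "kinship"
        F = pedmod.inbreeding(ped)
        A_inv = pedmod.a_inverse(ped, F)
        dm = mm.build_design(phen, ped, trait=cfg.trait, fixed=tuple(cfg.fixed))

        H_inv = None
        g_star_inv = None
        W = scale = geno_idx = None
        if have_geno:
            A22, A22_inv = pedmod.a22(ped, geno.animal_ids)
            dos = gt.impute_mean(geno)
            p = dos.mean(axis=0) / 2.0
            gmat = gt.vanraden_g(dos, p)
            G_star, tune_params = gt.blend_tune_g(gmat.G, A22, cfg.blend_w,
                                                  cfg.tune)
            g_star_inv = gt.inverse_spd(G_star)
            geno_idx = ped.indices_of(geno.animal_ids)
            H_inv = mm.h_inverse(A_inv, A22_inv, g_star_inv, geno_idx)
            W = gt.center_dosages(dos, p)
            scale = gmat.scale
            run_log["g_matrix"] = {"scale": scale, **tune_params}

        # ---------------- REML, both methods (cached)
        stage = "reml"
        methods = {"PBLUP": A_inv}
        if have_geno:
            methods["ssGBLUP"] = H_inv
        reml_rows = []
        vcs = {}
        cache_dir = out / "cache"
        cache_dir.mkdir(exist_ok=True)
        for method, K_inv in methods.items():
            key = _param_hash(cfg.pedigree, cfg.phenotypes, cfg.trait,
                              list(cfg.fixed), cfg.reml_tol, cfg.reml_max_iter,
                              method, cfg.blend_w, cfg.tune,
                              cfg.qc_call_rate, cfg.qc_maf, cfg.qc_hwe_p)
            cache_file = cache_dir / f"reml_{method}_{key}.json"
            if cache_file.exists():
                d = json.loads(cache_file.read_text())
                vc = mm.VarianceComponents(**d)
                log.info("REML %s: cache hit (%s)", method, key)
            else:
                vc = mm.ai_reml(dm, K_inv, tol=cfg.reml_tol,
                                max_iter=cfg.reml_max_iter)
                cache_file.write_text(json.dumps({
                    "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2,
                    "h2": vc.h2, "se_h2": vc.se_h2, "converged": vc.converged,
                    "n_iterations": vc.n_iterations}))
            vcs[method] = vc
            reml_rows.append({
                "trait": cfg.trait, "method": method,
                "sigma_a2": round(vc.sigma_a2, 2),
                "sigma_e2": round(vc.sigma_e2, 2),
                "sigma_p2": round(vc.sigma_p2, 2),
                "h2": round(vc.h2, 2), "se_h2": round(vc.se_h2, 2),
                "converged": vc.converged,
            })
        vc_table = pd.DataFrame(reml_rows)
        _write_table(vc_table, out / "variance_components.tsv",
                     {"tol": cfg.reml_tol, "max_iter": cfg.reml_max_iter})

        # ---------------- GEBVs + GWAS
        if have_geno:
            stage = "gebv"
            vc = vcs["ssGBLUP"]
            sol = mm.solve_mme(dm, H_inv, vc.sigma_a2, vc.sigma_e2,
                               return_inverse=True)
            gebv = pd.DataFrame({"id": ped.ids, "gebv": sol.a_hat})
            _write_table(gebv, out / "gebv.tsv",
                         {"sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2})

            stage = "gwas"
            th = gw.thresholds(geno.n_snps)
            a_g = sol.a_hat[geno_idx]
            u = gw.backsolve_snp_effects(W, g_star_inv, a_g, scale)
            G_star = np.linalg.inv(g_star_inv)
            caa_g = sol.caa(geno_idx)
            var_ahat = vc.sigma_a2 * G_star - vc.sigma_e2 * caa_g
            var_u = gw.snp_sampling_variances(W, g_star_inv, scale, var_ahat)
            tab = gw.snp_effect_table(geno.markers, u, var_u, th)
            _write_table(tab, out / "snp_effects.tsv",
                         {"bonferroni": th.bonferroni, "suggestive": th.suggestive})
            counts = gw.classify_and_count(tab["p_value"], th,
                                           chrom=tab["chrom"].to_numpy())
            run_log["gwas_counts"] = counts
            man = gw.manhattan_table(tab, th)
            _write_table(man, out / "manhattan.tsv",
                         {"guide_bonferroni": man.attrs["guide_bonferroni"],
                          "guide_suggestive": man.attrs["guide_suggestive"]})
            if cfg.render_png:
                gw.manhattan_plot(man, th, out / "manhattan.png")

            # ---------------- LD around the strongest region
            stage = "ld"
            top = tab.sort_values("p_value").iloc[0]
            chrom_tab = tab[tab["chrom"] == top["chrom"]]
            near = chrom_tab.iloc[
                (chrom_tab["bp"] - top["bp"]).abs().argsort()[:cfg.ld_top_n]]
            ids = list(near.sort_values("bp")["snp_id"])
            if len(ids) >= 2:
                report = ldmod.region_report(geno, ids,
                                             cfg.ld_dprime_threshold)
                ldmod.ld_heatmap(report, out / "ld_dprime.tsv",
                                 out / "ld_heatmap.png" if cfg.render_png else None)
                run_log["ld"] = {"chrom": str(top["chrom"]),
                                 "runs": report.runs,
                                 "spans_bp": report.spans_bp}

            # ---------------- annotation / enrichment
            if cfg.genes is not None:
                stage = "annotate"
                genes = ann.read_gene_table(cfg.genes)
                sig = tab[tab["class"] != "ns"]
                annots = ann.annotate_snps(sig, genes)
                atab = ann.annotation_table(annots)
                atab = atab.merge(sig[["snp_id", "p_value", "class"]], on="snp_id")
                _write_table(atab, out / "annotation.tsv",
                             {"n_significant": int(len(sig))})
                if cfg.terms is not None:
                    stage = "enrich"
                    terms = ann.read_term_map(cfg.terms)
                    hit_genes = sorted({g for a in annots for g in a.genes})
                    universe = sorted(set(genes["gene_id"]))
                    if hit_genes:
                        etab = ann.hypergeom_enrichment(hit_genes, terms, universe)
                        _write_table(etab, out / "enrichment.tsv",
                                     {"universe_size": len(universe),
                                      "list_size": len(hit_genes)})
                        run_log["enrichment_significant"] = int(etab["enriched"].sum())

        (out / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                     default=str))
        return out
    except Exception as exc:
        (out / "run_log.json").write_text(json.dumps(
            {**run_log, "failed_stage": stage, "error": str(exc)}, indent=2,
            default=str))
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
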