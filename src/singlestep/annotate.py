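"""SNP-to-gene annotation and hypergeometric term enrichment.

Significant markers are mapped onto a gene coordinate table: a SNP inside
a gene is *genic*; otherwise the nearest gene on each side is reported
with the unsigned distance (bp) to its closer boundary, matching the
common candidate-gene reporting convention.  The gene list so obtained can
be tested for over-representation of functional terms (GO, KEGG, or any
user-supplied gene→term map) with a one-sided hypergeometric test against
an explicit background universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gene table I/O

def read_gene_table(path) -> pd.DataFrame:
    """Read gene coordinates from GFF3 (``gene`` features) or BED.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand
    using 1-based inclusive coordinates (BED's 0-based half-open intervals
    are converted).  Format is sniffed from the extension and content.
    Malformed lines raise with their line number.
    """
    path = str(path)
    with open(path) as fh:
        lines = fh.readlines()
    is_gff = path.endswith((".gff", ".gff3")) or any(
        ln.startswith("##gff-version") for ln in lines[:5])
    rows = []
    for ln_no, ln in enumerate(lines, start=1):
        ln = ln.rstrip("\n")
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if is_gff:
            if len(parts) < 9:
                raise AnnotationError(f"{path}: malformed GFF3 line {ln_no}")
            if parts[2].lower() != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise AnnotationError(f"{path}: bad coordinates at line {ln_no}") from exc
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            gid = attrs.get("Name") or attrs.get("ID") or f"gene_line{ln_no}"
            gid = gid.removeprefix("gene:")
            rows.append((gid, parts[0], start, end, parts[6]))
        else:
            if len(parts) < 3:
                raise AnnotationError(f"{path}: malformed BED line {ln_no}")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}: bad coordinates at line {ln_no}") from exc
            gid = parts[3] if len(parts) > 3 else f"gene_line{ln_no}"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((gid, parts[0], start0 + 1, end0, strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if genes.empty:
        raise AnnotationError(f"{path}: no gene records found")
    if (genes["start"] > genes["end"]).any():
        bad = genes[genes["start"] > genes["end"]].iloc[0]
        raise AnnotationError(f"gene {bad.gene_id}: start > end")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise AnnotationError(f"duplicate gene id {dup!r}")
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SNP annotation

@dataclass
class SnpAnnotation:
    snp_id: str
    chrom: str
    bp: int
    status: str                       # genic | intergenic | unannotated
    genes: list = field(default_factory=list)       # gene ids
    distances: list = field(default_factory=list)   # bp, 0 when genic

    def describe(self) -> str:
        if self.status == "genic":
            return ", ".join(self.genes)
        if self.status == "unannotated":
            return "unannotated"
        return ", ".join(f"{g} ({d})" for g, d in zip(self.genes, self.distances))


def annotate_snps(snps: pd.DataFrame, genes: pd.DataFrame) -> list[SnpAnnotation]:
    """Annotate SNP positions (columns snp_id, chrom, bp; 1-based) with genes.

    Overlap (start ≤ bp ≤ end) → genic, all overlapping genes listed.
    Otherwise the nearest gene on each side is reported with distance to
    its closer boundary; both flanks tie → both reported at equal
    distance; a chromosome absent from the gene table → unannotated.
    """
    out = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    for _, row in snps.iterrows():
        snp_id, chrom, bp = str(row["snp_id"]), str(row["chrom"]), int(row["bp"])
        g = by_chrom.get(chrom)
        if g is None:
            out.append(SnpAnnotation(snp_id, chrom, bp, "unannotated"))
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        inside = (starts <= bp) & (bp <= ends)
        if inside.any():
            out.append(SnpAnnotation(snp_id, chrom, bp, "genic",
                                     genes=list(g.loc[inside, "gene_id"]),
                                     distances=[0] * int(inside.sum())))
            continue
        left = ends < bp
        right = starts > bp
        cand = []
        if left.any():
            i = int(np.argmax(np.where(left, ends, -np.inf)))
            cand.append((str(g["gene_id"][i]), int(bp - ends[i])))
        if right.any():
            i = int(np.argmin(np.where(right, starts, np.inf)))
            cand.append((str(g["gene_id"][i]), int(starts[i] - bp)))
        if not cand:
            out.append(SnpAnnotation(snp_id, chrom, bp, "unannotated"))
            continue
        out.append(SnpAnnotation(snp_id, chrom, bp, "intergenic",
                                 genes=[gid for gid, _ in cand],
                                 distances=[d for _, d in cand]))
    return out


def annotation_table(annots: list[SnpAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "snp_id": a.snp_id, "chrom": a.chrom, "bp": a.bp, "status": a.status,
        "gene_annotation": a.describe(),
    } for a in annots])


# ---------------------------------------------------------------------------
# enrichment

def read_term_map(path) -> pd.DataFrame:
    """TSV with columns term_id, term_name, gene_id (one gene per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"term_id", "term_name", "gene_id"}
    if not need.issubset(df.columns):
        raise AnnotationError(f"term map must have columns {sorted(need)}")
    return df


def hypergeom_enrichment(gene_list, term_map: pd.DataFrame, universe,
                         alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    With universe size N, term size K, list size n and overlap k, the
    p-value is P(X ≥ k) for X ~ Hypergeometric(N, K, n).  Rows are sorted
    by p; ``enriched`` flags raw p < alpha (no multiplicity adjustment, as
    customary for small candidate-gene lists); a Benjamini–Hochberg column
    is provided alongside.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not universe:
        raise AnnotationError("empty universe")
    if not gene_list:
        raise AnnotationError("empty gene list")
    if not gene_list <= universe:
        raise AnnotationError(
            f"gene list not contained in universe: {sorted(gene_list - universe)[:5]}")
    N, n = len(universe), len(gene_list)
    rows = []
    for (tid, tname), grp in term_map.groupby(["term_id", "term_name"], sort=False):
        term_genes = set(grp["gene_id"]) & universe
        K = len(term_genes)
        if K == 0:
            continue
        hit = sorted(gene_list & term_genes)
        k = len(hit)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))   # P(X >= k)
        rows.append((tid, tname, k, K, p, ",".join(hit)))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "count",
                                      "term_size", "p_value", "genes"])
    out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    out["enriched"] = out["p_value"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        prev = min(prev, val)
        adj[i] = prev
    return np.clip(adj, 0, 1)
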