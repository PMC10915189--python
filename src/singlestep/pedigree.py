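"""Pedigree handling and pedigree-based relationship matrices.

Implements the numerator relationship matrix A (tabular method), per-animal
inbreeding coefficients F (Meuwissen & Luo recursion), the sparse inverse
A⁻¹ (Henderson's rules with inbreeding), and the genotyped-animal block
A₂₂ with its inverse. The pedigree is kept topologically sorted (parents
before offspring); unknown parents are treated as draws from an unrelated,
non-inbred base population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

UNKNOWN = 0
#: sentinel parent code: ids are positive integers, 0 = unknown

DENSE_GUARD = 20_000


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    ``sire`` / ``dam`` hold 0-based positional indices into the sorted
    order, or -1 for an unknown parent.  ``ids`` are the original animal
    identifiers in sorted order.
    """

    ids: np.ndarray          # shape (N,), original identifiers
    sire: np.ndarray         # shape (N,), int index or -1
    dam: np.ndarray          # shape (N,), int index or -1
    id_index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.id_index:
            self.id_index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def indices_of(self, ids) -> np.ndarray:
        try:
            return np.array([self.id_index[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"id {exc.args[0]!r} not in pedigree") from exc


def sort_pedigree(records) -> Pedigree:
    """Topologically sort raw (id, sire, dam) records.

    Unknown parents may be 0, "", "0", None or NaN.  Raises on duplicate
    ids, on a parent id absent from the records, and on cycles (naming one
    involved id).
    """
    raw = [(_norm_id(a), _norm_parent(s), _norm_parent(d)) for a, s, d in records]
    ids = [a for a, _, _ in raw]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for a in ids:
            if a in seen:
                dup = a
                break
            seen.add(a)
        raise PedigreeError(f"duplicate animal id {dup!r}")
    known = set(ids)
    parents = {}
    for a, s, d in raw:
        for p in (s, d):
            if p is not None and p not in known:
                raise PedigreeError(f"parent id {p!r} of animal {a!r} not in pedigree")
        parents[a] = (s, d)

    # Kahn's algorithm on parent -> offspring edges
    n_unmet = {a: sum(p is not None for p in ps) for a, ps in parents.items()}
    children: dict = {a: [] for a in ids}
    for a, (s, d) in parents.items():
        for p in {s, d} - {None}:
            children[p].append(a)
    order = [a for a in ids if n_unmet[a] == 0]
    head = 0
    while head < len(order):
        for c in children[order[head]]:
            n_unmet[c] -= 1
            if n_unmet[c] == 0:
                order.append(c)
        head += 1
    if len(order) < len(ids):
        stuck = next(a for a in ids if n_unmet[a] > 0)
        raise PedigreeError(f"pedigree cycle involving id {stuck!r}")

    idx = {a: i for i, a in enumerate(order)}
    sire = np.array([-1 if parents[a][0] is None else idx[parents[a][0]] for a in order],
                    dtype=np.int64)
    dam = np.array([-1 if parents[a][1] is None else idx[parents[a][1]] for a in order],
                   dtype=np.int64)
    return Pedigree(ids=np.asarray(order, dtype=object), sire=sire, dam=dam, id_index=idx)


def _norm_id(a):
    if a is None or (isinstance(a, float) and np.isnan(a)):
        raise PedigreeError("animal id missing")
    return int(a) if not isinstance(a, str) else a


def _norm_parent(p):
    if p is None or p == "" or (isinstance(p, float) and np.isnan(p)):
        return None
    if isinstance(p, str):
        if p.strip() in ("0", "", "NA", "na", "."):
            return None
        return p
    p = int(p)
    return None if p == UNKNOWN else p


def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree CSV with columns id, sire, dam (0/empty/NA = unknown)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    for need in ("id", "sire", "dam"):
        if need not in cols:
            raise PedigreeError(f"pedigree file missing column {need!r}")
    df.columns = cols
    recs = list(zip(df["id"], df["sire"], df["dam"]))
    # coerce numeric-looking ids to int for convenience
    def coerce(v):
        try:
            return int(v)
        except (TypeError, ValueError):
            return v
    recs = [(coerce(a), coerce(s) if s not in ("", "NA") else 0,
             coerce(d) if d not in ("", "NA") else 0) for a, s, d in recs]
    return sort_pedigree(recs)


# ---------------------------------------------------------------------------
# inbreeding (Meuwissen & Luo 1992 recursion)

def mendelian_sampling_variance(F_sire: float, F_dam: float,
                                has_sire: bool, has_dam: bool) -> float:
    """Within-family (Mendelian sampling) variance d_i given parental F.

    ½ − ¼(F_s + F_d) with both parents, ¾ − ¼F_p with one, 1 with none
    (unknown parents are unrelated, non-inbred base animals).
    """
    if has_sire and has_dam:
        return 0.5 - 0.25 * (F_sire + F_dam)
    if has_sire or has_dam:
        return 0.75 - 0.25 * (F_sire if has_sire else F_dam)
    return 1.0


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (Meuwissen & Luo recursion).

    For each animal the ancestor list is climbed once, accumulating
    coefficients c_j (each ancestor passes half its coefficient to each
    known parent); the identity a(i,i) = Σ_j c_j² d_j over i and its
    ancestors yields F_i = a(i,i) − 1 without materializing A.  Processing
    ancestors in descending pedigree order guarantees every c_j is complete
    before j is expanded.  O(N · ancestry size); exact.
    """
    import heapq

    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d_ms = np.ones(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        d_ms[i] = mendelian_sampling_variance(
            F[s] if s >= 0 else 0.0, F[d] if d >= 0 else 0.0, s >= 0, d >= 0)
        if s < 0 or d < 0:
            # F = 0 when any parent is a base-population unknown
            continue
        coeff = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            cj = coeff.pop(j)
            a_ii += cj * cj * d_ms[j]
            for pj in (sire[j], dam[j]):
                if pj >= 0:
                    if pj in coeff:
                        coeff[pj] += 0.5 * cj
                    else:
                        coeff[pj] = 0.5 * cj
                        heapq.heappush(heap, -pj)
        F[i] = a_ii - 1.0
        # d of i used a pre-update view of F[i]=0 only via parents, unaffected
    return F


def a_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    a(i,i) = 1 + F_i; a(i,j) = ½(a(j,s_i) + a(j,d_i)); unknown parents
    contribute zero.  Guarded at N ≤ 20,000.
    """
    n = ped.n
    if n > DENSE_GUARD:
        raise PedigreeError(
            f"pedigree has {n} animals; dense A is guarded at {DENSE_GUARD} — "
            "use a_inverse / a22 on a pruned pedigree instead")
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            row = 0.5 * (A[s, :i] + A[d, :i])
            aii = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            row = 0.5 * A[p, :i]
            aii = 1.0
        else:
            row = np.zeros(i)
            aii = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return A


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A⁻¹ via Henderson's rules with inbreeding.

    For each animal i with Mendelian-sampling variance
    d_i = ½ − ¼(F_s + F_d) (¾ − ¼F_p with one parent, 1 with none),
    add d_i⁻¹ · k kᵀ over the (i, sire, dam) entries with k = (1, −½, −½).
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        inv_d = 1.0 / di
        members = [(i, 1.0)] + [(p, -0.5) for p in (s, d) if p >= 0]
        for a, ka in members:
            for b, kb in members:
                rows.append(a)
                cols.append(b)
                vals.append(inv_d * ka * kb)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def prune_to_ancestors(ped: Pedigree, keep_ids) -> tuple[Pedigree, np.ndarray]:
    """Restrict the pedigree to ``keep_ids`` and all their ancestors.

    Returns the pruned pedigree and the positions of ``keep_ids`` within it.
    """
    keep_idx = ped.indices_of(keep_ids)
    needed = np.zeros(ped.n, dtype=bool)
    needed[keep_idx] = True
    for i in range(ped.n - 1, -1, -1):
        if needed[i]:
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0:
                    needed[p] = True
    old_new = -np.ones(ped.n, dtype=np.int64)
    old_new[needed] = np.arange(int(needed.sum()))
    sire = np.where(ped.sire[needed] >= 0, old_new[np.clip(ped.sire[needed], 0, None)], -1)
    dam = np.where(ped.dam[needed] >= 0, old_new[np.clip(ped.dam[needed], 0, None)], -1)
    sub = Pedigree(ids=ped.ids[needed], sire=sire, dam=dam)
    return sub, old_new[keep_idx]


def a22(ped: Pedigree, genotyped_ids) -> tuple[np.ndarray, np.ndarray]:
    """A₂₂ (genotyped block of A) and its inverse.

    Computed exactly by tabular evaluation on the pedigree pruned to the
    genotyped animals' ancestors, then sliced; the inverse uses a symmetric
    (Cholesky) factorization.
    """
    sub, pos = prune_to_ancestors(ped, genotyped_ids)
    A22 = a_matrix(sub)[np.ix_(pos, pos)]
    try:
        cf = scipy.linalg.cho_factor(A22)
        A22_inv = scipy.linalg.cho_solve(cf, np.eye(A22.shape[0]))
    except scipy.linalg.LinAlgError as exc:
        raise PedigreeError(
            "A22 is singular (e.g. duplicated identical animals); "
            "consider a small diagonal jitter") from exc
    return A22, A22_inv


def write_sparse_tsv(mat: sp.spmatrix, path) -> None:
    """Export a sparse symmetric matrix as 1-based coordinate TSV (i, j, value)."""
    coo = mat.tocoo()
    df = pd.DataFrame({"i": coo.row + 1, "j": coo.col + 1, "value": coo.data})
    df.to_csv(path, sep="\t", index=False)
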