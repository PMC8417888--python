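"""Pedigree relationship machinery.

Numerator relationship matrix A, its sparse inverse (Henderson rules with
inbreeding), the genotyped submatrix A22, the QP-transformed inverse A* with
unknown-parent groups, and the metafounder-modified relationship matrix
A(Gamma) together with its inverse and genotyped submatrix.

Conventions
-----------
Animals are stored 0-based in topological order (parents precede offspring);
an unknown parent is encoded as -1 in memory and 0 in files.  Unknown-parent
groups and metafounders occupy extra columns appended *after* the animal
columns, so every relationship-inverse variant shares the layout
``[animals 0..n) | groups/metafounders n..n+g)``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

UNKNOWN = -1

#: dense constructions (A, A22 closure, A(Gamma)) refuse beyond this size
DEFAULT_DENSE_LIMIT = 5000


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    sire, dam
        Integer arrays of parent indices, ``-1`` for unknown.
    breed_comp
        Optional ``(n, 4)`` array of breed fractions (NABC order), rows
        summing to 1 where known, NaN rows where unknown.
    sex
        Optional array, 1 = male, 2 = female, 0 = unknown.
    birth_gen
        Optional integer birth period (used for validation cohorts).
    pool
        Optional per-animal label of the mating-plan pool that produced it.
    """

    sire: np.ndarray
    dam: np.ndarray
    breed_comp: np.ndarray | None = None
    sex: np.ndarray | None = None
    birth_gen: np.ndarray | None = None
    pool: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.sire.shape != self.dam.shape:
            raise PedigreeError("sire/dam length mismatch")
        idx = np.arange(self.n)
        if np.any(self.sire >= idx) or np.any(self.dam >= idx):
            raise PedigreeError("pedigree is not topologically ordered "
                                "(a parent does not precede its offspring)")
        if self.breed_comp is not None:
            self.breed_comp = np.asarray(self.breed_comp, dtype=float)
            ok = ~np.isnan(self.breed_comp).any(axis=1)
            sums = self.breed_comp[ok].sum(axis=1)
            if ok.any() and not np.allclose(sums, 1.0, atol=1e-6):
                raise PedigreeError("breed fractions must sum to 1")

    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def subset_closure(self, ids: np.ndarray) -> tuple[np.ndarray, "Pedigree"]:
        """Ancestor closure of ``ids`` as a re-indexed sub-pedigree.

        Returns the sorted original indices of the closure and the
        sub-pedigree restricted to them (topological order preserved).
        """
        keep = np.zeros(self.n, dtype=bool)
        keep[np.asarray(ids, dtype=np.int64)] = True
        for i in range(self.n - 1, -1, -1):
            if keep[i]:
                if self.sire[i] != UNKNOWN:
                    keep[self.sire[i]] = True
                if self.dam[i] != UNKNOWN:
                    keep[self.dam[i]] = True
        orig = np.flatnonzero(keep)
        remap = np.full(self.n, UNKNOWN, dtype=np.int64)
        remap[orig] = np.arange(orig.size)
        def _re(par):
            out = par[orig].copy()
            known = out != UNKNOWN
            out[known] = remap[out[known]]
            return out
        sub = Pedigree(
            _re(self.sire), _re(self.dam),
            breed_comp=None if self.breed_comp is None else self.breed_comp[orig],
            sex=None if self.sex is None else self.sex[orig],
            birth_gen=None if self.birth_gen is None else self.birth_gen[orig],
            pool=None if self.pool is None else self.pool[orig],
        )
        return orig, sub


@dataclass
class GammaMatrix:
    """Symmetric relationship matrix among metafounders."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("gamma must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("gamma must be symmetric")
        if not self.labels:
            self.labels = [f"MF{i + 1}" for i in range(self.k)]

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def inverse(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.values)
        except np.linalg.LinAlgError as e:
            raise ValueError("gamma matrix is singular") from e


@dataclass
class GroupIncidence:
    """Expected group (UPG/metafounder) contribution per animal."""

    values: np.ndarray      # (n, g)
    labels: list[str]


# ---------------------------------------------------------------------------
# inbreeding and Mendelian-sampling variances
# ---------------------------------------------------------------------------

def mendelian_variances(sire: np.ndarray, dam: np.ndarray,
                        F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance factors d_i.

    ``d_i = 1 - 0.25 (1 + F_s) - 0.25 (1 + F_d)`` with each term counted only
    for a known parent, i.e. 1, ``0.75 - 0.25 F_p`` or
    ``0.5 - 0.25 (F_s + F_d)``.
    """
    d = np.ones(sire.size)
    ks, kd = sire != UNKNOWN, dam != UNKNOWN
    d[ks] -= 0.25 * (1.0 + F[sire[ks]])
    d[kd] -= 0.25 * (1.0 + F[dam[kd]])
    return d


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients (Meuwissen & Luo recursion).

    F_i = 0.5 a(s_i, d_i); an unknown parent contributes 0.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    D = np.zeros(n)  # Mendelian variance of each animal, filled as we go
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s != UNKNOWN else -1.0
        Fd = F[d] if d != UNKNOWN else -1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
        if s == UNKNOWN or d == UNKNOWN:
            # a(s, d) = 0 whenever either parent is unknown
            F[i] = 0.0
            continue
        # trace a_ii = sum_j L_ij^2 D_j upward through the ancestors
        coeff: dict[int, float] = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lij = coeff.pop(j, 0.0)
            if lij == 0.0:
                continue
            aii += lij * lij * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * lij
        F[i] = aii - 1.0
    return F


# ---------------------------------------------------------------------------
# A and its inverse
# ---------------------------------------------------------------------------

def build_A(ped: Pedigree, dense_limit: int = DEFAULT_DENSE_LIMIT) -> np.ndarray:
    """Numerator relationship matrix by the tabular method (dense).

    a_ii = 1 + 0.5 a(s, d); a_ij = 0.5 (a(j, s) + a(j, d)); an unknown
    parent contributes 0.
    """
    n = ped.n
    if n > dense_limit:
        raise PedigreeError(
            f"pedigree of {n} animals exceeds the dense limit {dense_limit}; "
            "use build_A_inverse for the sparse path")
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Adds ``(1/d_i) w w'`` per animal with ``w = e_i - 0.5 e_s - 0.5 e_d``
    over known parents and d_i from :func:`mendelian_variances`.
    """
    if F is None:
        F = compute_inbreeding(ped)
    d = mendelian_variances(ped.sire, ped.dam, F)
    if np.any(d <= 0):
        raise PedigreeError("non-positive Mendelian variance: corrupt inbreeding")
    return _accumulate_ww(ped.sire, ped.dam, d, ped.n)


def _accumulate_ww(sire: np.ndarray, dam: np.ndarray, d: np.ndarray,
                   size: int, offset: int = 0) -> sp.csr_matrix:
    """Sum of (1/d_i) w w' contributions; parent index -1 is skipped.

    ``offset`` shifts the animal (row-owner) indices, letting the same
    accumulator serve extended (metafounder) pedigrees.
    """
    n = sire.size
    rows, cols, vals = [], [], []
    inv_d = 1.0 / d
    idx = np.arange(n) + offset
    rows.append(idx); cols.append(idx); vals.append(inv_d)
    for par in (sire, dam):
        k = par != UNKNOWN
        p = par[k]
        a = idx[k]
        rows.append(a); cols.append(p); vals.append(-0.5 * inv_d[k])
        rows.append(p); cols.append(a); vals.append(-0.5 * inv_d[k])
    ks, kd = sire != UNKNOWN, dam != UNKNOWN
    for m1, p1, m2, p2 in (
        (ks, sire, ks, sire), (kd, dam, kd, dam),
        (ks, sire, kd, dam), (kd, dam, ks, sire),
    ):
        m = m1 & m2
        rows.append(p1[m]); cols.append(p2[m]); vals.append(0.25 * inv_d[m])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    out = sp.coo_matrix((vals, (rows, cols)), shape=(size, size))
    return out.tocsr()


def build_A22(ped: Pedigree, genotyped: np.ndarray,
              dense_limit: int = DEFAULT_DENSE_LIMIT,
              return_inverse: bool = False):
    """Relationship submatrix among genotyped animals.

    Computed without forming the full A: the tabular method runs on the
    ancestor closure of the genotyped set only.
    """
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if genotyped.size and genotyped.max() >= ped.n:
        raise PedigreeError("genotyped id outside pedigree")
    orig, sub = ped.subset_closure(genotyped)
    A = build_A(sub, dense_limit=dense_limit)
    remap = {o: i for i, o in enumerate(orig)}
    pos = np.array([remap[g] for g in genotyped], dtype=np.int64)
    A22 = A[np.ix_(pos, pos)]
    if not return_inverse:
        return A22
    try:
        A22inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as e:
        raise PedigreeError("A22 is singular (duplicate animals?)") from e
    return A22, A22inv


# ---------------------------------------------------------------------------
# unknown-parent groups
# ---------------------------------------------------------------------------

def _check_assignment(ped: Pedigree, sire_group: np.ndarray,
                      dam_group: np.ndarray, n_groups: int) -> None:
    for par, grp, what in ((ped.sire, sire_group, "sire"),
                           (ped.dam, dam_group, "dam")):
        unknown = par == UNKNOWN
        if np.any(grp[unknown] < 0):
            raise PedigreeError(f"unknown {what} without a group code")
        if np.any(grp >= n_groups):
            raise PedigreeError("group code out of range")


def build_Q(ped: Pedigree, sire_group: np.ndarray, dam_group: np.ndarray,
            n_groups: int, labels: list[str] | None = None) -> GroupIncidence:
    """Group incidence Q: expected contribution of each group to each animal.

    Q_i = 0.5 Q_s + 0.5 Q_d where an unknown parent contributes half the
    unit vector of its group.
    """
    _check_assignment(ped, sire_group, dam_group, n_groups)
    n = ped.n
    Q = np.zeros((n, n_groups))
    for i in range(n):
        row = Q[i]
        for par, grp in ((ped.sire[i], sire_group[i]),
                         (ped.dam[i], dam_group[i])):
            if par == UNKNOWN:
                row[grp] += 0.5
            else:
                row += 0.5 * Q[par]
    if labels is None:
        labels = [f"G{j + 1}" for j in range(n_groups)]
    return GroupIncidence(Q, list(labels))


def build_QP_Astar(ped: Pedigree, sire_group: np.ndarray,
                   dam_group: np.ndarray, n_groups: int,
                   F: np.ndarray | None = None) -> sp.csr_matrix:
    """QP-transformed A* of size (n + g): Henderson accumulation where every
    unknown parent is replaced by its group column.

    Group columns act as parents with F = -1, so each d_i equals the plain
    unknown-parent value; group columns receive no diagonal seeding, which
    makes the animal block identical to A^-1 when no group is ever used.
    """
    _check_assignment(ped, sire_group, dam_group, n_groups)
    if F is None:
        F = compute_inbreeding(ped)
    d = mendelian_variances(ped.sire, ped.dam, F)
    n = ped.n
    # rewire unknown parents to group columns n..n+g
    s = ped.sire.copy()
    dm = ped.dam.copy()
    s[s == UNKNOWN] = n + sire_group[s == UNKNOWN]
    dm[dm == UNKNOWN] = n + dam_group[dm == UNKNOWN]
    return _accumulate_ww(s, dm, d, n + n_groups)


# ---------------------------------------------------------------------------
# metafounders
# ---------------------------------------------------------------------------

@dataclass
class MetafounderMatrices:
    """A(Gamma) products, animal-first ordering (metafounders last)."""

    A: np.ndarray               # (n+k, n+k) dense, animals then metafounders
    Ainv: sp.csr_matrix         # (n+k, n+k)
    F_gamma: np.ndarray         # per-animal inbreeding on the Gamma scale
    gamma: GammaMatrix

    @property
    def n_animals(self) -> int:
        return self.A.shape[0] - self.gamma.k

    def A22(self, genotyped: np.ndarray) -> np.ndarray:
        g = np.asarray(genotyped, dtype=np.int64)
        return self.A[np.ix_(g, g)]


def build_Agamma(ped: Pedigree, gamma: GammaMatrix,
                 sire_group: np.ndarray, dam_group: np.ndarray,
                 dense_limit: int = DEFAULT_DENSE_LIMIT,
                 include_prior: bool = True) -> MetafounderMatrices:
    """Metafounder-modified relationship matrix and its inverse.

    The k metafounders enter as pseudo-animals at the head of an extended
    pedigree, related by a(mf_j, mf_l) = gamma_jl (self-relationship
    gamma_jj, i.e. F = gamma_jj - 1); every unknown parent is replaced by
    its metafounder.  The tabular recursion then yields A(Gamma); the
    inverse is assembled from per-animal Mendelian variances
    ``d_i = a_ii - 0.25 (a_ss + 2 a_sd + a_dd)`` plus Gamma^-1 on the
    metafounder block.

    ``include_prior=False`` omits the Gamma^-1 term, which is the exact
    zero-Gamma limit in which metafounders behave as fixed unknown-parent
    groups (the QP-transformed A*).
    """
    k = gamma.k
    n = ped.n
    if n + k > dense_limit:
        raise PedigreeError(
            f"extended pedigree of {n + k} exceeds the dense limit {dense_limit}")
    _check_assignment(ped, sire_group, dam_group, k)
    # extended parents: metafounders occupy 0..k, animals k..k+n
    s = np.where(ped.sire == UNKNOWN, sire_group,
                 np.where(ped.sire >= 0, ped.sire + k, ped.sire))
    dm = np.where(ped.dam == UNKNOWN, dam_group,
                  np.where(ped.dam >= 0, ped.dam + k, ped.dam))
    N = n + k
    A = np.zeros((N, N))
    A[:k, :k] = gamma.values
    for i in range(n):
        ei = k + i
        row = 0.5 * (A[s[i], :ei] + A[dm[i], :ei])
        A[ei, :ei] = row
        A[:ei, ei] = row
        A[ei, ei] = 1.0 + 0.5 * A[s[i], dm[i]]
    diag = np.diag(A)
    d = (diag[k:] - 0.25 * (diag[s] + 2.0 * A[s, dm] + diag[dm]))
    if np.any(d <= 0):
        raise PedigreeError(
            "non-positive Mendelian sampling variance in the Gamma-extended "
            "pedigree (a metafounder self-relationship >= 2 leaves founders "
            "no variance); check the Gamma estimate")
    Ainv = _accumulate_ww(s, dm, d, N, offset=k).tolil()
    if include_prior:
        Ainv[:k, :k] += gamma.inverse()
    # permute to animals-first ordering
    perm = np.concatenate([np.arange(k, N), np.arange(k)])
    A = A[np.ix_(perm, perm)]
    Ainv = Ainv.tocsr()[perm][:, perm]
    F_gamma = np.diag(A)[:n] - 1.0
    return MetafounderMatrices(A=A, Ainv=Ainv.tocsr(), F_gamma=F_gamma,
                               gamma=gamma)
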