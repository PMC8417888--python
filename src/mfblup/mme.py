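"""Multi-trait mixed-model equations for seven evaluation variants.

Variants: ``BLUP``, ``BLUP_UPG``, ``BLUP_MF`` (pedigree-only) and
``ssGBLUP``, ``ssGBLUP_UPG``, ``ssGBLUP_UPGA``, ``ssGBLUP_MF``
(single-step genomic).  The model per trait is

    y = Xb + Z1 u + Z2 m + Z3 c + e

with b fixed (contemporary group, class factors, covariates), u direct
genetic, m maternal genetic (designated traits), c maternal permanent
environment and e residual; genetic effects share one relationship
structure K (A, the QP-transformed A* with unknown-parent groups, the
metafounder A(Gamma), or a single-step H built from these plus G/G05)
through the Kronecker penalty ``G0^-1 (x) K^-1``.

Unknown-parent groups enter through the QP transformation: group effects
become extra columns of the genetic-effect vector and the solved animal
effects are the *total* merits Qg + u.  Because rows of Q sum to one, the
QP system carries an exact confounding with the contemporary-group
intercepts; one reference group (the last used label) is therefore dropped
(its solution pinned to zero), which makes every system positive definite
and both solvers (sparse LU and preconditioned conjugate gradients)
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import (DEFAULT_DENSE_LIMIT, UNKNOWN, GammaMatrix,
                       GroupIncidence, MetafounderMatrices, Pedigree,
                       build_A22, build_Agamma, build_A_inverse, build_Q,
                       build_QP_Astar, compute_inbreeding)
from .groups import GroupAssignment

VARIANTS = ("BLUP", "BLUP_UPG", "BLUP_MF",
            "ssGBLUP", "ssGBLUP_UPG", "ssGBLUP_UPGA", "ssGBLUP_MF")


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# variance components and model specification
# ---------------------------------------------------------------------------

@dataclass
class VarComponents:
    """Genetic (G0), permanent-environment (P0) and residual (R0)
    covariance matrices.

    G0 is ordered direct effects for every trait, then maternal effects for
    the designated maternal traits.  P0 follows the maternal-trait order.
    """

    g0: np.ndarray
    p0: np.ndarray
    r0: np.ndarray
    trait_names: list[str]
    maternal_traits: list[str]

    def __post_init__(self) -> None:
        self.g0 = np.atleast_2d(np.asarray(self.g0, dtype=float))
        self.p0 = np.atleast_2d(np.asarray(self.p0, dtype=float))
        self.r0 = np.atleast_2d(np.asarray(self.r0, dtype=float))
        nd, nm = len(self.trait_names), len(self.maternal_traits)
        if self.g0.shape != (nd + nm, nd + nm):
            raise ModelError("G0 dimension does not match the effect list")
        if self.r0.shape != (nd, nd):
            raise ModelError("R0 dimension does not match the trait list")

    @property
    def n_effects(self) -> int:
        return self.g0.shape[0]

    @property
    def n_pe(self) -> int:
        return self.p0.shape[0] if self.p0.size else 0

    def direct_index(self, trait: str) -> int:
        return self.trait_names.index(trait)

    def maternal_index(self, trait: str) -> int:
        return len(self.trait_names) + self.maternal_traits.index(trait)

    def pe_index(self, trait: str) -> int:
        return self.maternal_traits.index(trait)

    def direct_variance(self, trait: str) -> float:
        i = self.direct_index(trait)
        return float(self.g0[i, i])

    def maternal_variance(self, trait: str) -> float:
        i = self.maternal_index(trait)
        return float(self.g0[i, i])

    def scaled(self, k: float) -> "VarComponents":
        """Additive components divided by the metafounder constant k."""
        return VarComponents(self.g0 / k, self.p0.copy(), self.r0.copy(),
                             list(self.trait_names),
                             list(self.maternal_traits))


@dataclass
class TraitModel:
    """Fixed-effect layout of one analysed trait."""

    name: str
    cg: str                              # contemporary-group factor column
    factors: list[str] = field(default_factory=list)   # ref-coded classes
    covariates: list[str] = field(default_factory=list)
    maternal: bool = False
    pe: bool = False


@dataclass
class ModelSpec:
    traits: list[TraitModel]
    varcomps: VarComponents
    variant: str = "BLUP"
    group_mode: str = "GG4"
    alpha: float = 0.95

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ModelError(f"unknown variant {self.variant!r}")
        names = [t.name for t in self.traits]
        if names != self.varcomps.trait_names:
            raise ModelError("trait order mismatch between spec and varcomps")

    @property
    def genomic(self) -> bool:
        return self.variant.startswith("ssGBLUP")

    @property
    def base(self) -> str:
        if self.variant.endswith("_MF"):
            return "MF"
        if self.variant.endswith("_UPGA"):
            return "UPGA"
        if self.variant.endswith("_UPG"):
            return "UPG"
        return "none"


# ---------------------------------------------------------------------------
# phenotype editing
# ---------------------------------------------------------------------------

def edit_phenotypes(phen: pd.DataFrame, trait_names: list[str],
                    sd_mult: float = 3.0, min_cg: int = 5,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-pass record editing per trait.

    First removes records deviating more than ``sd_mult`` sample standard
    deviations from their contemporary-group mean, then removes whole
    contemporary groups left with fewer than ``min_cg`` records.  Removal
    blanks the trait value (other traits of the same animal are kept).
    """
    out = phen.copy()
    rows = []
    for t in trait_names:
        y, cg = f"y_{t}", f"cg_{t}"
        obs = out[y].notna()
        n0 = int(obs.sum())
        grp = out.loc[obs].groupby(cg)[y]
        mean = grp.transform("mean")
        sd = grp.transform("std").fillna(0.0)
        dev = (out.loc[obs, y] - mean).abs()
        outlier = dev > sd_mult * sd.replace(0.0, np.inf)
        out.loc[outlier.index[outlier], y] = np.nan
        obs = out[y].notna()
        counts = out.loc[obs].groupby(cg)[y].transform("size")
        small = counts < min_cg
        out.loc[small.index[small], y] = np.nan
        n_small = int(small.sum())
        rows.append({"trait": t, "records_in": n0,
                     "removed_outlier": int(outlier.sum()),
                     "removed_small_cg": n_small,
                     "records_out": int(out[y].notna().sum())})
    report = pd.DataFrame(rows)
    if report["records_out"].sum() == 0:
        raise ModelError("no records left after editing")
    return out, report


# ---------------------------------------------------------------------------
# relationship-inverse assembly
# ---------------------------------------------------------------------------

@dataclass
class RelationshipSet:
    """K^-1 for the genetic effects plus its bookkeeping.

    Level layout: animals ``0..n`` then kept group/metafounder columns.
    """

    kinv: sp.csr_matrix
    n_animals: int
    group_labels: list[str]
    variant: str
    Q: np.ndarray | None = None          # incidence over kept groups (UPG)
    reference_group: str | None = None
    mf: MetafounderMatrices | None = None
    F: np.ndarray | None = None          # pedigree inbreeding

    @property
    def n_levels(self) -> int:
        return self.kinv.shape[0]


def _scatter(block: np.ndarray, rows: np.ndarray, cols: np.ndarray,
             size: int) -> sp.coo_matrix:
    r = np.repeat(rows, cols.size)
    c = np.tile(cols, rows.size)
    return sp.coo_matrix((block.ravel(), (r, c)), shape=(size, size))


def _reduced_assignment(assignment: GroupAssignment,
                        constrain: bool) -> tuple[np.ndarray, list[str], str | None]:
    """Map used groups to contiguous codes, optionally dropping the last
    used group as the zero reference."""
    used = assignment.used_groups()
    labels = [assignment.definition.labels[g] for g in used]
    # a complete pedigree uses no groups: the variant collapses to its
    # group-free counterpart (A* == A^-1 with zero group columns)
    ref = labels[-1] if (constrain and labels) else None
    return used, labels, ref


def assemble_relationship_inverse(
    variant: str,
    ped: Pedigree,
    assignment: GroupAssignment | None = None,
    genotyped: np.ndarray | None = None,
    G: np.ndarray | None = None,
    gamma: GammaMatrix | None = None,
    mf: MetafounderMatrices | None = None,
    F: np.ndarray | None = None,
    constrain_group: bool = True,
    group_ridge: float = 0.0,
    dense_limit: int = DEFAULT_DENSE_LIMIT,
) -> RelationshipSet:
    """Build K^-1 for one variant.

    Pedigree-only variants return A^-1, the QP-transformed A* or the
    metafounder A(Gamma)^-1; single-step variants add the genomic
    corrections of the corresponding H^-1:

    * ``ssGBLUP``       : ``A^-1  + [G^-1 - A22^-1]``
    * ``ssGBLUP_UPG``   : ``A*    + [D, -DQ; -Q'D, Q'DQ]`` with
      ``D = G^-1 - A22^-1`` and Q restricted to genotyped animals
    * ``ssGBLUP_UPGA``  : ``A*    + [D, -A22^-1 Q; -Q'A22^-1, Q'A22^-1 Q]``
    * ``ssGBLUP_MF``    : ``A(Gamma)^-1 + [G05^-1 - A22(Gamma)^-1]``

    ``G`` is the (blended) genomic matrix matching the variant's centering;
    in UPG variants the last used group is dropped as the zero reference.

    ``group_ridge`` adds a small constant to the diagonal of the remaining
    group equations — the standard stabilization for UPG systems, which
    treats groups as random with a very large variance
    (prior variance ``sigma_u^2 / group_ridge``).  Group effects can be
    exactly confounded with trait fixed effects through the incidence Q;
    the ridge pins the unidentifiable directions without perceptibly
    shrinking identifiable group solutions.
    """
    if variant not in VARIANTS:
        raise ModelError(f"unknown variant {variant!r}")
    n = ped.n
    if F is None:
        F = compute_inbreeding(ped)
    genomic = variant.startswith("ssGBLUP")
    if genomic:
        if genotyped is None or len(genotyped) == 0:
            # empty genomic part: collapse to the pedigree-only counterpart
            return assemble_relationship_inverse(
                variant.replace("ssGBLUP", "BLUP").replace("_UPGA", "_UPG"),
                ped, assignment=assignment, gamma=gamma, mf=mf, F=F,
                constrain_group=constrain_group, group_ridge=group_ridge,
                dense_limit=dense_limit)
        genotyped = np.asarray(genotyped, dtype=np.int64)
        if G is None:
            raise ModelError("genomic variant requires the G matrix")
        if G.shape[0] != genotyped.size:
            raise ModelError("G dimension does not match the genotyped set")

    base = ("MF" if variant.endswith("_MF") else
            "UPGA" if variant.endswith("_UPGA") else
            "UPG" if variant.endswith("_UPG") else "none")

    if base == "none":
        kinv = build_A_inverse(ped, F=F)
        out = RelationshipSet(kinv, n, [], variant, F=F)
    elif base == "MF":
        if assignment is None:
            raise ModelError("metafounder variant requires a group assignment")
        if mf is None:
            if gamma is None:
                raise ModelError("metafounder variant requires Gamma")
            mf = build_Agamma(ped, gamma, assignment.sire_group,
                              assignment.dam_group, dense_limit=dense_limit)
        out = RelationshipSet(mf.Ainv.copy().tocsr(), n,
                              list(mf.gamma.labels), variant, mf=mf, F=F)
    else:  # UPG / UPGA share the QP-transformed A*
        if assignment is None:
            raise ModelError("UPG variant requires a group assignment")
        used, labels, ref = _reduced_assignment(assignment, constrain_group)
        if used.size == 0:
            # complete pedigree: Q = 0 and the variant collapses to its
            # group-free counterpart
            out = RelationshipSet(build_A_inverse(ped, F=F), n, [],
                                  variant, Q=np.zeros((n, 0)), F=F)
        else:
            remap = np.full(assignment.definition.n_groups, -1,
                            dtype=np.int64)
            remap[used] = np.arange(used.size)
            sg = np.where(assignment.sire_group >= 0,
                          remap[assignment.sire_group], -1)
            dg = np.where(assignment.dam_group >= 0,
                          remap[assignment.dam_group], -1)
            astar = build_QP_Astar(ped, sg, dg, used.size, F=F)
            Qfull = build_Q(ped, sg, dg, used.size, labels=labels).values
            keep_g = used.size - (1 if ref is not None else 0)
            keep = np.concatenate([np.arange(n), n + np.arange(keep_g)])
            kinv = astar[keep][:, keep].tocsr()
            if group_ridge > 0.0 and keep_g:
                ridge = sp.diags(np.concatenate(
                    [np.zeros(n), np.full(keep_g, group_ridge)]))
                kinv = (kinv + ridge).tocsr()
            out = RelationshipSet(kinv, n, labels[:keep_g], variant,
                                  Q=Qfull[:, :keep_g], reference_group=ref,
                                  F=F)

    if not genomic:
        return out

    Ginv = np.linalg.inv(G)
    size = out.n_levels
    if base == "MF":
        A22g = out.mf.A22(genotyped)
        corr = Ginv - np.linalg.inv(A22g)
        delta = _scatter(corr, genotyped, genotyped, size)
    else:
        _, A22inv = build_A22(ped, genotyped, dense_limit=dense_limit,
                              return_inverse=True)
        corr = Ginv - A22inv
        delta = _scatter(corr, genotyped, genotyped, size)
        if base in ("UPG", "UPGA"):
            Q2 = out.Q[genotyped]            # genotyped rows of Q
            gcols = n + np.arange(len(out.group_labels))
            M = A22inv if base == "UPGA" else corr
            mq = M @ Q2
            delta = (delta
                     + _scatter(-mq, genotyped, gcols, size)
                     + _scatter(-mq.T, gcols, genotyped, size)
                     + _scatter(Q2.T @ mq, gcols, gcols, size))
    out.kinv = (out.kinv + delta.tocsr()).tocsr()
    return out


# ---------------------------------------------------------------------------
# design and system assembly
# ---------------------------------------------------------------------------

@dataclass
class MMESystem:
    lhs: sp.csr_matrix
    rhs: np.ndarray
    spec: ModelSpec
    rel: RelationshipSet
    fixed_names: list[str]
    n_fixed: int
    n_levels: int
    n_effects: int
    n_animals: int
    n_pe: int
    dropped_maternal_links: int
    dropped_covariates: list[str]

    @property
    def u_offset(self) -> int:
        return self.n_fixed

    @property
    def pe_offset(self) -> int:
        return self.n_fixed + self.n_levels * self.n_effects


def _screen_collinear(candidates, cg_codes: np.ndarray, n_cg: int,
                      tol: float = 1e-7) -> list:
    """Keep a maximal independent subset of fixed columns.

    Each candidate is orthogonalized against the contemporary-group space
    (within-group demeaning) and the previously kept columns; a candidate
    whose residual norm falls below ``tol`` is exactly confounded and is
    dropped.
    """
    if not candidates or cg_codes.size == 0:
        return []
    counts = np.bincount(cg_codes, minlength=n_cg).astype(float)
    kept = []
    basis: list[np.ndarray] = []
    for name, level, x in candidates:
        gmean = np.bincount(cg_codes, weights=x, minlength=n_cg) / counts
        r = x - gmean[cg_codes]
        scale = np.linalg.norm(x) or 1.0
        for b in basis:
            r = r - (b @ r) * b
        nrm = np.linalg.norm(r)
        if nrm > tol * scale:
            basis.append(r / nrm)
            kept.append((name, level, x))
    return kept


def build_mme(phen: pd.DataFrame, ped: Pedigree, spec: ModelSpec,
              rel: RelationshipSet) -> MMESystem:
    """Assemble LHS/RHS of the mixed-model equations.

    Records are rows of ``phen`` (one row per animal, one column
    ``y_<trait>`` per trait, NaN = no record).  Maternal genetic and PE
    effects link to the record's dam from the analysis pedigree; a record
    of a maternal trait whose dam is unknown keeps its direct part and the
    lost link is counted.
    """
    vc = spec.varcomps
    nd = len(spec.traits)
    ne = vc.n_effects
    npe = vc.n_pe
    nlev = rel.n_levels
    n = rel.n_animals
    if ped.n != n:
        raise ModelError("pedigree/relationship size mismatch")

    animals = phen["animal"].to_numpy(dtype=np.int64)
    dams = ped.dam[animals]

    # --- fixed-effect layout -------------------------------------------------
    # The contemporary-group one-hot block is full rank by construction.
    # Factor dummies (reference level dropped) and covariates are screened
    # for exact collinearity after absorbing the CG means: structured
    # populations can make breed-fraction and heterosis covariates linearly
    # dependent, which would leave the equations singular.
    fixed_names: list[str] = []
    col_maps = []          # per trait: (cg_map, factor_maps, covariates)
    dropped_cov: list[str] = []
    offset = 0
    for t in spec.traits:
        obs = phen[f"y_{t.name}"].notna().to_numpy()
        cg_vals = phen.loc[obs, t.cg].to_numpy()
        cg_levels, cg_codes = np.unique(cg_vals, return_inverse=True)
        cg_map = {v: offset + j for j, v in enumerate(cg_levels)}
        fixed_names += [f"{t.name}:{t.cg}={v}" for v in cg_levels]
        offset += len(cg_levels)

        candidates: list[tuple[str, object, np.ndarray]] = []
        for f in t.factors:
            levels = np.unique(phen.loc[obs, f].to_numpy())
            for v in levels[1:]:
                x = (phen.loc[obs, f].to_numpy() == v).astype(float)
                candidates.append((f, v, x))
        for c in t.covariates:
            candidates.append((c, None, phen.loc[obs, c].to_numpy(dtype=float)))

        kept = _screen_collinear(candidates, cg_codes, len(cg_levels))
        fmaps: dict = {}
        covs = []
        for name, level, _x in kept:
            if level is not None:
                fmaps.setdefault(name, {})[level] = offset
                fixed_names.append(f"{t.name}:{name}={level}")
            else:
                covs.append((name, offset))
                fixed_names.append(f"{t.name}:{name}")
            offset += 1
        dropped_cov += [f"{t.name}:{name}" + ("" if lv is None else f"={lv}")
                        for name, lv, _ in candidates
                        if (name, lv) not in {(n, l) for n, l, _ in kept}]
        col_maps.append((cg_map, fmaps, covs))
    nf = offset
    u_off = nf
    pe_off = nf + nlev * ne

    # --- observation rows ----------------------------------------------------
    ymat = np.column_stack([phen[f"y_{t.name}"].to_numpy(dtype=float)
                            for t in spec.traits])
    cg_arr = [phen[t.cg].to_numpy() for t in spec.traits]
    fac_arr = [{f: phen[f].to_numpy() for f in t.factors}
               for t in spec.traits]
    cov_arr = [{c: phen[c].to_numpy(dtype=float) for c, _ in col_maps[ti][2]}
               for ti, t in enumerate(spec.traits)]
    wr, wc, wv = [], [], []
    yvals = []
    rrows, rcols, rvals = [], [], []
    pattern_inv: dict[tuple, np.ndarray] = {}
    dropped_links = 0
    row = 0
    for r in range(len(phen)):
        a = animals[r]
        obs_t = [ti for ti in range(nd) if not np.isnan(ymat[r, ti])]
        if not obs_t:
            continue
        key = tuple(obs_t)
        if key not in pattern_inv:
            sub = vc.r0[np.ix_(obs_t, obs_t)]
            pattern_inv[key] = np.linalg.inv(sub)
        rinv = pattern_inv[key]
        base_row = row
        for ti in obs_t:
            t = spec.traits[ti]
            cg_map, fmaps, covs = col_maps[ti]
            wr.append(row); wc.append(cg_map[cg_arr[ti][r]]); wv.append(1.0)
            for f, fmap in fmaps.items():
                col = fmap.get(fac_arr[ti][f][r])
                if col is not None:
                    wr.append(row); wc.append(col); wv.append(1.0)
            for c, col in covs:
                x = cov_arr[ti][c][r]
                if x != 0.0:
                    wr.append(row); wc.append(col); wv.append(x)
            wr.append(row)
            wc.append(u_off + a * ne + vc.direct_index(t.name))
            wv.append(1.0)
            if t.maternal:
                d = dams[r]
                if d == UNKNOWN:
                    dropped_links += 1
                else:
                    wr.append(row)
                    wc.append(u_off + d * ne + vc.maternal_index(t.name))
                    wv.append(1.0)
                    if t.pe and npe:
                        wr.append(row)
                        wc.append(pe_off + d * npe + vc.pe_index(t.name))
                        wv.append(1.0)
            yvals.append(ymat[r, ti])
            row += 1
        for i in range(len(obs_t)):
            for j in range(len(obs_t)):
                rrows.append(base_row + i)
                rcols.append(base_row + j)
                rvals.append(rinv[i, j])
    n_obs = row
    n_unknowns = pe_off + n * npe
    W = sp.coo_matrix((wv, (wr, wc)), shape=(n_obs, n_unknowns)).tocsr()
    Rinv = sp.coo_matrix((rvals, (rrows, rcols)),
                         shape=(n_obs, n_obs)).tocsr()
    y = np.array(yvals)

    lhs = (W.T @ Rinv @ W).tocsr()
    g0inv = np.linalg.inv(vc.g0)
    penalty = sp.kron(rel.kinv, sp.csr_matrix(g0inv), format="csr")
    pad = sp.csr_matrix((nf, nf))
    blocks = [pad, penalty]
    if npe:
        blocks.append(sp.kron(sp.identity(n, format="csr"),
                              sp.csr_matrix(np.linalg.inv(vc.p0)),
                              format="csr"))
    else:
        blocks.append(sp.csr_matrix((0, 0)))
    lhs = lhs + sp.block_diag(blocks, format="csr")
    rhs = W.T @ (Rinv @ y)
    return MMESystem(lhs=lhs.tocsr(), rhs=rhs, spec=spec, rel=rel,
                     fixed_names=fixed_names, n_fixed=nf, n_levels=nlev,
                     n_effects=ne, n_animals=n, n_pe=npe,
                     dropped_maternal_links=dropped_links,
                     dropped_covariates=dropped_cov)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

@dataclass
class SolutionSet:
    system: MMESystem
    values: np.ndarray
    solver: str
    iterations: int
    relative_residual: float

    @property
    def fixed(self) -> pd.Series:
        return pd.Series(self.values[:self.system.n_fixed],
                         index=self.system.fixed_names)

    @property
    def u(self) -> np.ndarray:
        """Genetic-effect solutions, levels x effects."""
        s = self.system
        block = self.values[s.u_offset:s.u_offset + s.n_levels * s.n_effects]
        return block.reshape(s.n_levels, s.n_effects)

    @property
    def pe(self) -> np.ndarray:
        s = self.system
        return (self.values[s.pe_offset:].reshape(s.n_animals, s.n_pe)
                if s.n_pe else np.zeros((s.n_animals, 0)))

    def group_solutions(self) -> pd.DataFrame:
        s = self.system
        rows = []
        for j, lab in enumerate(s.rel.group_labels):
            for e, ename in enumerate(_effect_labels(s.spec.varcomps)):
                rows.append({"group": lab, "effect": ename,
                             "solution": self.u[s.n_animals + j, e]})
        return pd.DataFrame(rows)


def _effect_labels(vc: VarComponents) -> list[str]:
    return ([f"{t}_dir" for t in vc.trait_names]
            + [f"{t}_mat" for t in vc.maternal_traits])


def _block_jacobi(system: MMESystem) -> spla.LinearOperator:
    """Inverse of the level-wise diagonal blocks (block-Jacobi)."""
    lhs = system.lhs.tocoo()
    nf, ne, npe = system.n_fixed, system.n_effects, system.n_pe
    u_off, pe_off = system.u_offset, system.pe_offset
    nlev, n = system.n_levels, system.n_animals
    ntot = lhs.shape[0]
    diag = np.asarray(system.lhs.diagonal())
    diag[diag == 0.0] = 1.0
    ublocks = np.zeros((nlev, ne, ne))
    pblocks = np.zeros((n, npe, npe)) if npe else None
    i, j, v = lhs.row, lhs.col, lhs.data
    in_u = (i >= u_off) & (i < pe_off) & (j >= u_off) & (j < pe_off)
    bi, bj = (i[in_u] - u_off) // ne, (j[in_u] - u_off) // ne
    same = bi == bj
    np.add.at(ublocks,
              (bi[same], (i[in_u][same] - u_off) % ne,
               (j[in_u][same] - u_off) % ne), v[in_u][same])
    if npe:
        in_p = (i >= pe_off) & (j >= pe_off)
        bi, bj = (i[in_p] - pe_off) // npe, (j[in_p] - pe_off) // npe
        same = bi == bj
        np.add.at(pblocks,
                  (bi[same], (i[in_p][same] - pe_off) % npe,
                   (j[in_p][same] - pe_off) % npe), v[in_p][same])
    uinv = np.linalg.inv(ublocks)
    pinv = np.linalg.inv(pblocks) if npe else None

    def apply(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        out[:nf] = x[:nf] / diag[:nf]
        xu = x[u_off:pe_off].reshape(nlev, ne)
        out[u_off:pe_off] = np.einsum("lij,lj->li", uinv, xu).ravel()
        if npe:
            xp = x[pe_off:].reshape(n, npe)
            out[pe_off:] = np.einsum("lij,lj->li", pinv, xp).ravel()
        return out

    return spla.LinearOperator((ntot, ntot), matvec=apply)


def solve_mme(system: MMESystem, method: str = "direct",
              tol: float = 1e-12, maxiter: int = 5000) -> SolutionSet:
    """Solve the assembled equations.

    ``method='direct'`` uses sparse LU; ``'pcg'`` uses conjugate gradients
    with a block-Jacobi preconditioner.  Every solution is checked against
    the residual contract ``||LHS s - RHS|| / ||RHS|| < 1e-10``.
    """
    rhs = system.rhs
    if np.allclose(rhs, 0.0):
        return SolutionSet(system, np.zeros_like(rhs), method, 0, 0.0)
    if method == "direct":
        lu = spla.splu(system.lhs.tocsc())
        x = lu.solve(rhs)
        iters = 1
    elif method == "pcg":
        M = _block_jacobi(system)
        count = {"n": 0}

        def cb(_):
            count["n"] += 1

        x, info = spla.cg(system.lhs, rhs, rtol=tol, maxiter=maxiter,
                          M=M, callback=cb)
        iters = count["n"]
        if info > 0:
            raise ModelError(
                f"PCG did not converge in {maxiter} iterations "
                f"(residual {np.linalg.norm(system.lhs @ x - rhs):.3e})")
    else:
        raise ModelError("method must be 'direct' or 'pcg'")
    resid = float(np.linalg.norm(system.lhs @ x - rhs)
                  / np.linalg.norm(rhs))
    if resid > 1e-10:
        raise ModelError(f"solver residual {resid:.3e} violates the "
                         "1e-10 contract")
    return SolutionSet(system, x, method, iters, resid)


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def total_genetic_value(sol: SolutionSet, trait: str,
                        effect: str = "direct",
                        Q: np.ndarray | None = None,
                        group_solutions: np.ndarray | None = None,
                        ) -> np.ndarray:
    """Per-animal (G)EBV for one trait.

    With the QP transformation (UPG variants) and with metafounders the
    solved animal effects already carry the group contribution, so the
    total merit Qg + u is the animal block itself.  For an explicit
    group-covariate formulation pass ``Q`` and the fixed group solutions to
    add Qg to u.
    """
    s = sol.system
    vc = s.spec.varcomps
    idx = (vc.direct_index(trait) if effect == "direct"
           else vc.maternal_index(trait))
    u = sol.u[:s.n_animals, idx]
    if Q is not None:
        if group_solutions is None:
            raise ModelError("explicit formulation requires group solutions")
        return u + Q @ group_solutions
    return u
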