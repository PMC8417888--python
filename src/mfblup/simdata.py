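"""Synthetic composite beef-cattle population with known truth.

The generator emulates a four-breed composite population (NABC biological
types): divergent purebred base breeds, intermediate two-way crosses and
three/four-way composites, phenotypes with direct and maternal genetic
effects, maternal permanent environment and heterosis, parents masked at
random to create unknown-parent slots, and a genotyped subset concentrated
in the youngest generations.

Breed divergence follows a Balding-Nichols drift model: for each marker an
ancestral frequency p0 ~ U[0.05, 0.95] and per-breed frequencies
``p_b ~ Beta(p0 (1-F_b)/F_b, (1-p0)(1-F_b)/F_b)``.  The matrix of
relationships among the four base populations is then known exactly as
``Gamma = 8 Cov(p)`` across markers, which makes recovery of Gamma from
genotypes a testable target.  Markers are independent (no linkage), so the
relationship-matrix formulas used downstream are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import MarkerMatrix
from .groups import BREEDS, HET_COLUMNS, heterosis_covariates, propagate_breed_composition
from .mme import VarComponents
from .pedigree import (UNKNOWN, GammaMatrix, Pedigree, compute_inbreeding,
                       mendelian_variances)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TraitDef:
    """One simulated trait (variances in standardized phenotypic units)."""

    name: str
    var_direct: float
    var_residual: float
    var_maternal: float = 0.0
    cov_direct_maternal: float = 0.0
    var_pe: float = 0.0
    male_only: bool = False
    cg_scheme: str = "fys"      # 'fys' farm-year-season-sex | 'fy' farm-year
    het_direct: tuple = (0.25, 0.25, 0.25, 0.10, 0.10, 0.10)
    het_maternal: float = 0.0
    breed_means: tuple = (0.0, 0.0, 0.0, 0.0)
    age_coef: float = 0.0

    @property
    def maternal(self) -> bool:
        return self.var_maternal > 0.0


@dataclass
class TraitParams:
    """Trait set plus across-trait correlations."""

    traits: list[TraitDef]
    gen_corr_direct: float = 0.3
    gen_corr_maternal: float = 0.3
    res_corr: float = 0.2
    #: fraction of the direct genetic variance carried by the simulated
    #: markers (the markers act as the causal loci; the remainder is a
    #: polygenic term generated by pedigree recursion).  Maternal effects
    #: are fully polygenic.
    marker_fraction: float = 0.8

    def __post_init__(self) -> None:
        for t in self.traits:
            if t.var_direct <= 0 or t.var_residual <= 0:
                raise SimulationError(f"trait {t.name}: variances must be > 0")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def maternal_names(self) -> list[str]:
        return [t.name for t in self.traits if t.maternal]

    def effect_labels(self) -> list[str]:
        return ([f"{t.name}_dir" for t in self.traits]
                + [f"{t.name}_mat" for t in self.traits if t.maternal])

    def varcomponents(self) -> VarComponents:
        """Assemble the genetic (G0), PE (P0) and residual (R0) covariances."""
        nd = len(self.traits)
        mat = [t for t in self.traits if t.maternal]
        nm = len(mat)
        g0 = np.zeros((nd + nm, nd + nm))
        sd_d = np.sqrt([t.var_direct for t in self.traits])
        for i in range(nd):
            for j in range(nd):
                r = 1.0 if i == j else self.gen_corr_direct
                g0[i, j] = r * sd_d[i] * sd_d[j]
        sd_m = np.sqrt([t.var_maternal for t in mat])
        for i in range(nm):
            for j in range(nm):
                r = 1.0 if i == j else self.gen_corr_maternal
                g0[nd + i, nd + j] = r * sd_m[i] * sd_m[j]
        for mi, t in enumerate(mat):
            di = self.names.index(t.name)
            g0[di, nd + mi] = g0[nd + mi, di] = t.cov_direct_maternal
        p0 = np.diag([t.var_pe for t in mat]) if nm else np.zeros((0, 0))
        r0 = np.zeros((nd, nd))
        sd_e = np.sqrt([t.var_residual for t in self.traits])
        for i in range(nd):
            for j in range(nd):
                r = 1.0 if i == j else self.res_corr
                r0[i, j] = r * sd_e[i] * sd_e[j]
        np.linalg.cholesky(g0)   # must be positive definite
        np.linalg.cholesky(r0)
        return VarComponents(g0=g0, p0=p0, r0=r0,
                             trait_names=self.names,
                             maternal_traits=self.maternal_names)


def default_trait_params() -> TraitParams:
    """Four traits mirroring a beef-cattle evaluation.

    A male-only reproductive trait (h2 = 0.25), post-weaning gain
    (h2 = 0.09), weaning weight (h2 = 0.23, maternal) and birth weight
    (h2 = 0.22, maternal); unit phenotypic variance per trait.
    """
    return TraitParams(traits=[
        TraitDef("sc", 0.25, 0.75, male_only=True, cg_scheme="fy",
                 age_coef=0.10),
        TraitDef("pwg", 0.09, 0.91, cg_scheme="fy"),
        TraitDef("ww", 0.23, 0.62, var_maternal=0.10,
                 cov_direct_maternal=-0.3 * np.sqrt(0.23 * 0.10),
                 var_pe=0.05, het_maternal=0.10),
        TraitDef("bw", 0.22, 0.70, var_maternal=0.05,
                 cov_direct_maternal=-0.3 * np.sqrt(0.22 * 0.05),
                 var_pe=0.03, het_maternal=0.05),
    ])


@dataclass
class MatingRule:
    """One mating-plan rule: offspring pool built from two parent pools.

    A pool reference may be a union, written ``"NABC|NAB"``: parents are
    drawn from the pooled animals, so offspring breed compositions vary
    within the new pool — the composite stages then carry a quasi-continuous
    spread of compositions, as in a real composite program.
    """

    name: str
    sire_pool: str
    dam_pool: str
    n_offspring: int


def default_mating_plan(scale: float = 1.0) -> list[MatingRule]:
    """Crossing plan: two-way crosses, three/four-way intermediates, then
    three admixed composite generations."""
    c = lambda n: max(4, int(round(n * scale)))
    return [
        MatingRule("NA", "N", "A", c(240)),
        MatingRule("NB", "N", "B", c(240)),
        MatingRule("NC", "N", "C", c(160)),
        MatingRule("BC", "B", "C", c(160)),
        MatingRule("NAB", "NA", "B", c(200)),
        MatingRule("NBC", "NB", "C", c(200)),
        MatingRule("NABC", "NA", "BC", c(240)),
        MatingRule("COMP1", "NABC|NAB", "NABC|NBC", c(420)),
        MatingRule("COMP2", "COMP1", "COMP1|NABC", c(420)),
        MatingRule("COMP3", "COMP2", "COMP2|COMP1", c(520)),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic composite population."""

    n_markers: int = 3000
    n_base_per_breed: int = 150
    divergence: tuple = (0.20, 0.10, 0.08, 0.12)
    mating_plan: list[MatingRule] = field(default_factory=default_mating_plan)
    trait_params: TraitParams = field(default_factory=default_trait_params)
    mask_sire_prob: float = 0.15
    mask_dam_prob: float = 0.10
    genotyped_pools: tuple = ("COMP2", "COMP3")
    #: fraction of every other non-founder pool that is genotyped, mimicking
    #: the scattering of genotyped animals across intermediate-cross groups
    #: (it also keeps the breed-composition design of the genotyped set at
    #: full rank for base-frequency estimation)
    genotype_cross_fraction: float = 0.05
    genotype_founder_fraction: float = 0.0
    n_farms: int = 8
    n_seasons: int = 2
    cg_sd: float = 0.3
    dam_age_effects: tuple = (0.0, 0.08, 0.12, 0.05)
    seed: int = 20160612

    def __post_init__(self) -> None:
        if not all(0.0 < f < 1.0 for f in self.divergence):
            raise SimulationError("divergence F_b must be in (0, 1)")
        for p in (self.mask_sire_prob, self.mask_dam_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("masking probabilities must be in [0, 1]")
        if self.n_markers < 1:
            raise SimulationError("n_markers must be >= 1")


# ---------------------------------------------------------------------------
# base frequencies
# ---------------------------------------------------------------------------

def sample_base_frequencies(n_markers: int, divergence, rng
                            ) -> tuple[np.ndarray, GammaMatrix]:
    """Balding-Nichols base-breed allele frequencies and the true Gamma.

    Returns a markers x 4 frequency matrix and ``Gamma = 8 x`` the sample
    covariance of the four frequency columns across markers.
    """
    divergence = np.asarray(divergence, dtype=float)
    if np.any(divergence <= 0.0) or np.any(divergence >= 1.0):
        raise SimulationError("divergence F_b must be in (0, 1)")
    if n_markers < 1:
        raise SimulationError("n_markers must be >= 1")
    p0 = rng.uniform(0.05, 0.95, size=n_markers)
    freqs = np.empty((n_markers, divergence.size))
    for b, F in enumerate(divergence):
        a = p0 * (1.0 - F) / F
        bpar = (1.0 - p0) * (1.0 - F) / F
        freqs[:, b] = rng.beta(a, bpar)
    true_gamma = GammaMatrix(8.0 * np.cov(freqs, rowvar=False),
                             labels=list(BREEDS[:divergence.size]))
    return freqs, true_gamma


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig, rng) -> Pedigree:
    """Founders (purebred, both parents unknown) plus the mating plan.

    Offspring breed composition is the mean of the parents'; birth order is
    topological; each rule draws a limited sire team (one sire per ~10
    offspring) to create paternal half-sib families.
    """
    nb = config.n_base_per_breed
    n_founders = 4 * nb
    sire = [UNKNOWN] * n_founders
    dam = [UNKNOWN] * n_founders
    comp = np.zeros((n_founders, 4))
    sex = np.empty(n_founders, dtype=np.int8)
    gen = np.zeros(n_founders, dtype=np.int64)
    pool_names = [""] * n_founders
    pools: dict[str, np.ndarray] = {}
    for b, breed in enumerate(BREEDS):
        idx = np.arange(b * nb, (b + 1) * nb)
        comp[idx, b] = 1.0
        sex[idx] = np.where(np.arange(nb) % 2 == 0, 1, 2)
        for i in idx:
            pool_names[i] = breed
        pools[breed] = idx
    comp_rows = [comp]
    nxt = n_founders
    sex = list(sex)
    gen = list(gen)
    for r_i, rule in enumerate(config.mating_plan):
        def members(ref: str) -> list[int]:
            out = []
            for pname in ref.split("|"):
                if pname not in pools:
                    raise SimulationError(
                        f"rule {rule.name!r} references undefined pool "
                        f"{pname!r} (undefined or cyclic mating plan)")
                out.extend(pools[pname].tolist())
            return out
        males = [i for i in members(rule.sire_pool) if sex[i] == 1]
        females = [i for i in members(rule.dam_pool) if sex[i] == 2]
        if not males or not females:
            raise SimulationError(f"rule {rule.name!r}: empty parent pool")
        n_sires = min(len(males), max(1, rule.n_offspring // 10))
        team = rng.choice(males, size=n_sires, replace=False)
        new = np.arange(nxt, nxt + rule.n_offspring)
        s_draw = rng.choice(team, size=rule.n_offspring)
        d_draw = rng.choice(females, size=rule.n_offspring)
        sire.extend(s_draw.tolist())
        dam.extend(d_draw.tolist())
        allc = np.vstack(comp_rows)
        comp_rows.append(0.5 * (allc[s_draw] + allc[d_draw]))
        sex.extend(rng.integers(1, 3, size=rule.n_offspring).tolist())
        gen.extend([r_i + 1] * rule.n_offspring)
        pool_names.extend([rule.name] * rule.n_offspring)
        pools[rule.name] = new
        nxt += rule.n_offspring
    return Pedigree(np.array(sire), np.array(dam),
                    breed_comp=np.vstack(comp_rows),
                    sex=np.array(sex, dtype=np.int8),
                    birth_gen=np.array(gen),
                    pool=np.array(pool_names))


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def gene_drop(ped: Pedigree, base_freqs: np.ndarray, rng) -> np.ndarray:
    """Drop alleles through the pedigree (independent markers).

    Founder alleles are two Bernoulli draws from the breed frequency;
    non-founder genotypes transmit one random allele from each parent.
    Founders must be purebred (unit breed-composition vector).
    """
    n, m = ped.n, base_freqs.shape[0]
    geno = np.zeros((n, m), dtype=np.int8)
    founder = ped.is_founder
    if ped.breed_comp is None:
        raise SimulationError("pedigree lacks breed composition")
    for i in np.flatnonzero(founder):
        c = ped.breed_comp[i]
        if not np.isclose(c.max(), 1.0):
            raise SimulationError(
                f"founder {i} is not purebred; the simulator requires "
                "purebred founders")
        p = base_freqs[:, int(np.argmax(c))]
        geno[i] = rng.binomial(2, p).astype(np.int8)
    for i in np.flatnonzero(~founder):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            raise SimulationError("gene_drop requires a complete pedigree "
                                  "below the founders")
        a1 = rng.random(m) < geno[s] / 2.0
        a2 = rng.random(m) < geno[d] / 2.0
        geno[i] = (a1.astype(np.int8) + a2.astype(np.int8))
    return geno


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

@dataclass
class TrueState:
    """Ground truth retained by the simulator."""

    base_freqs: np.ndarray
    true_gamma: GammaMatrix
    true_bv: np.ndarray | None = None      # animals x genetic effects
    effect_labels: list[str] = field(default_factory=list)


def simulate_breeding_values(ped: Pedigree, params: TraitParams, rng,
                             F: np.ndarray | None = None,
                             geno: np.ndarray | None = None,
                             base_freqs: np.ndarray | None = None,
                             ) -> np.ndarray:
    """Multivariate breeding values: polygenic recursion plus marker QTL.

    The polygenic part follows ``u_i = 0.5 (u_s + u_d) + phi_i`` with
    Mendelian-sampling covariance ``d_i G0`` where
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` over known parents; founders draw
    from ``N(0, G0)``.  When ``marker_fraction`` > 0 the simulated markers
    act as causal loci for the direct effects: per-marker effects are drawn
    correlated across traits and scaled so the marker term contributes
    ``marker_fraction`` of the direct variance in the ancestral base (breed
    divergence then shifts base-breed trait means exactly as overlapping
    base populations would).  Configured base-breed means are added through
    the breed composition on top.
    """
    vc = params.varcomponents()
    L = np.linalg.cholesky(vc.g0)
    ne = vc.g0.shape[0]
    if F is None:
        F = compute_inbreeding(ped)
    d = mendelian_variances(ped.sire, ped.dam, F)
    nd = len(params.traits)
    omega = params.marker_fraction
    if not 0.0 <= omega <= 1.0:
        raise SimulationError("marker_fraction must be in [0, 1]")
    # polygenic component (direct columns down-weighted by 1 - omega)
    w = np.ones(ne)
    w[:nd] = np.sqrt(1.0 - omega)
    u = np.empty((ped.n, ne))
    z = rng.standard_normal((ped.n, ne))
    for i in range(ped.n):
        s, dd = ped.sire[i], ped.dam[i]
        phi = w * (z[i] @ L.T)
        if s == UNKNOWN and dd == UNKNOWN:
            u[i] = phi
            continue
        pa = np.zeros(ne)
        if s != UNKNOWN:
            pa += 0.5 * u[s]
        if dd != UNKNOWN:
            pa += 0.5 * u[dd]
        u[i] = pa + np.sqrt(d[i]) * phi
    if omega > 0.0:
        if geno is None or base_freqs is None:
            raise SimulationError(
                "marker_fraction > 0 requires gene content and base "
                "frequencies")
        pbar = base_freqs.mean(axis=1)
        denom = float(np.sum(2.0 * pbar * (1.0 - pbar)))
        C = np.full((nd, nd), params.gen_corr_direct)
        np.fill_diagonal(C, 1.0)
        raw = rng.standard_normal((base_freqs.shape[0], nd)) @ np.linalg.cholesky(C).T
        sd_t = np.sqrt([t.var_direct / denom for t in params.traits])
        beta = raw * sd_t
        u[:, :nd] += np.sqrt(omega) * ((geno - 2.0 * pbar) @ beta)
    if ped.breed_comp is not None:
        for t_i, t in enumerate(params.traits):
            u[:, t_i] += ped.breed_comp @ np.asarray(t.breed_means, dtype=float)
    return u


def simulate_traits(ped: Pedigree, params: TraitParams, rng,
                    het: pd.DataFrame | None = None,
                    geno: np.ndarray | None = None,
                    base_freqs: np.ndarray | None = None,
                    n_farms: int = 8, n_seasons: int = 2,
                    cg_sd: float = 0.3,
                    dam_age_effects=(0.0, 0.08, 0.12, 0.05),
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Phenotypes for all non-founder animals.

    ``y = CG effect + fixed covariates + direct BV + dam's maternal BV +
    dam's PE + residual``; contemporary groups come from simulated
    farm x generation (x season x sex) factors; the male-only trait is
    recorded for males only.  Returns the record table and the true
    breeding values (animals x genetic effects).
    """
    vc = params.varcomponents()
    u = simulate_breeding_values(ped, params, rng, geno=geno,
                                 base_freqs=base_freqs)
    n = ped.n
    nd = len(params.traits)
    mat_names = params.maternal_names
    if het is None:
        het = heterosis_covariates(ped, propagate_breed_composition(ped))
    # permanent environment of every animal in its role as dam
    if vc.p0.shape[0]:
        pe = rng.multivariate_normal(np.zeros(vc.p0.shape[0]), vc.p0, size=n)
    else:
        pe = np.zeros((n, 0))
    farm = rng.integers(0, n_farms, size=n)
    season = rng.integers(0, n_seasons, size=n)
    dam_age = rng.integers(0, len(dam_age_effects), size=n)
    sex = ped.sex if ped.sex is not None else np.full(n, 1, dtype=np.int8)
    gen = ped.birth_gen if ped.birth_gen is not None else np.zeros(n, int)
    age_dev = rng.standard_normal(n)
    resid = rng.multivariate_normal(np.zeros(nd), vc.r0, size=n)
    recorded = ~ped.is_founder
    rows = {"animal": np.flatnonzero(recorded)}
    phen = pd.DataFrame(rows)
    phen["sex"] = sex[recorded]
    phen["gen"] = gen[recorded]
    phen["farm"] = farm[recorded]
    phen["season"] = season[recorded]
    phen["dam_age"] = dam_age[recorded]
    phen["age_dev"] = age_dev[recorded]
    for c in list(HET_COLUMNS) + ["het_maternal"]:
        phen[c] = het[c].to_numpy()[recorded]
    het_d = het[list(HET_COLUMNS)].to_numpy()
    het_m = het["het_maternal"].to_numpy()
    dam_age_effects = np.asarray(dam_age_effects, dtype=float)
    has_dam = ped.dam != UNKNOWN
    dam_idx = np.where(has_dam, ped.dam, 0)
    cg_effect_store: dict[str, np.ndarray] = {}
    for t_i, t in enumerate(params.traits):
        if t.cg_scheme == "fys":
            keys = list(zip(farm, gen, season, sex))
        else:
            keys = list(zip(farm, gen))
        codes, uniq = pd.factorize(pd.Series(keys))
        eff = rng.normal(0.0, cg_sd, size=len(uniq))
        cg_effect_store[t.name] = eff
        y = (eff[codes] + u[:, t_i] + resid[:, t_i]
             + het_d @ np.asarray(t.het_direct, dtype=float)
             + t.het_maternal * het_m + t.age_coef * age_dev)
        if t.maternal:
            mi = nd + mat_names.index(t.name)
            add = (u[dam_idx, mi] + pe[dam_idx, mat_names.index(t.name)]
                   + dam_age_effects[dam_age])
            y = np.where(has_dam, y + add, y)
        keep = recorded & (sex == 1) if t.male_only else recorded
        y = np.where(keep, y, np.nan)
        phen[f"y_{t.name}"] = y[recorded]
        phen[f"cg_{t.name}"] = codes[recorded]
    phen.attrs["cg_effects"] = cg_effect_store
    return phen, u


# ---------------------------------------------------------------------------
# masking and genotyped subset
# ---------------------------------------------------------------------------

def mask_parents(ped: Pedigree, mask_sire_prob: float, mask_dam_prob: float,
                 rng) -> tuple[Pedigree, dict]:
    """Randomly hide parents of non-founders; keep the truth map."""
    for p in (mask_sire_prob, mask_dam_prob):
        if not 0.0 <= p <= 1.0:
            raise SimulationError("masking probabilities must be in [0, 1]")
    sire = ped.sire.copy()
    dam = ped.dam.copy()
    nonf = ~ped.is_founder
    drop_s = nonf & (rng.random(ped.n) < mask_sire_prob)
    drop_d = nonf & (rng.random(ped.n) < mask_dam_prob)
    sire[drop_s] = UNKNOWN
    dam[drop_d] = UNKNOWN
    masked = Pedigree(sire, dam, breed_comp=ped.breed_comp, sex=ped.sex,
                      birth_gen=ped.birth_gen, pool=ped.pool)
    truth = {"true_sire": ped.sire.copy(), "true_dam": ped.dam.copy(),
             "masked_sire": np.flatnonzero(drop_s),
             "masked_dam": np.flatnonzero(drop_d)}
    return masked, truth


def select_genotyped(ped: Pedigree, config: SimConfig, rng) -> np.ndarray:
    """Genotyped subset: configured recent pools plus an optional founder
    fraction (founder genotypes anchor the base-frequency estimation)."""
    chosen = []
    if ped.pool is not None:
        for name in config.genotyped_pools:
            chosen.append(np.flatnonzero(ped.pool == name))
        if config.genotype_cross_fraction > 0:
            others = {r.name for r in config.mating_plan
                      if r.name not in config.genotyped_pools}
            for name in sorted(others):
                idx = np.flatnonzero(ped.pool == name)
                k = int(round(config.genotype_cross_fraction * idx.size))
                if k:
                    chosen.append(np.sort(rng.choice(idx, size=k,
                                                     replace=False)))
    if config.genotype_founder_fraction > 0:
        f = np.flatnonzero(ped.is_founder)
        k = int(round(config.genotype_founder_fraction * f.size))
        if k:
            chosen.append(np.sort(rng.choice(f, size=k, replace=False)))
    if not chosen:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate(chosen))


# ---------------------------------------------------------------------------
# one-call simulation bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    config: SimConfig
    ped_true: Pedigree          # complete pedigree
    ped: Pedigree               # masked pedigree (the analyst's view)
    truth_map: dict
    genotyped: np.ndarray       # pedigree indices of genotyped animals
    markers: MarkerMatrix       # gene content of the genotyped subset
    gene_content: np.ndarray    # full animals x markers matrix
    phenotypes: pd.DataFrame
    state: TrueState


def simulate(config: SimConfig) -> SimulatedData:
    """Run the full generator under one seed: frequencies, pedigree, gene
    drop, traits, masking, genotyped subset."""
    rng = np.random.default_rng(config.seed)
    freqs, true_gamma = sample_base_frequencies(config.n_markers,
                                                config.divergence, rng)
    ped_true = simulate_pedigree(config, rng)
    geno = gene_drop(ped_true, freqs, rng)
    phen, u = simulate_traits(
        ped_true, config.trait_params, rng,
        geno=geno, base_freqs=freqs,
        n_farms=config.n_farms, n_seasons=config.n_seasons,
        cg_sd=config.cg_sd, dam_age_effects=config.dam_age_effects)
    masked, truth = mask_parents(ped_true, config.mask_sire_prob,
                                 config.mask_dam_prob, rng)
    genotyped = select_genotyped(ped_true, config, rng)
    markers = MarkerMatrix(geno[genotyped], animal_ids=genotyped)
    state = TrueState(base_freqs=freqs, true_gamma=true_gamma, true_bv=u,
                      effect_labels=config.trait_params.effect_labels())
    return SimulatedData(config=config, ped_true=ped_true, ped=masked,
                         truth_map=truth, genotyped=genotyped,
                         markers=markers, gene_content=geno,
                         phenotypes=phen, state=state)
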