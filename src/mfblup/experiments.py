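"""Reproducible study-scale experiments.

Each function runs one self-contained experiment — oracle equivalences on
random pedigrees, Gamma recovery, LR-method calibration, the plain-vs-
metafounder bias comparison, base-compatibility diagnostics and the solver
contract — and returns a flat dict of measured quantities.  The acceptance
checks and the ``scripts/acceptance.py`` entry point both run these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .gamma import estimate_gamma, gls_base_frequencies
from .genomic import (AUTOSOME, SEX, MarkerMatrix, build_G, build_G05,
                      matrix_summary, qc_markers)
from .groups import GroupDefinition, assign_groups, propagate_breed_composition
from .mme import (ModelSpec, RelationshipSet, TraitModel,
                  assemble_relationship_inverse, build_mme, edit_phenotypes,
                  solve_mme, total_genetic_value)
from .pedigree import (GammaMatrix, Pedigree, build_A, build_Agamma,
                       build_A_inverse, compute_inbreeding)
from .pipeline import RunConfig, make_trait_models, run_evaluation
from .simdata import (MatingRule, SimConfig, TraitDef, TraitParams,
                      default_mating_plan, gene_drop, sample_base_frequencies,
                      simulate_pedigree)


# ---------------------------------------------------------------------------
# random pedigrees for matrix oracles
# ---------------------------------------------------------------------------

def random_pedigree(rng, n: int, p_unknown: float = 0.25,
                    founder_frac: float = 0.25) -> Pedigree:
    """Random topologically ordered pedigree with scattered unknown parents."""
    nf = max(2, int(n * founder_frac))
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    for i in range(nf, n):
        if rng.random() >= p_unknown:
            sire[i] = rng.integers(0, i)
        if rng.random() >= p_unknown:
            dam[i] = rng.integers(0, i)
    return Pedigree(sire, dam)


def random_groups(rng, ped: Pedigree, n_groups: int = 4):
    """Random group codes for every unknown-parent slot."""
    sg = np.where(ped.sire == -1, rng.integers(0, n_groups, ped.n), -1)
    dg = np.where(ped.dam == -1, rng.integers(0, n_groups, ped.n), -1)
    return sg.astype(np.int64), dg.astype(np.int64)


def pedigree_inverse_oracle(seed: int, n_pedigrees: int = 50,
                            max_n: int = 200) -> dict:
    """A^-1 A = I and A(Gamma)^-1 A(Gamma) = I against the tabular method."""
    rng = np.random.default_rng(seed)
    worst_a = worst_g = 0.0
    for _ in range(n_pedigrees):
        n = int(rng.integers(20, max_n + 1))
        ped = random_pedigree(rng, n)
        A = build_A(ped)
        Ainv = build_A_inverse(ped).toarray()
        worst_a = max(worst_a, np.abs(Ainv @ A - np.eye(n)).max())
        sg, dg = random_groups(rng, ped)
        raw = rng.standard_normal((4, 6))
        gamma = GammaMatrix(raw @ raw.T / 6 * 0.3 + 0.05 * np.eye(4))
        mf = build_Agamma(ped, gamma, sg, dg)
        worst_g = max(worst_g,
                      np.abs(mf.Ainv.toarray() @ mf.A - np.eye(n + 4)).max())
    trio = Pedigree(np.array([-1, -1, 0]), np.array([-1, -1, 1]))
    trio_dev = np.abs(build_A_inverse(trio).toarray()
                      - np.array([[1.5, 0.5, -1.0],
                                  [0.5, 1.5, -1.0],
                                  [-1.0, -1.0, 2.0]])).max()
    return {"max_dev_AinvA": worst_a, "max_dev_AGinvAG": worst_g,
            "trio_dev": trio_dev, "n_pedigrees": n_pedigrees}


# ---------------------------------------------------------------------------
# shared small-population helper
# ---------------------------------------------------------------------------

def _small_population(seed: int, scale: float, n_base: int = 25,
                      n_markers: int = 60,
                      breed_means=(0.5, 0.2, -0.2, -0.5)) -> tuple:
    """A small masked population with one direct trait and GG4 assignment."""
    sd = np.sqrt(0.3)
    tp = TraitParams(traits=[TraitDef(
        "t", 0.3, 0.7, cg_scheme="fy",
        breed_means=tuple(np.asarray(breed_means) * sd))],
        marker_fraction=0.0)
    cfg = SimConfig(n_markers=n_markers, n_base_per_breed=n_base,
                    mating_plan=default_mating_plan(scale=scale),
                    trait_params=tp, seed=seed)
    from .simdata import simulate
    data = simulate(cfg)
    ped = data.ped
    comps = propagate_breed_composition(ped)
    assignment = assign_groups(ped, comps, GroupDefinition("GG4"))
    phen, _ = edit_phenotypes(data.phenotypes, ["t"], min_cg=2)
    traits = make_trait_models(tp, include_breed_fracs=False)
    vc = tp.varcomponents()
    return data, ped, assignment, phen, traits, vc


def zero_gamma_equivalence(seed: int, scale: float = 0.105) -> dict:
    """Zero-Gamma metafounder limit versus QP-transformed UPGs.

    Solves pedigree BLUP three ways on one ~300-animal population:
    QP-transformed UPGs; the exact zero-Gamma metafounder limit
    (A(Gamma)^-1 accumulation at Gamma = eps I with the vanishing
    metafounder prior omitted, matching reference constraint); and the
    small-Gamma model with its prior retained, whose metafounder solutions
    shrink to zero so it reduces to plain BLUP rather than to the UPG
    model.  Differences are reported in units of the genetic standard
    deviation.
    """
    data, ped, assignment, phen, traits, vc = _small_population(seed, scale)
    sd = np.sqrt(vc.g0[0, 0])
    F = compute_inbreeding(ped)

    def run(rel):
        spec = ModelSpec(traits=traits, varcomps=vc, variant=rel.variant)
        return solve_mme(build_mme(phen, ped, spec, rel))

    rel_upg = assemble_relationship_inverse("BLUP_UPG", ped,
                                            assignment=assignment, F=F)
    u_upg = total_genetic_value(run(rel_upg), "t")

    eps = 1e-6
    gamma_eps = GammaMatrix(eps * np.eye(4), labels=["N", "A", "B", "C"])
    # exact zero-Gamma limit: metafounders as fixed columns, matched
    # reference constraint (the dropped reference group's metafounder
    # column is removed the same way)
    mf_fixed = build_Agamma(ped, gamma_eps, assignment.sire_group,
                            assignment.dam_group, include_prior=False)
    labels = list(rel_upg.group_labels)
    used = assignment.used_groups()
    keep = np.concatenate([np.arange(ped.n), ped.n + used[:-1]])
    rel_fixed = RelationshipSet(mf_fixed.Ainv[keep][:, keep].tocsr(), ped.n,
                                labels, "BLUP_MF", F=F)
    u_fixed = total_genetic_value(run(rel_fixed), "t")

    rel_prior = assemble_relationship_inverse(
        "BLUP_MF", ped, assignment=assignment, gamma=gamma_eps, F=F)
    u_prior = total_genetic_value(run(rel_prior), "t")
    u_blup = total_genetic_value(
        run(assemble_relationship_inverse("BLUP", ped, F=F)), "t")

    # matrix-level check: accumulation part of A(Gamma)^-1 vs A*
    astar = assemble_relationship_inverse("BLUP_UPG", ped,
                                          assignment=assignment, F=F,
                                          constrain_group=False).kinv
    perm = np.concatenate([np.arange(ped.n), ped.n + used])
    acc = mf_fixed.Ainv[perm][:, perm]
    matrix_dev = np.abs((acc - astar)).max()
    return {
        "n_animals": ped.n,
        "max_dev_zero_limit_sd": float(np.abs(u_fixed - u_upg).max() / sd),
        "max_dev_prior_vs_blup_sd": float(np.abs(u_prior - u_blup).max() / sd),
        "max_dev_prior_vs_upg_sd": float(np.abs(u_prior - u_upg).max() / sd),
        "matrix_dev": float(matrix_dev),
    }


def qp_explicit_equivalence(seed: int, scale: float = 0.03) -> dict:
    """QP-transformed UPG solutions versus explicit group covariates."""
    data, ped, assignment, phen, traits, vc = _small_population(
        seed, scale, n_base=12)
    F = compute_inbreeding(ped)
    rel_upg = assemble_relationship_inverse("BLUP_UPG", ped,
                                            assignment=assignment, F=F)
    spec = ModelSpec(traits=traits, varcomps=vc, variant="BLUP_UPG")
    sol_qp = solve_mme(build_mme(phen, ped, spec, rel_upg))
    total_qp = total_genetic_value(sol_qp, "t")

    # explicit formulation: same kept groups as fixed per-record covariates
    Q = rel_upg.Q
    phen2 = phen.copy()
    qcols = []
    an = phen2["animal"].to_numpy()
    for j, lab in enumerate(rel_upg.group_labels):
        col = f"q_{lab}"
        phen2[col] = Q[an, j]
        qcols.append(col)
    traits2 = [TraitModel(name="t", cg="cg_t", factors=[],
                          covariates=traits[0].covariates + qcols)]
    spec2 = ModelSpec(traits=traits2, varcomps=vc, variant="BLUP")
    rel_plain = assemble_relationship_inverse("BLUP", ped, F=F)
    sol_ex = solve_mme(build_mme(phen2, ped, spec2, rel_plain))
    g_ex = np.array([sol_ex.fixed.get(f"t:q_{lab}", 0.0)
                     for lab in rel_upg.group_labels])
    total_ex = total_genetic_value(sol_ex, "t", Q=Q, group_solutions=g_ex)
    g_qp = sol_qp.u[ped.n:, 0]
    return {"n_animals": ped.n,
            "max_dev_gebv": float(np.abs(total_qp - total_ex).max()),
            "max_dev_groups": float(np.abs(g_qp - g_ex).max())}


# ---------------------------------------------------------------------------
# Gamma recovery
# ---------------------------------------------------------------------------

def gamma_recovery(seed: int, n_markers: int = 5000,
                   n_per_breed: int = 110) -> dict:
    """Recover the true Gamma from purebred genotyped founders.

    Unrelated purebred base animals are genotyped; base frequencies are
    estimated by GLS on the breed fractions (identity weights: the animals
    are unrelated) and Gamma as 8x the across-marker covariance.
    """
    rng = np.random.default_rng(seed)
    freqs, true_gamma = sample_base_frequencies(
        n_markers, (0.20, 0.10, 0.08, 0.12), rng)
    n = 4 * n_per_breed
    sire = np.full(n, -1, dtype=np.int64)
    ped = Pedigree(sire, sire.copy(),
                   breed_comp=np.kron(np.eye(4), np.ones((n_per_breed, 1))))
    geno = gene_drop(ped, freqs, rng)
    est = gls_base_frequencies(geno.astype(float), ped.breed_comp,
                               A22=None, labels=["N", "A", "B", "C"])
    ghat = estimate_gamma(est).values
    gtrue = true_gamma.values
    diag_rel = np.abs(np.diag(ghat) - np.diag(gtrue)) / np.diag(gtrue)
    off = np.triu_indices(4, k=1)
    off_abs = np.abs(ghat[off] - gtrue[off])
    return {"n_genotyped": n, "n_markers": n_markers,
            "max_diag_rel_err": float(diag_rel.max()),
            "max_offdiag_abs_err": float(off_abs.max()),
            "gamma_diag_mean": float(np.diag(ghat).mean()),
            "true_diag_mean": float(np.diag(gtrue).mean())}


# ---------------------------------------------------------------------------
# LR calibration and the bias comparison
# ---------------------------------------------------------------------------

def _study_config(seed: int, homogeneous: bool, scale: float = 0.85,
                  n_markers: int = 2000) -> RunConfig:
    """Study-scale single-trait configuration (~3,000 animals).

    ``homogeneous=True`` gives the correctly-specified setting (near-zero
    breed divergence, no breed means); otherwise the composite base is
    heterogeneous: divergent breeds plus configured base-breed trait means
    spanning two genetic standard deviations.
    """
    sd = np.sqrt(0.3)
    if homogeneous:
        div = (0.02, 0.02, 0.02, 0.02)
        means = (0.0, 0.0, 0.0, 0.0)
    else:
        div = (0.20, 0.10, 0.08, 0.12)
        means = (1.0 * sd, sd / 3.0, -sd / 3.0, -1.0 * sd)
    tp = TraitParams(traits=[TraitDef("t", 0.3, 0.7, cg_scheme="fy",
                                      breed_means=means)])
    return RunConfig(
        sim=SimConfig(n_markers=n_markers, n_base_per_breed=150,
                      mating_plan=default_mating_plan(scale=scale),
                      divergence=div, trait_params=tp, seed=seed),
        variants=("ssGBLUP",), fit_breed_fractions=not homogeneous)


def lr_calibration(seed: int, n_reps: int = 10) -> dict:
    """LR-method calibration of a correctly specified ssGBLUP.

    Ten replicates of a ~3,000-animal near-homogeneous-base population;
    reports the mean dispersion slope, mean bias in genetic SD, and the gap
    between the LR accuracy and the empirical cor(GEBV_r, true BV) of the
    validation cohort.
    """
    rng = np.random.default_rng(seed)
    b1s, biases, accs, emps = [], [], [], []
    for _ in range(n_reps):
        cfg = _study_config(int(rng.integers(2 ** 31 - 1)), homogeneous=True)
        res = run_evaluation(cfg)
        lr = res.variants["ssGBLUP"].lr["t"]
        val = res.split.validation_ids
        ur = res.variants["ssGBLUP"].gebv_reduced["t"][val]
        tb = res.data.state.true_bv[val, 0]
        b1s.append(lr.slope)
        biases.append(lr.bias / np.sqrt(0.3))
        accs.append(lr.accuracy)
        emps.append(float(np.corrcoef(ur, tb)[0, 1]))
    return {"n_reps": n_reps,
            "mean_b1": float(np.mean(b1s)),
            "mean_bias_sd": float(np.mean(biases)),
            "mean_lr_accuracy": float(np.mean(accs)),
            "mean_empirical_accuracy": float(np.mean(emps)),
            "accuracy_gap": float(abs(np.mean(accs) - np.mean(emps)))}


def bias_comparison(seed: int, n_reps: int = 10) -> dict:
    """Plain ssGBLUP (base-ignorant) versus ssGBLUP_MF on the same data.

    Heterogeneous composite base (divergent breeds, breed trait means
    spanning 2 genetic SD); per replicate the two models run on identical
    data and the LR dispersion and bias are compared pairwise; one-sided
    sign tests ask whether the metafounder model is closer to b1 = 1 and
    bias = 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        cfg = _study_config(int(rng.integers(2 ** 31 - 1)),
                            homogeneous=False)
        cfg.variants = ("ssGBLUP", "ssGBLUP_MF")
        cfg.fit_breed_fractions = False
        res = run_evaluation(cfg)
        p = res.variants["ssGBLUP"].lr["t"]
        m = res.variants["ssGBLUP_MF"].lr["t"]
        rows.append({"plain_b1": p.slope, "mf_b1": m.slope,
                     "plain_bias": p.bias, "mf_bias": m.bias})
    df = pd.DataFrame(rows)
    wins_b1 = int((abs(df.mf_b1 - 1) < abs(df.plain_b1 - 1)).sum())
    wins_bias = int((abs(df.mf_bias) < abs(df.plain_bias)).sum())
    p_b1 = binomtest(wins_b1, n_reps, 0.5, alternative="greater").pvalue
    p_bias = binomtest(wins_bias, n_reps, 0.5, alternative="greater").pvalue
    sd = np.sqrt(0.3)
    return {"n_reps": n_reps, "wins_b1": wins_b1, "wins_bias": wins_bias,
            "sign_p_b1": float(p_b1), "sign_p_bias": float(p_bias),
            "mean_abs_b1_dev_plain": float(abs(df.plain_b1 - 1).mean()),
            "mean_abs_b1_dev_mf": float(abs(df.mf_b1 - 1).mean()),
            "mean_abs_bias_sd_plain": float(abs(df.plain_bias).mean() / sd),
            "mean_abs_bias_sd_mf": float(abs(df.mf_bias).mean() / sd)}


# ---------------------------------------------------------------------------
# base-compatibility diagnostics
# ---------------------------------------------------------------------------

def base_compatibility(seed: int, scale: float = 0.3,
                       n_markers: int = 1500) -> dict:
    """Table-3-style diagnostics on simulated multibreed data.

    Builds raw G (observed-frequency centring) and G05 (0.5 centring) for
    the genotyped animals together with A22 and the metafounder-modified
    A22(Gamma), and reports the diagonal-element correlations and means.
    """
    from .pedigree import build_A22
    from .simdata import simulate
    tp = TraitParams(traits=[TraitDef("t", 0.3, 0.7, cg_scheme="fy")])
    cfg = SimConfig(n_markers=n_markers, n_base_per_breed=80,
                    mating_plan=default_mating_plan(scale=scale),
                    trait_params=tp, genotype_founder_fraction=0.3,
                    seed=seed)
    data = simulate(cfg)
    ped = data.ped
    comps = propagate_breed_composition(ped)
    definition = GroupDefinition("GG4")
    assignment = assign_groups(ped, comps, definition)
    markers, _ = qc_markers(data.markers)
    genotyped = data.genotyped
    A22 = build_A22(ped, genotyped)
    est = gls_base_frequencies(markers.geno.astype(float),
                               ped.breed_comp[genotyped], A22,
                               labels=["N", "A", "B", "C"])
    gamma = estimate_gamma(est)
    mf = build_Agamma(ped, gamma, assignment.sire_group, assignment.dam_group)
    A22g = mf.A22(genotyped)
    G = build_G(markers, alpha=1.0).values
    G05 = build_G05(markers, alpha=1.0).values
    summary = matrix_summary(
        {"G": G, "A22": A22, "G05": G05, "A22G": A22g},
        pairs=[("G", "A22"), ("G05", "A22G")])
    d = summary.set_index(["matrix", "part"])
    return {
        "diag_corr_plain": float(d.loc[("G~A22", "diagonal"), "correlation"]),
        "diag_corr_mf": float(d.loc[("G05~A22G", "diagonal"), "correlation"]),
        "mean_diag_G": float(d.loc[("G", "diagonal"), "mean"]),
        "mean_diag_G05": float(d.loc[("G05", "diagonal"), "mean"]),
        "mean_diag_A22": float(d.loc[("A22", "diagonal"), "mean"]),
        "mean_diag_A22G": float(d.loc[("A22G", "diagonal"), "mean"]),
        "mean_off_G": float(d.loc[("G", "offdiagonal"), "mean"]),
        "mean_off_G05": float(d.loc[("G05", "offdiagonal"), "mean"]),
        "mean_off_A22": float(d.loc[("A22", "offdiagonal"), "mean"]),
        "mean_off_A22G": float(d.loc[("A22G", "offdiagonal"), "mean"]),
    }


# ---------------------------------------------------------------------------
# filter fixtures
# ---------------------------------------------------------------------------

def qc_fixture() -> MarkerMatrix:
    """Ten-marker genotype fixture with one planted violation per rule.

    Markers: 0 = sex chromosome, 1 = low call rate, 2 = low MAF,
    3 = all-heterozygous (HWE deviation), 4-9 clean; six markers survive.
    """
    rng = np.random.default_rng(42)
    n = 40
    geno = rng.binomial(2, 0.5, size=(n, 10)).astype(np.int8)
    chrom = np.full(10, AUTOSOME)
    chrom[0] = SEX
    geno[: n // 2, 1] = 5                      # call rate 0.5 < 0.9
    geno[:, 2] = 0
    geno[0, 2] = 1                             # p = 1/80 < 0.05
    geno[:, 3] = 1                             # all heterozygous at p = 0.5
    for j in (4, 5, 6, 7, 8, 9):               # keep clean markers legal
        col = geno[:, j]
        if np.minimum(col.mean() / 2, 1 - col.mean() / 2) < 0.1:
            geno[:, j] = rng.binomial(2, 0.5, size=n)
    return MarkerMatrix(geno, np.arange(n), chrom_class=chrom)


def edit_fixture() -> pd.DataFrame:
    """Phenotype fixture: one planted outlier in a 20-record group and one
    4-record contemporary group among healthy groups."""
    rng = np.random.default_rng(7)
    rows = []
    an = 0
    base = rng.normal(0.0, 1.0, size=19)
    for v in base:                      # CG 0: 20 records, one outlier
        rows.append({"animal": an, "y_t": v, "cg_t": 0}); an += 1
    rows.append({"animal": an, "y_t": 10.0, "cg_t": 0}); an += 1
    for v in rng.normal(0.0, 1.0, 4):   # CG 1: too small
        rows.append({"animal": an, "y_t": v, "cg_t": 1}); an += 1
    for cg in (2, 3):
        for v in rng.normal(0.0, 1.0, 8):
            rows.append({"animal": an, "y_t": v, "cg_t": cg}); an += 1
    return pd.DataFrame(rows)


def filter_fixtures() -> dict:
    """Run both planted-violation fixtures and report the removal counts."""
    markers, report = qc_markers(qc_fixture())
    phen = edit_fixture()
    edited, ereport = edit_phenotypes(phen, ["t"])
    er = ereport.iloc[0]
    return {"qc_in": report.n_in, "qc_out": report.n_out,
            "qc_removed_position": report.removed_position,
            "qc_removed_call_rate": report.removed_call_rate,
            "qc_removed_maf": report.removed_maf,
            "qc_removed_hwe": report.removed_hwe,
            "edit_in": int(er.records_in),
            "edit_removed_outlier": int(er.removed_outlier),
            "edit_removed_small_cg": int(er.removed_small_cg),
            "edit_out": int(er.records_out)}


# ---------------------------------------------------------------------------
# solver contract
# ---------------------------------------------------------------------------

def solver_contract(seed: int, scale: float = 0.107) -> dict:
    """Direct vs preconditioned-CG agreement on all seven variants.

    A ~500-animal two-trait population (one maternal trait with permanent
    environment); every system is solved by sparse LU and by PCG and the
    worst relative residual and GEBV disagreement are reported.
    """
    tp = TraitParams(traits=[
        TraitDef("t1", 0.25, 0.75, cg_scheme="fy"),
        TraitDef("t2", 0.23, 0.62, var_maternal=0.10,
                 cov_direct_maternal=-0.3 * np.sqrt(0.023),
                 var_pe=0.05, het_maternal=0.1),
    ])
    cfg = RunConfig(
        sim=SimConfig(n_markers=400, n_base_per_breed=50,
                      mating_plan=default_mating_plan(scale=scale),
                      genotype_founder_fraction=0.3,
                      trait_params=tp, seed=seed),
        variants=("BLUP", "BLUP_UPG", "BLUP_MF", "ssGBLUP", "ssGBLUP_UPG",
                  "ssGBLUP_UPGA", "ssGBLUP_MF"))
    res_d = run_evaluation(cfg)
    import copy
    cfg2 = copy.deepcopy(cfg)
    cfg2.solver = "pcg"
    res_p = run_evaluation(cfg2, data=res_d.data)
    worst_resid = 0.0
    worst_diff = 0.0
    for v in cfg.variants:
        for which, res in (("direct", res_d), ("pcg", res_p)):
            st = res.variants[v].solver_stats
            worst_resid = max(worst_resid, st["residual_complete"],
                              st["residual_reduced"])
        for key in res_d.variants[v].gebv_complete:
            diff = np.abs(res_d.variants[v].gebv_complete[key]
                          - res_p.variants[v].gebv_complete[key]).max()
            worst_diff = max(worst_diff, float(diff))
    return {"n_animals": res_d.data.ped.n,
            "max_relative_residual": float(worst_resid),
            "max_solver_disagreement": float(worst_diff)}
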