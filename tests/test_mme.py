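"""Mixed-model equations: editing, assembly, solving, breeding values."""

import numpy as np
import pandas as pd
import pytest

from mfblup.experiments import edit_fixture
from mfblup.groups import GroupDefinition, assign_groups, propagate_breed_composition
from mfblup.mme import (ModelError, ModelSpec, TraitModel, VarComponents,
                        assemble_relationship_inverse, build_mme,
                        edit_phenotypes, solve_mme, total_genetic_value)
from mfblup.pedigree import GammaMatrix, Pedigree, build_A
from mfblup.pipeline import make_trait_models


def _vc(var_u=0.5, var_e=0.5):
    return VarComponents(np.array([[var_u]]), np.zeros((0, 0)),
                         np.array([[var_e]]), ["t"], [])


def _spec(variant="BLUP", covariates=(), var_u=0.5, var_e=0.5):
    return ModelSpec(traits=[TraitModel("t", "cg_t",
                                        covariates=list(covariates))],
                     varcomps=_vc(var_u, var_e), variant=variant)


# --- phenotype editing ------------------------------------------------------

def test_identical_cg_of_five_all_kept():
    phen = pd.DataFrame({"animal": range(5), "y_t": [3.0] * 5,
                         "cg_t": [0] * 5})
    out, report = edit_phenotypes(phen, ["t"])
    assert out["y_t"].notna().sum() == 5
    assert report.iloc[0].removed_outlier == 0


def test_cg_of_four_entirely_removed():
    phen = pd.DataFrame({"animal": range(9),
                         "y_t": list(range(4)) + [1.0] * 5,
                         "cg_t": [0] * 4 + [1] * 5})
    out, report = edit_phenotypes(phen, ["t"])
    assert out.loc[out.cg_t == 0, "y_t"].isna().all()
    assert out.loc[out.cg_t == 1, "y_t"].notna().all()
    assert report.iloc[0].removed_small_cg == 4


def test_planted_outlier_and_small_cg_removed_exactly():
    phen = edit_fixture()
    out, report = edit_phenotypes(phen, ["t"])
    r = report.iloc[0]
    assert (r.removed_outlier, r.removed_small_cg) == (1, 4)
    assert r.records_out == r.records_in - 5
    # the planted outlier (y = 10) is the removed record
    assert out.loc[phen["y_t"] == 10.0, "y_t"].isna().all()


def test_empty_edit_result_raises():
    phen = pd.DataFrame({"animal": [0, 1], "y_t": [1.0, 2.0],
                         "cg_t": [0, 1]})
    with pytest.raises(ModelError):
        edit_phenotypes(phen, ["t"])


# --- assembly oracles -------------------------------------------------------

def _tiny_data(n=6, seed=0, cg=None):
    rng = np.random.default_rng(seed)
    ped = Pedigree(np.array([-1, -1, -1, 0, 0, 3]),
                   np.array([-1, -1, -1, 1, 2, 4]))
    y = rng.normal(size=n)
    phen = pd.DataFrame({"animal": np.arange(n), "y_t": y,
                         "cg_t": cg if cg is not None else [0, 0, 1, 1, 0, 1]})
    return ped, phen


def dense_mme_oracle(ped, phen, var_u, var_e):
    """Independent dense Henderson system for a single-trait animal model."""
    n = ped.n
    cg_levels = np.unique(phen["cg_t"])
    X = np.zeros((len(phen), len(cg_levels)))
    for r, c in enumerate(phen["cg_t"]):
        X[r, np.searchsorted(cg_levels, c)] = 1.0
    Z = np.zeros((len(phen), n))
    Z[np.arange(len(phen)), phen["animal"]] = 1.0
    Ainv = np.linalg.inv(build_A(ped))
    lam = var_e / var_u
    lhs = np.block([[X.T @ X, X.T @ Z],
                    [Z.T @ X, Z.T @ Z + lam * Ainv]])
    rhs = np.concatenate([X.T @ phen["y_t"], Z.T @ phen["y_t"]])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:len(cg_levels)], sol[len(cg_levels):]


def test_solutions_match_dense_henderson_oracle():
    ped, phen = _tiny_data()
    spec = _spec()
    rel = assemble_relationship_inverse("BLUP", ped)
    sol = solve_mme(build_mme(phen, ped, spec, rel))
    b_o, u_o = dense_mme_oracle(ped, phen, 0.5, 0.5)
    np.testing.assert_allclose(sol.fixed.to_numpy(), b_o, atol=1e-8)
    np.testing.assert_allclose(sol.u[:, 0], u_o, atol=1e-8)


def test_single_record_two_by_two_hand_solve():
    """One founder, one record: the 2x2 system pushes everything into the
    contemporary-group mean and leaves u = 0."""
    ped = Pedigree(np.array([-1]), np.array([-1]))
    phen = pd.DataFrame({"animal": [0], "y_t": [3.7], "cg_t": [0]})
    rel = assemble_relationship_inverse("BLUP", ped)
    sol = solve_mme(build_mme(phen, ped, _spec(), rel))
    assert sol.fixed.iloc[0] == pytest.approx(3.7)
    assert sol.u[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_no_phenotypes_gives_zero_solutions():
    ped, phen = _tiny_data()
    phen["y_t"] = np.nan
    rel = assemble_relationship_inverse("BLUP", ped)
    sol = solve_mme(build_mme(phen, ped, _spec(), rel))
    assert np.all(sol.values == 0.0)


def test_direct_and_pcg_agree():
    ped, phen = _tiny_data()
    rel = assemble_relationship_inverse("BLUP", ped)
    system = build_mme(phen, ped, _spec(), rel)
    xd = solve_mme(system, method="direct").values
    xp = solve_mme(system, method="pcg").values
    np.testing.assert_allclose(xd, xp, atol=1e-8)


# --- relationship assembly --------------------------------------------------

def test_empty_genotyped_set_collapses_to_pedigree_variant(single_trait_sim):
    ped = single_trait_sim.ped
    a = assemble_relationship_inverse("ssGBLUP", ped, genotyped=np.array([]))
    b = assemble_relationship_inverse("BLUP", ped)
    assert (a.kinv - b.kinv).nnz == 0
    assert a.variant == "BLUP"


def test_zero_group_usage_upg_equals_ssgblup(single_trait_sim):
    """When no unknown-parent slot carries a group the UPG single-step
    variant is identical to plain ssGBLUP (Q = 0 collapse)."""
    data = single_trait_sim
    ped = data.ped_true
    from mfblup.genomic import MarkerMatrix, build_G
    from mfblup.groups import GroupAssignment
    from mfblup.pedigree import build_A22
    geno = data.markers.geno.astype(float)
    A22 = build_A22(ped, data.genotyped)
    G = build_G(MarkerMatrix(geno, data.genotyped), alpha=0.95, A22=A22)
    empty = GroupAssignment(GroupDefinition("GG4"),
                            np.full(ped.n, -1), np.full(ped.n, -1))
    # treat founders' unknown parents as truly unrelated base animals
    complete = Pedigree(np.where(ped.is_founder, -1, ped.sire),
                        np.where(ped.is_founder, -1, ped.dam))
    a = assemble_relationship_inverse("ssGBLUP_UPG", complete,
                                      assignment=empty,
                                      genotyped=data.genotyped,
                                      G=G.values)
    b = assemble_relationship_inverse("ssGBLUP", complete,
                                      genotyped=data.genotyped, G=G.values)
    assert abs(a.kinv - b.kinv).max() < 1e-12


def test_assembled_matrices_symmetric(single_trait_sim):
    data = single_trait_sim
    ped = data.ped
    comps = propagate_breed_composition(ped)
    assignment = assign_groups(ped, comps, GroupDefinition("GG4"))
    from mfblup.genomic import MarkerMatrix, build_G
    from mfblup.pedigree import build_A22
    geno = data.markers.geno.astype(float)
    A22 = build_A22(ped, data.genotyped)
    G = build_G(MarkerMatrix(geno, data.genotyped), alpha=0.95, A22=A22)
    for variant in ("ssGBLUP", "ssGBLUP_UPG", "ssGBLUP_UPGA"):
        rel = assemble_relationship_inverse(
            variant, ped, assignment=assignment,
            genotyped=data.genotyped, G=G.values)
        dev = abs(rel.kinv - rel.kinv.T).max()
        assert dev < 1e-10, variant


def test_mf_variant_with_tiny_gamma_matches_ssgblup(single_trait_sim):
    """ssGBLUP_MF with Gamma = eps I and G in place of G05 reproduces plain
    ssGBLUP solutions (the metafounder block carries no information)."""
    data = single_trait_sim
    ped = data.ped
    comps = propagate_breed_composition(ped)
    assignment = assign_groups(ped, comps, GroupDefinition("GG4"))
    from mfblup.genomic import MarkerMatrix, build_G
    from mfblup.pedigree import build_A22
    geno = data.markers.geno.astype(float)
    A22 = build_A22(ped, data.genotyped)
    G = build_G(MarkerMatrix(geno, data.genotyped), alpha=0.95, A22=A22)
    phen, _ = edit_phenotypes(data.phenotypes, ["t"], min_cg=2)
    tp = data.config.trait_params
    traits = make_trait_models(tp, include_breed_fracs=False)
    vc = tp.varcomponents()
    gamma = GammaMatrix(1e-8 * np.eye(4), labels=["N", "A", "B", "C"])
    sols = {}
    for variant, kw in (
        ("ssGBLUP", {}),
        ("ssGBLUP_MF", {"assignment": assignment, "gamma": gamma}),
    ):
        rel = assemble_relationship_inverse(variant, ped,
                                            genotyped=data.genotyped,
                                            G=G.values, **kw)
        spec = ModelSpec(traits=traits, varcomps=vc, variant=variant)
        sol = solve_mme(build_mme(phen, ped, spec, rel))
        sols[variant] = total_genetic_value(sol, "t")
    np.testing.assert_allclose(sols["ssGBLUP_MF"], sols["ssGBLUP"],
                               atol=1e-4)


# --- multi-trait structure --------------------------------------------------

def test_uncorrelated_bivariate_equals_two_univariate_solves():
    rng = np.random.default_rng(8)
    ped = Pedigree(np.array([-1, -1, -1, 0, 0, 3]),
                   np.array([-1, -1, -1, 1, 2, 4]))
    phen = pd.DataFrame({
        "animal": np.arange(6),
        "y_a": rng.normal(size=6), "cg_a": [0, 0, 0, 1, 1, 1],
        "y_b": rng.normal(size=6), "cg_b": [0, 1, 0, 1, 0, 1]})
    phen.loc[2, "y_b"] = np.nan    # one missing record
    vc2 = VarComponents(np.diag([0.4, 0.3]), np.zeros((0, 0)),
                        np.diag([0.6, 0.7]), ["a", "b"], [])
    spec2 = ModelSpec(traits=[TraitModel("a", "cg_a"),
                              TraitModel("b", "cg_b")],
                      varcomps=vc2, variant="BLUP")
    rel = assemble_relationship_inverse("BLUP", ped)
    sol2 = solve_mme(build_mme(phen, ped, spec2, rel))
    for name, vu, ve in (("a", 0.4, 0.6), ("b", 0.3, 0.7)):
        vc1 = VarComponents(np.array([[vu]]), np.zeros((0, 0)),
                            np.array([[ve]]), [name], [])
        spec1 = ModelSpec(traits=[TraitModel(name, f"cg_{name}")],
                          varcomps=vc1, variant="BLUP")
        sol1 = solve_mme(build_mme(phen, ped, spec1, rel))
        np.testing.assert_allclose(
            total_genetic_value(sol2, name),
            total_genetic_value(sol1, name), atol=1e-8)


def test_maternal_link_zeroed_and_counted_for_unknown_dam():
    ped = Pedigree(np.array([-1, -1, 0]), np.array([-1, -1, -1]))
    phen = pd.DataFrame({"animal": [2, 1], "y_t": [1.0, 2.0],
                         "cg_t": [0, 0]})
    vc = VarComponents(np.array([[0.4, 0.0], [0.0, 0.2]]),
                       np.array([[0.1]]), np.array([[0.6]]), ["t"], ["t"])
    spec = ModelSpec(traits=[TraitModel("t", "cg_t", maternal=True,
                                        pe=True)],
                     varcomps=vc, variant="BLUP")
    rel = assemble_relationship_inverse("BLUP", ped)
    system = build_mme(phen, ped, spec, rel)
    assert system.dropped_maternal_links == 2   # both records lack dams
    sol = solve_mme(system)
    assert np.allclose(sol.u[:, 1], 0.0)        # maternal effects get no data


def test_total_genetic_value_explicit_combination():
    ped, phen = _tiny_data()
    rel = assemble_relationship_inverse("BLUP", ped)
    sol = solve_mme(build_mme(phen, ped, _spec(), rel))
    u = total_genetic_value(sol, "t")
    Q = np.ones((6, 1))
    g = np.array([2.0])
    np.testing.assert_allclose(
        total_genetic_value(sol, "t", Q=Q, group_solutions=g), u + 2.0)
    with pytest.raises(ModelError):
        total_genetic_value(sol, "t", Q=Q)
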