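"""Synthetic-population generator: drift model, gene drop, traits, masking."""

import numpy as np
import pandas as pd
import pytest

from mfblup.pedigree import compute_inbreeding
from mfblup.simdata import (MatingRule, SimConfig, SimulationError, TraitDef,
                            TraitParams, default_mating_plan, gene_drop,
                            mask_parents, sample_base_frequencies,
                            simulate, simulate_breeding_values,
                            simulate_pedigree, simulate_traits)


# --- base frequencies -------------------------------------------------------

def test_no_drift_limit_gives_near_rank_one_gamma(rng):
    freqs, gamma = sample_base_frequencies(4000, (1e-6,) * 4, rng)
    g = gamma.values
    # all breeds track the ancestral frequency: every entry ~ 8 Var(p0)
    target = 8.0 * np.var(freqs.mean(axis=1))
    np.testing.assert_allclose(g, target, rtol=0.05)


def test_shared_frequency_column_gives_constant_gamma():
    from mfblup.pedigree import GammaMatrix
    p = np.random.default_rng(0).uniform(0.1, 0.9, 200)
    g = GammaMatrix(8.0 * np.cov(np.column_stack([p, p, p, p]),
                                 rowvar=False))
    assert np.allclose(g.values, g.values[0, 0])


def test_degenerate_drift_rejected(rng):
    with pytest.raises(SimulationError):
        sample_base_frequencies(10, (0.0, 0.1, 0.1, 0.1), rng)
    with pytest.raises(SimulationError):
        sample_base_frequencies(10, (1.0, 0.1, 0.1, 0.1), rng)


def test_gamma_diagonal_matches_drift_theory():
    """Balding-Nichols: diag = 8 (Var(p0) + F E[p0 (1-p0)]) with p0 uniform
    on [0.05, 0.95], i.e. Var(p0) = 0.0675 and E[p0 q0] = 0.1825."""
    rng = np.random.default_rng(123)
    F = (0.2, 0.1, 0.1, 0.15)
    freqs, gamma = sample_base_frequencies(5000, F, rng)
    for b, fb in enumerate(F):
        target = 8.0 * (0.0675 + fb * 0.1825)
        assert gamma.values[b, b] == pytest.approx(target, rel=0.15)
    # determinism: same seed reproduces bit-identically
    rng2 = np.random.default_rng(123)
    freqs2, gamma2 = sample_base_frequencies(5000, F, rng2)
    assert np.array_equal(freqs, freqs2)
    assert np.array_equal(gamma.values, gamma2.values)


# --- pedigree ---------------------------------------------------------------

def test_offspring_composition_is_parent_average(rng):
    cfg = SimConfig(n_base_per_breed=10, mating_plan=[
        MatingRule("NA", "N", "A", 8), MatingRule("BC", "B", "C", 8),
        MatingRule("NABC", "NA", "BC", 8)])
    ped = simulate_pedigree(cfg, rng)
    na = ped.pool == "NA"
    np.testing.assert_allclose(ped.breed_comp[na],
                               np.tile([0.5, 0.5, 0, 0], (na.sum(), 1)))
    nabc = ped.pool == "NABC"
    np.testing.assert_allclose(ped.breed_comp[nabc], 0.25, atol=1e-12)
    # composites of >= 3 breeds in the final generation
    assert np.all((ped.breed_comp[nabc] > 0).sum(axis=1) >= 3)


def test_pedigree_size_equals_founders_plus_rule_counts(rng):
    plan = [MatingRule("NA", "N", "A", 13), MatingRule("NB", "N", "B", 7),
            MatingRule("X", "NA", "NB", 9)]
    cfg = SimConfig(n_base_per_breed=12, mating_plan=plan)
    ped = simulate_pedigree(cfg, rng)
    assert ped.n == 4 * 12 + 13 + 7 + 9
    # topological order and birth periods
    idx = np.arange(ped.n)
    assert np.all(ped.sire < idx) and np.all(ped.dam < idx)
    assert np.all(np.diff(ped.birth_gen) >= 0)


def test_undefined_pool_rejected(rng):
    cfg = SimConfig(mating_plan=[MatingRule("X", "N", "NOPE", 5)])
    with pytest.raises(SimulationError, match="undefined"):
        simulate_pedigree(cfg, rng)


# --- gene drop --------------------------------------------------------------

def test_fixed_marker_fixed_in_everyone(rng):
    cfg = SimConfig(n_base_per_breed=6,
                    mating_plan=[MatingRule("NA", "N", "A", 10)])
    ped = simulate_pedigree(cfg, rng)
    geno = gene_drop(ped, np.ones((5, 4)), rng)
    assert np.all(geno == 2)


def test_gene_drop_requires_purebred_founders(rng):
    from mfblup.pedigree import Pedigree
    ped = Pedigree(np.array([-1]), np.array([-1]),
                   breed_comp=np.array([[0.5, 0.5, 0, 0]]))
    with pytest.raises(SimulationError, match="purebred"):
        gene_drop(ped, np.full((3, 4), 0.5), rng)


def test_gene_drop_deterministic_and_mendelian(rng):
    cfg = SimConfig(n_base_per_breed=6,
                    mating_plan=[MatingRule("NA", "N", "A", 12)], seed=4)
    ped = simulate_pedigree(cfg, np.random.default_rng(4))
    freqs, _ = sample_base_frequencies(50, (0.2, 0.1, 0.1, 0.1),
                                       np.random.default_rng(5))
    g1 = gene_drop(ped, freqs, np.random.default_rng(6))
    g2 = gene_drop(ped, freqs, np.random.default_rng(6))
    assert np.array_equal(g1, g2)


def test_trio_offspring_frequency_matches_mid_parent():
    """Monte-Carlo oracle: repeated drops of one trio give offspring
    allele frequency = mid-parent gene content / 2 within binomial error."""
    from mfblup.pedigree import Pedigree
    rng = np.random.default_rng(11)
    ped = Pedigree(np.array([-1, -1, 0]), np.array([-1, -1, 1]),
                   breed_comp=np.array([[1, 0, 0, 0], [0, 1, 0, 0],
                                        [0.5, 0.5, 0, 0]]))
    n_rep = 10_000
    freqs = np.array([[0.9, 0.2, 0.5, 0.5]])   # one marker, breeds N and A
    counts = np.zeros(n_rep)
    for r in range(n_rep):
        g = gene_drop(ped, freqs, rng)
        counts[r] = g[2, 0]
    parents_expected = 2 * (0.9 + 0.2) / 2
    se = np.sqrt(2 * 0.55 * 0.45 / n_rep) * 4   # generous binomial bound
    assert counts.mean() == pytest.approx(parents_expected, abs=se + 0.05)


# --- traits -----------------------------------------------------------------

def _poly_params(**kw):
    defaults = dict(traits=[TraitDef("t", 0.25, 0.75, cg_scheme="fy")],
                    marker_fraction=0.0)
    defaults.update(kw)
    return TraitParams(**defaults)


def test_founder_bv_variance_matches_sigma2u():
    rng = np.random.default_rng(21)
    from mfblup.pedigree import Pedigree
    n = 2000
    ped = Pedigree(np.full(n, -1), np.full(n, -1))
    u = simulate_breeding_values(ped, _poly_params(), rng)
    assert u[:, 0].var() == pytest.approx(0.25, rel=0.10)


def test_parent_offspring_regression_recovers_heritability():
    """Classical oracle: offspring phenotype on mid-parent phenotype has
    slope h^2 (here 0.25) for a purely additive trait."""
    rng = np.random.default_rng(22)
    from mfblup.pedigree import Pedigree
    n_fam = 10_000
    sire = np.concatenate([np.full(2 * n_fam, -1),
                           np.arange(0, 2 * n_fam, 2)])
    dam = np.concatenate([np.full(2 * n_fam, -1),
                          np.arange(1, 2 * n_fam, 2)])
    ped = Pedigree(sire, dam)
    params = _poly_params()
    u = simulate_breeding_values(ped, params, rng)
    y = u[:, 0] + rng.normal(0, np.sqrt(0.75), ped.n)
    mid = 0.5 * (y[0:2 * n_fam:2] + y[1:2 * n_fam:2])
    off = y[2 * n_fam:]
    slope = np.cov(off, mid)[0, 1] / np.var(mid, ddof=1)
    assert slope == pytest.approx(0.25, abs=0.03)


def test_residual_only_trait_has_residual_variance_within_cg():
    rng = np.random.default_rng(23)
    cfg = SimConfig(n_base_per_breed=40,
                    mating_plan=[MatingRule("NA", "N", "A", 800)],
                    trait_params=TraitParams(
                        traits=[TraitDef("t", 1e-8, 1.0, cg_scheme="fy")],
                        marker_fraction=0.0),
                    n_farms=2, cg_sd=0.5)
    ped = simulate_pedigree(cfg, rng)
    phen, _ = simulate_traits(ped, cfg.trait_params, rng, n_farms=2,
                              cg_sd=0.5)
    within = phen.groupby("cg_t")["y_t"].var(ddof=1)
    sizes = phen.groupby("cg_t")["y_t"].size()
    pooled = np.average(within[sizes > 30], weights=sizes[sizes > 30] - 1)
    assert pooled == pytest.approx(1.0, rel=0.15)


def test_cg_means_equal_effects_plus_genetic_means():
    rng = np.random.default_rng(24)
    cfg = SimConfig(n_base_per_breed=50,
                    mating_plan=[MatingRule("NA", "N", "A", 1500)],
                    trait_params=_poly_params(), n_farms=2, cg_sd=1.0)
    ped = simulate_pedigree(cfg, rng)
    phen, u = simulate_traits(ped, cfg.trait_params, rng, n_farms=2,
                              cg_sd=1.0)
    eff = phen.attrs["cg_effects"]["t"]
    from mfblup.groups import HET_COLUMNS
    het_beta = np.asarray(cfg.trait_params.traits[0].het_direct)
    resid = []
    for cg, grp in phen.groupby("cg_t"):
        if len(grp) < 100:
            continue
        gmean = u[grp["animal"].to_numpy(), 0].mean()
        het = grp[list(HET_COLUMNS)].to_numpy() @ het_beta
        resid.append(grp["y_t"].mean() - eff[cg] - gmean - het.mean())
    assert np.abs(np.mean(resid)) < 0.1


def test_male_only_trait_recorded_for_males_only(small_sim):
    phen = small_sim.phenotypes
    females = phen["sex"] == 2
    assert phen.loc[females, "y_sc"].isna().all()
    assert phen.loc[~females, "y_sc"].notna().any()


def test_maternal_trait_uses_dams_maternal_bv(small_sim):
    """Phenotype decomposition: y - (direct BV + dam maternal BV) has no
    residual correlation with the dam's maternal BV."""
    phen = small_sim.phenotypes
    u = small_sim.state.true_bv
    labels = small_sim.state.effect_labels
    mi = labels.index("ww_mat")
    ped = small_sim.ped_true
    an = phen["animal"].to_numpy()
    dams = ped.dam[an]
    ok = (dams >= 0) & phen["y_ww"].notna().to_numpy()
    resid = (phen.loc[ok, "y_ww"].to_numpy()
             - u[an[ok], labels.index("ww_dir")]
             - u[dams[ok], mi])
    r = np.corrcoef(resid, u[dams[ok], mi])[0, 1]
    assert abs(r) < 0.25


# --- masking and reproducibility -------------------------------------------

def test_masking_probability_zero_is_identity(small_sim, rng):
    ped = small_sim.ped_true
    masked, truth = mask_parents(ped, 0.0, 0.0, rng)
    assert np.array_equal(masked.sire, ped.sire)
    assert np.array_equal(masked.dam, ped.dam)
    assert truth["masked_sire"].size == 0


def test_masked_count_within_binomial_interval(small_sim):
    ped = small_sim.ped_true
    rng = np.random.default_rng(31)
    masked, truth = mask_parents(ped, 0.3, 0.3, rng)
    n = int((~ped.is_founder).sum())
    k = truth["masked_sire"].size
    half = 2.58 * np.sqrt(n * 0.3 * 0.7)
    assert abs(k - 0.3 * n) < half
    # truth map restores the original parents
    np.testing.assert_array_equal(truth["true_sire"], ped.sire)


def test_simulate_is_bit_reproducible(small_config_factory):
    a = simulate(small_config_factory(seed=55))
    b = simulate(small_config_factory(seed=55))
    assert np.array_equal(a.gene_content, b.gene_content)
    assert np.array_equal(a.ped.sire, b.ped.sire)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    assert np.array_equal(a.state.true_bv, b.state.true_bv)


def test_invalid_masking_probability_rejected():
    with pytest.raises(SimulationError):
        SimConfig(mask_sire_prob=1.5)
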