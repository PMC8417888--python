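"""Configuration-driven orchestration of the full evaluation.

``run_evaluation`` simulates (or accepts) a composite population, edits the
data, assigns unknown-parent groups, estimates Gamma, runs the requested
model variants on the complete and reduced datasets, and emits the LR
validation report plus cross-model (G)EBV correlations.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, is_dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gamma import (estimate_gamma, gls_base_frequencies,
                    map_gamma_to_groups, scale_variance_components)
from .genomic import (MarkerMatrix, build_G, build_G05,
                      impute_missing_within_matrix, qc_markers)
from .groups import (HET_COLUMNS, GroupDefinition, assign_groups,
                     heterosis_covariates, propagate_breed_composition)
from .mme import (ModelSpec, TraitModel, VARIANTS, assemble_relationship_inverse,
                  build_mme, edit_phenotypes, solve_mme, total_genetic_value)
from .pedigree import GammaMatrix, Pedigree, build_A22, build_Agamma, compute_inbreeding
from .simdata import SimConfig, SimulatedData, simulate
from .validation import LRStatistics, ValidationSplit, lr_statistics, make_split, model_correlations


@dataclass
class RunConfig:
    """One evaluation run: simulation conditions plus analysis choices."""

    sim: SimConfig = field(default_factory=SimConfig)
    variants: tuple = VARIANTS
    group_mode: str = "GG4"
    alpha: float = 0.95
    gamma_centering: str = "mean"
    scale_mf_variances: bool = True
    constrain_group: bool = True
    #: stabilizing ridge on unknown-parent-group equations (UPGs fitted as
    #: random with prior variance sigma_u^2 / group_ridge)
    group_ridge: float = 1e-4
    solver: str = "direct"
    validate_maternal: bool = True
    #: fit breed-fraction covariates in variants without UPGs/metafounders
    #: (the current-practice model); disable to run a base-ignorant model
    fit_breed_fractions: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .simdata import MatingRule, TraitDef, TraitParams
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if isinstance(sim_raw, dict):
            if isinstance(sim_raw.get("mating_plan"), list):
                sim_raw["mating_plan"] = [
                    MatingRule(**r) if isinstance(r, dict) else r
                    for r in sim_raw["mating_plan"]]
            tp = sim_raw.get("trait_params")
            if isinstance(tp, dict):
                tp = dict(tp)
                tp["traits"] = [TraitDef(**t) if isinstance(t, dict) else t
                                for t in tp.get("traits", [])]
                sim_raw["trait_params"] = TraitParams(**tp)
            sim = SimConfig(**sim_raw)
        else:
            sim = sim_raw
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(sim=sim, **raw)


def _config_hash(cfg) -> str:
    def enc(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    payload = json.dumps(asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_trait_models(trait_params, include_breed_fracs: bool) -> list[TraitModel]:
    """Analysis-side fixed-effect layout matching the simulated data.

    Breed-fraction covariates are fitted only in variants without UPGs or
    metafounders (they would be confounded with group effects); three
    fractions are used, the zebu fraction being the reference.
    """
    models = []
    for t in trait_params.traits:
        covs = list(HET_COLUMNS)
        if t.het_maternal or t.maternal:
            covs.append("het_maternal")
        if t.age_coef:
            covs.append("age_dev")
        if include_breed_fracs:
            covs += ["frac_A", "frac_B", "frac_C"]
        models.append(TraitModel(
            name=t.name, cg=f"cg_{t.name}",
            factors=["dam_age"] if t.maternal else [],
            covariates=covs, maternal=t.maternal, pe=t.var_pe > 0))
    return models


def estimate_gamma_for_definition(markers, ped: Pedigree, genotyped,
                                  definition: GroupDefinition,
                                  assignment, A22: np.ndarray,
                                  centering: str = "mean") -> GammaMatrix:
    """Gamma under a group definition, by GLS from genotypes.

    GG4 regresses gene content on the four breed fractions.  GG10 uses the
    ten group-incidence columns directly when every group has genotyped
    support, otherwise falls back to expanding the GG4 estimate through the
    groups' breed-fraction vectors.
    """
    from .pedigree import build_Q
    geno = markers.geno.astype(float)
    comp = ped.breed_comp[genotyped]
    g4 = estimate_gamma(
        gls_base_frequencies(geno, comp, A22, labels=["N", "A", "B", "C"]),
        centering=centering)
    if definition.mode == "GG4":
        return g4
    Q10 = build_Q(ped, assignment.sire_group, assignment.dam_group,
                  definition.n_groups, labels=definition.labels).values
    Q10g = Q10[genotyped]
    if np.all((Q10g > 1e-8).any(axis=0)):
        est = gls_base_frequencies(geno, Q10g, A22,
                                   labels=definition.labels)
        if not est.dropped:
            return estimate_gamma(est, centering=centering)
    return map_gamma_to_groups(g4, definition.fraction_vectors(),
                               definition.labels)


@dataclass
class VariantResult:
    variant: str
    gebv_complete: dict
    gebv_reduced: dict
    lr: dict                      # trait -> LRStatistics
    group_solutions: pd.DataFrame | None
    solver_stats: dict


@dataclass
class RunResult:
    config: RunConfig
    report: pd.DataFrame
    correlations: dict            # trait -> long-format correlation table
    variants: dict                # name -> VariantResult
    gamma: GammaMatrix | None
    split: ValidationSplit
    data: SimulatedData
    edit_report: pd.DataFrame
    qc_report: pd.DataFrame
    manifest: dict


def run_evaluation(config: RunConfig,
                   data: SimulatedData | None = None) -> RunResult:
    """Simulate, edit, assign groups, estimate Gamma, solve every variant
    on complete and reduced data, and compute the LR report."""
    t0 = time.time()
    timings = {}
    if data is None:
        data = simulate(config.sim)
        timings["simulate"] = time.time() - t0
    ped = data.ped
    params = config.sim.trait_params
    trait_names = params.names

    # analyst's view: recompute compositions/heterosis from the masked pedigree
    comps = propagate_breed_composition(ped)
    definition = GroupDefinition(mode=config.group_mode)
    assignment = assign_groups(ped, comps, definition)
    het = heterosis_covariates(ped, comps)
    phen = data.phenotypes.copy()
    an = phen["animal"].to_numpy()
    for c in list(HET_COLUMNS) + ["het_maternal"]:
        phen[c] = het[c].to_numpy()[an]
    for j, b in enumerate("NABC"):
        phen[f"frac_{b}"] = comps.comp[an, j]

    phen, edit_report = edit_phenotypes(phen, trait_names)

    markers, qc_report = qc_markers(data.markers)
    markers, _ = impute_missing_within_matrix(markers)
    genotyped = data.genotyped

    F = compute_inbreeding(ped)
    need_genomic = any(v.startswith("ssGBLUP") for v in config.variants)
    need_mf = any(v.endswith("_MF") for v in config.variants)
    need_upg = any("UPG" in v for v in config.variants)
    A22 = A22inv = G = None
    if need_genomic or need_mf:
        A22, A22inv = build_A22(ped, genotyped, return_inverse=True)
    if need_genomic:
        G = build_G(markers, alpha=config.alpha, A22=A22)
    gamma = None
    mf = None
    vc_mf = None
    if need_mf:
        gamma = estimate_gamma_for_definition(
            markers, ped, genotyped, definition, assignment, A22,
            centering=config.gamma_centering)
        mf = build_Agamma(ped, gamma, assignment.sire_group,
                          assignment.dam_group)
        if config.scale_mf_variances:
            _, k = scale_variance_components(1.0, gamma)
            vc_mf = params.varcomponents().scaled(k)
        else:
            vc_mf = params.varcomponents()
    vc = params.varcomponents()
    G05 = (build_G05(markers, alpha=config.alpha,
                     A22_gamma=mf.A22(genotyped)) if need_mf and need_genomic
           else None)

    split = make_split(phen, ped, genotyped, trait_names)
    val = split.validation_ids
    timings["preparation"] = time.time() - t0

    results: dict[str, VariantResult] = {}
    report_rows = []
    for variant in config.variants:
        tv = time.time()
        is_mf = variant.endswith("_MF")
        use_vc = vc_mf if is_mf else vc
        spec = ModelSpec(
            traits=make_trait_models(
                params,
                include_breed_fracs=(config.fit_breed_fractions
                                     and not is_mf
                                     and "UPG" not in variant)),
            varcomps=use_vc, variant=variant,
            group_mode=config.group_mode, alpha=config.alpha)
        rel = assemble_relationship_inverse(
            variant, ped,
            assignment=assignment if (is_mf or "UPG" in variant) else None,
            genotyped=genotyped if spec.genomic else None,
            G=(G05.values if is_mf else G.values) if spec.genomic else None,
            gamma=gamma if is_mf else None,
            mf=mf if is_mf else None, F=F,
            constrain_group=config.constrain_group,
            group_ridge=config.group_ridge)
        sols = {}
        for label, table in (("complete", split.complete),
                             ("reduced", split.reduced)):
            system = build_mme(table, ped, spec, rel)
            sols[label] = solve_mme(system, method=config.solver)
        gebv_c, gebv_r, lr = {}, {}, {}
        fbar = float((rel.mf.F_gamma[val] if is_mf else F[val]).mean())
        for t in params.traits:
            targets = [(t.name, "direct")]
            if config.validate_maternal and t.maternal:
                targets.append((t.name, "maternal"))
            for name, effect in targets:
                key = name if effect == "direct" else f"{name}_mat"
                uc = total_genetic_value(sols["complete"], name, effect)
                ur = total_genetic_value(sols["reduced"], name, effect)
                gebv_c[key], gebv_r[key] = uc, ur
                s2 = (use_vc.direct_variance(name) if effect == "direct"
                      else use_vc.maternal_variance(name))
                stats = lr_statistics(uc[val], ur[val], fbar, s2)
                lr[key] = stats
                for stat, value, se in (
                    ("accuracy", stats.accuracy, np.nan),
                    ("stability", stats.stability, np.nan),
                    ("slope", stats.slope, stats.slope_se),
                    ("bias", stats.bias, stats.bias_se),
                ):
                    report_rows.append({"model": variant, "trait": key,
                                        "statistic": stat, "value": value,
                                        "se": se})
        grp = (sols["complete"].group_solutions()
               if rel.group_labels else None)
        results[variant] = VariantResult(
            variant=variant, gebv_complete=gebv_c, gebv_reduced=gebv_r,
            lr=lr, group_solutions=grp,
            solver_stats={"residual_complete":
                          sols["complete"].relative_residual,
                          "residual_reduced":
                          sols["reduced"].relative_residual})
        timings[variant] = time.time() - tv

    report = pd.DataFrame(report_rows)
    correlations = {}
    keys = set()
    for r in results.values():
        keys |= set(r.gebv_complete)
    for key in sorted(keys):
        vecs = {v: r.gebv_complete[key] for v, r in results.items()
                if key in r.gebv_complete}
        correlations[key] = model_correlations(vecs, validation_ids=val)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.sim.seed,
        "version": __version__,
        "n_animals": ped.n,
        "n_genotyped": int(len(genotyped)),
        "n_markers_post_qc": markers.n_markers,
        "n_validation": int(val.size),
        "records_post_edit": {r["trait"]: r["records_out"]
                              for r in edit_report.to_dict("records")},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return RunResult(config=config, report=report, correlations=correlations,
                     variants=results, gamma=gamma, split=split, data=data,
                     edit_report=edit_report, qc_report=qc_report.to_frame(),
                     manifest=manifest)


def compare_definitions(report_a: pd.DataFrame, report_b: pd.DataFrame,
                        labels: tuple = ("GG4", "GG10")) -> pd.DataFrame:
    """Per-statistic deltas between two group definitions' reports."""
    keys = ["model", "trait", "statistic"]
    if (sorted(map(tuple, report_a[keys].values.tolist()))
            != sorted(map(tuple, report_b[keys].values.tolist()))):
        raise ValueError("mismatched report schema")
    merged = report_a.merge(report_b, on=keys, suffixes=tuple(
        f"_{l}" for l in labels))
    a, b = (f"value_{l}" for l in labels)
    merged["delta"] = merged[b] - merged[a]
    merged["sign_change"] = np.sign(merged[a]) != np.sign(merged[b])
    return merged[keys + [a, b, "delta", "sign_change"]]
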