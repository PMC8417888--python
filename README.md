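# mfblup

Pedigree and single-step genomic BLUP for composite beef-cattle
populations whose base is a mixture of divergent breeds, with the two
standard devices for modelling that heterogeneous base — unknown-parent
groups (UPGs, via the QP transformation) and metafounders (related
pseudo-founders with relationship matrix **Γ**) — plus the LR
cross-validation statistics used to measure how much either device
changes accuracy, stability, dispersion and bias of breeding values.

It is written for quantitative geneticists who want a transparent,
fully scriptable implementation of this model family at desk scale:
every matrix (A, A⁻¹, A₂₂, the QP-transformed A\*, A(Γ), G, G₀₅, the
single-step H⁻¹ variants) is built by explicit, tested rules, and a
synthetic composite-population generator provides data with known truth
so that every claim can be checked against it.

## The models

For each trait the evaluation model is

```
y = Xb + Z₁u + Z₂m + Z₃c + e
```

with fixed effects **b** (contemporary group, class factors, heterosis
and other covariates), direct additive genetic effects **u**, maternal
genetic effects **m** and maternal permanent environment **c** for the
designated traits, and residual **e**; genetic effects share one
relationship structure **K** through the multi-trait penalty
G₀⁻¹ ⊗ K⁻¹.  Seven variants differ only in **K**:

| variant       | K⁻¹ |
|---------------|-----------------------------------------------|
| `BLUP`        | A⁻¹ (Henderson rules with inbreeding) |
| `BLUP_UPG`    | A\* (QP transformation: group columns appended) |
| `BLUP_MF`     | A(Γ)⁻¹ (metafounders as related pseudo-founders) |
| `ssGBLUP`     | A⁻¹ + [G⁻¹ − A₂₂⁻¹] on the genotyped block |
| `ssGBLUP_UPG` | A\* + [D, −DQ; −Q′D, Q′DQ], D = G⁻¹ − A₂₂⁻¹ |
| `ssGBLUP_UPGA`| A\* + [D, −A₂₂⁻¹Q; −Q′A₂₂⁻¹, Q′A₂₂⁻¹Q] |
| `ssGBLUP_MF`  | A(Γ)⁻¹ + [G₀₅⁻¹ − A₂₂(Γ)⁻¹] |

G is the VanRaden genomic matrix centred at observed allele
frequencies; G₀₅ is centred at 0.5, the companion of the
metafounder-modified pedigree matrix.  **Γ** is estimated from
genotypes by generalized least squares of gene content on breed
fractions followed by `Γ̂ = 8 Cov(p̂)` across markers, and the additive
variances are rescaled by `k = 1 + mean(diag Γ)/2 − mean(Γ)` on the
metafounder base.  Missing parents are assigned to groups from breed
compositions propagated through the pedigree, under a 4-group (one per
biological type N, A, B, C) or a 10-group (purebreds plus merged
crossbred combinations) definition.

Model quality is measured with the LR method: predictions from a
reduced dataset (validation cohort's records and their contemporaries'
records removed) are compared with predictions from the complete data,
giving accuracy `ρ = sqrt(cov(û_c, û_r) / ((1 − F̄) σ²_u))`, stability
`cor(û_c, û_r)`, dispersion slope `b₁` from `û_c = b₀ + b₁ û_r`, and
bias `mean(û_r) − mean(û_c)`.

## Worked example

`examples/04_single_step_evaluation.py` simulates a 720-animal
composite population (222 genotyped, 104 validation animals), runs all
seven variants and prints the LR report; an excerpt for weaning weight
(direct effects):

```
model              BLUP  BLUP_MF  BLUP_UPG  ssGBLUP  ssGBLUP_MF
ww     accuracy  0.185    0.187     0.354    0.223       0.217
       bias      0.029    0.023     0.520    0.016       0.006
       slope     1.563    1.631     0.557    1.224       1.288
       stability 0.641    0.666     0.361    0.581       0.591
```

Genomic variants are more accurate and better dispersed than pedigree
BLUP; the UPG variant's free group effects are poorly estimable at this
tiny scale and destabilize its proofs (large bias, slope far from 1) —
the same erratic behaviour reported for UPG single-step models on real
composite data — while the metafounder variant stays close to plain
ssGBLUP but on a compatible base.  The estimated Γ printed alongside
(diagonal ≈ 0.7, off-diagonals ≈ 0.4) says the simulated base breeds
are heterozygous and share ancestral variation.

`examples/05_lr_validation_and_compatibility.py` checks calibration and
the compatibility diagnostics:

```
LR calibration of a correctly specified ssGBLUP (3 replicates):
  mean dispersion slope b1 : 1.066   (target 1)
  mean bias (genetic SD)   : -0.001 (target 0)
cor(diag G,   diag A22)        : 0.08
cor(diag G05, diag A22(Gamma)) : 0.75
```

Putting both matrices on the metafounder base raises their means and
reconciles their diagonals.

The remaining examples cover the simulator (`01`), the relationship
machinery on hand-checkable pedigrees (`02`) and group assignment plus
Γ estimation (`03`).  A thin CLI wraps the same functions:
`mfblup simulate --out DIR --seed N` and
`mfblup run --config cfg.yaml --out DIR`.

## Layout

```
src/mfblup/
  simdata.py      synthetic composite population with known truth
  pedigree.py     A, A⁻¹, A₂₂, QP-transformed A*, A(Γ) and inverses
  groups.py       breed-composition propagation, UPG/MF assignment,
                  heterosis covariates
  genomic.py      marker QC, imputation, G and G₀₅, matrix summaries
  gamma.py        GLS base frequencies, Γ estimation, variance scaling
  mme.py          multi-trait mixed-model equations, seven variants,
                  direct and PCG solvers
  validation.py   LR split construction and estimators
  pipeline.py     configuration-driven end-to-end runs
  experiments.py  reproducible study-scale experiments
docs/methods.md   model and simulator documentation
examples/         one narrative script per capability
```
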