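# Methods

## Scope and model family

`mfblup` evaluates breeding values in a composite cattle population whose
base is a mixture of four divergent biological types (N = zebu,
A = tropically adapted taurine, B = British taurine, C = Continental
taurine).  The per-trait model is `y = Xb + Z₁u + Z₂m + Z₃c + e`; up to
four traits are analysed jointly, direct genetic effects for all traits
and maternal genetic plus maternal permanent-environment effects for the
designated traits, with a full genetic covariance matrix G₀ across the
effect–trait combinations, a diagonal-by-animal residual structure R₀
partitioned per record over the observed traits, and a single genetic
relationship structure K shared by all genetic effects through the
Kronecker penalty G₀⁻¹ ⊗ K⁻¹.

Three treatments of the heterogeneous base are implemented.

*Unknown-parent groups (QP transformation).*  Each missing-parent slot is
assigned to a group; the group columns are appended to the genetic-effect
vector, Henderson's accumulation treats a group column like a parent with
F = −1, and no diagonal is seeded for group columns.  The solved animal
effects are then the *total* merits `u + Qg`.  Two consequences drive the
numerical choices below: rows of Q sum to one, so group effects are
exactly confounded with the contemporary-group intercepts; and beyond
that, A\* is null on every direction `{a = Qg}`, so a group is identified
only through data contrasts that the fixed effects do not absorb.

*Metafounders.*  Groups become pseudo-founders related by a k×k matrix Γ.
They are carried as extra levels of an extended pedigree: the tabular
recursion seeded with Γ in the metafounder block yields A(Γ), its inverse
is the usual per-animal accumulation (Mendelian variances read off the
A(Γ) diagonal) plus Γ⁻¹ on the metafounder block, and A₂₂(Γ) is the
genotyped submatrix.  Γ's diagonal below 1 encodes excess base
heterozygosity; positive off-diagonals encode overlapping ancestral
populations.

*Single-step.*  H⁻¹ adds the genomic correction to the matching pedigree
inverse: `G⁻¹ − A₂₂⁻¹` for the plain and UPG forms (with the group
couplings `−DQ`/`−A₂₂⁻¹Q` for UPGs in all matrices vs in the pedigree
matrices only), and `G₀₅⁻¹ − A₂₂(Γ)⁻¹` with no group coupling for
metafounders.  G is VanRaden's matrix centred at the observed allele
frequencies of the current genotyped animals; G₀₅ uses −1/0/1 coding and
the scale `m/2`, which is the genomic matrix whose expectation matches
A(Γ) on the metafounder base.

## The zero-Γ correspondence

The accumulation part of A(Γ)⁻¹ at Γ → 0 is exactly the QP-transformed
A\*: Mendelian variances agree to O(γ) and the unknown-parent couplings
coincide.  The correspondence between the two devices therefore holds
when the metafounders carry *no prior precision* (fixed group columns),
and `build_Agamma(..., include_prior=False)` constructs precisely that
object.  With the Γ⁻¹ prior retained and a small Γ, the prior precision
diverges, metafounder solutions shrink to zero and the model reduces to
plain BLUP with unrelated founders — not to the UPG model.  Both limits
are measured by `experiments.zero_gamma_equivalence` and asserted in the
test suite; the distinction matters when interpreting "a zero Γ is
equivalent to unknown-parent groups": it is an identity of relationship
structures, not of the small-variance random-effect model.

## Γ estimation and variance scaling

Per marker, gene content is regressed on the k group fractions by GLS
with A₂₂ as the error covariance, `p̂ⱼ = ½ (Q'A₂₂⁻¹Q)⁻¹ Q'A₂₂⁻¹ mⱼ`;
identity weights (OLS) are available and serve as the test oracle.
`Γ̂ = 8 ×` the across-marker covariance of the estimated frequency
columns.  Columns are centred at their own means by default — invariant
to which allele is called the reference — with 0.5-centring as an option
(`centering="half"`); for frequency distributions symmetric about 0.5 the
two differ negligibly.  Additive (co)variances are divided by
`k = 1 + mean(diag Γ)/2 − mean(Γ)` for metafounder runs; non-additive
components are untouched.

Estimation quality depends strongly on the composition design of the
genotyped set.  With genotyped purebreds the GLS is well conditioned and
Γ̂ reaches the truth to ~1% on 5,000 markers (`gamma_recovery`).  With a
crossbred-dominated genotyped set the per-marker frequency errors are
large and negatively correlated across breeds, inflating Γ̂'s diagonal
and deflating its off-diagonals; a composition design of affine dimension
< 4 (e.g. all genotyped animals sharing one breed fraction) makes the
normal equations singular, in which case the minimum-norm solution is
used with a warning.  A Γ̂ diagonal ≥ 2 would leave founders a
non-positive Mendelian variance and is rejected with a clear error.

## Solving

Systems are solved by sparse LU or by conjugate gradients with a
block-Jacobi preconditioner (blocks = the effect×effect sub-matrix per
genetic level, per PE level, and the diagonal for fixed effects; cap
5,000 iterations, relative tolerance 1e−12).  Every returned solution is
checked against the residual contract ‖LHS·s − RHS‖/‖RHS‖ < 1e−10.

Three devices make all seven variants uniquely solvable so that both
solvers return the same answer:

1. **Reference group.**  The last used group label is dropped (its
   solution pinned to zero), removing the Q·1 = 1 confounding with the
   contemporary-group intercepts.  Applied identically to the explicit
   group-covariate formulation, so the QP equivalence is exact.
2. **Group ridge.**  An optional constant (default 1e−4 in `RunConfig`,
   zero at the `assemble_relationship_inverse` level) added to the
   remaining group diagonals, i.e. groups fitted as random with prior
   variance σ²ᵤ/ridge ≈ 10⁴ σ²ᵤ.  It pins group directions that the
   trait's fixed effects span through Q while shrinking identifiable
   group solutions imperceptibly.
3. **Collinearity screen.**  Factor dummies and covariates are
   orthogonalized against the contemporary-group space and each other;
   exactly confounded columns are dropped and reported.  In structured
   populations breed-fraction and heterosis covariates are low-rank
   functions of a few pool compositions and routinely collide.

Dense constructions (A, the A₂₂ ancestor closure, A(Γ)) are capped at a
configurable 5,000 animals; A₂₂ is computed on the ancestor closure of
the genotyped set rather than from the full A.

## The synthetic population

The generator is the package's test bed and defines its study
conditions.

* **Base breeds.**  Balding–Nichols drift: ancestral frequency
  p₀ ~ U[0.05, 0.95] per marker, breed frequency
  Beta(p₀(1−F_b)/F_b, (1−p₀)(1−F_b)/F_b) with per-breed drift F_b
  (defaults 0.20, 0.10, 0.08, 0.12; the zebu type most diverged).  The
  true Γ is then known exactly as 8 × Cov of the frequency columns
  (diagonal ≈ 8(Var p₀ + F_b E[p₀q₀]), an analytic check used in the
  tests).
* **Crossing plan.**  150 purebred founders per breed, two-way crosses,
  three/four-way intermediates, then three admixed composite generations
  whose parents are drawn from unions of pools, giving a quasi-continuous
  spread of breed compositions (≈ 3,400 animals at scale 1; experiments
  use scale 0.85 ≈ 2,980).  Sire teams of ~1 sire per 10 offspring
  create paternal half-sib families.
* **Genotypes.**  Founder alleles Bernoulli(p_breed), Mendelian
  transmission below, independent markers (no linkage).  Without LD the
  relationship-matrix algebra is exact, which keeps the oracles sharp; it
  also means marker density is not a tunable realism knob here.
* **Traits.**  Four standardized traits mirroring a beef evaluation: a
  male-only reproductive trait (h² = 0.25), post-weaning gain (0.09),
  weaning weight (0.23, maternal h² 0.10, PE 0.05) and birth weight
  (0.22, maternal 0.05, PE 0.03); direct–maternal correlation −0.3,
  modest across-trait correlations (0.3 genetic, 0.2 residual);
  heterosis effects 0.25 σ_P for zebu×taurine pairs and 0.10 within
  taurine; contemporary groups from farm × generation (× season × sex
  for the weight traits) with SD 0.3.
* **Genetic architecture.**  Direct breeding values are 80% marker-borne
  (`marker_fraction = 0.8`: the simulated markers act as causal loci,
  with per-marker effects correlated across traits) and 20% polygenic by
  pedigree recursion `uᵢ = ½(u_s + u_d) + φᵢ`,
  Var(φ) = (0.5 − 0.25(F_s + F_d)) G₀.  The marker component is what
  makes genomic information genuinely informative — with a purely
  polygenic trait the marker Mendelian sampling is independent of the
  trait Mendelian sampling and G adds only noise.  Maternal effects are
  fully polygenic.  Configured base-breed means enter through the breed
  composition; marker drift additionally shifts base means organically,
  exactly as overlapping base populations would.
* **Missingness and genotyping.**  Parents of non-founders are masked
  with probabilities 0.15 (sire) and 0.10 (dam); founder parents are
  unknown by construction.  Genotyping covers the two youngest composite
  pools plus 5% of every other cross pool (which also keeps the
  composition design of the genotyped set at full rank for Γ
  estimation); the validation cohort is the youngest genotyped pool.

What the generator does **not** contain, and what passing tests
therefore cannot show: selection and genetic trend (matings are random,
so there is no trend for a validation cohort to extrapolate), linkage
disequilibrium, genotyping error, age structure beyond discrete
generations, and composition-recording error (all compositions are
known).

## Validation statistics

Accuracy is reported as the square root of
`cov(û_c, û_r) / ((1 − F̄) σ²ᵤ)` — the LR ratio estimates a squared
accuracy, and the root form is what is comparable with an empirical
correlation; the unrooted ratio is kept in the result object.  For
metafounder runs F̄ is measured on the A(Γ) scale (diagonal − 1 of the
extended matrix) and σ²ᵤ is the scaled variance, keeping numerator and
denominator on one base; pedigree F is used otherwise.  Slope and bias
standard errors are ordinary least-squares formulas.

Calibration, measured by `experiments.lr_calibration` (ten ~3,000-animal
replicates, 2,000 markers, near-homogeneous base so that plain ssGBLUP is
correctly specified): mean b₁ ≈ 1.02, mean bias ≈ 0.003 genetic SD, LR
accuracy within 0.01 of the empirical cor(GEBV_r, true BV).

## The plain-vs-metafounder contrast

`experiments.bias_comparison` runs plain ssGBLUP (no breed-composition
covariates — a base-ignorant model) against ssGBLUP with estimated GG4
metafounders on identical replicates of a heterogeneous-base population
(divergent breeds plus configured base means spanning two genetic SD)
and compares |b₁ − 1| and |bias| pairwise.  Under this generator the
contrast does **not** systematically favour metafounders: without
selection the LR bias of the plain model is structurally near zero
(cohort-level means are absorbed by the contemporary-group effects, and
the genotyped validation cohort is anchored through G to the genotyped
reference, so masked-pedigree errors cancel), while the metafounder arm
carries genuine Γ-estimation noise from the crossbred-dominated GLS.
The experiment reports the paired sign tests either way; interpreting
metafounders as a bias *reduction* requires mechanisms this simulator
deliberately excludes (selection and trend foremost).  What the package
does demonstrate positively is the compatibility mechanism: on the
metafounder base the genomic and pedigree matrices agree — the
diagonal-element correlation between genomic and pedigree matrices rises
from ≈ 0.05 to ≈ 0.77 and both means shift upward
(`experiments.base_compatibility`).

## Editing and marker QC defaults

Phenotypes: records beyond ±3 sample SD of their contemporary-group mean
are removed first, then groups left with < 5 records.  Markers, in fixed
order: unknown position or sex chromosome → call rate < 0.90 →
MAF < 0.05 → |observed − expected heterozygote frequency| > 0.15.
Remaining missing genotypes are imputed by twice the observed frequency.
Genomic matrices are blended `α G_raw + (1 − α) A₂₂(·)` with α = 0.95
(metafounder runs blend against A₂₂(Γ)); no rescaling of G to A₂₂ means
is applied by default, since base compatibility is exactly what UPGs and
metafounders are for.

## Known limitations

Dense tabular constructions bound the pedigree size (configurable,
default 5,000); no REML/Gibbs variance estimation (variance components
are inputs); no genotype imputation across panels; UPG solutions at
small scale are erratic whenever group contrasts are weakly identified —
visible in the examples and consistent with field experience; the
GG10 definition inherits all of this with ten sparser groups, and its Γ
falls back to the quadratic-form expansion `f'Γ₄f` of the four-breed
estimate when some of the ten groups lack genotyped support.
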