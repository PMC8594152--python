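# Methods

`liabped` estimates the heritability of a binary, screened trait on a dog
pedigree two ways — a linear (Gaussian) animal model on the 0/1 diagnosis
fitted by AI-REML, and a Bayesian threshold (liability) animal model fitted
by Gibbs sampling — and reconciles the two scales with the Dempster–Lerner
transformation.  This note records the models, the numerical choices, the
priors, and what the synthetic-data validation does and does not show.

## Data model and cleaning

The unit of analysis is one animal with one final diagnosis.  Raw data are
repeated eye-screening examinations; cleaning applies the screening
scheme's rules: any affected examination makes the animal affected ("once
affected = affected", i.e. the worst of conflicting results is kept), the
worst grade ever recorded is retained (mild < moderate < severe; an
affected-but-ungraded exam ranks below mild), undated examinations are
discarded (an animal is dropped only when none of its exams is dated), and
animals without a birth date are dropped.  Age at diagnosis is anchored at
the first *affected* examination for affected animals and at the first
examination otherwise: the models' age effect is meant to capture age at
detection, and first detection is the defensible anchor.  Ages are
days/365.25 (continuous) and the floor of that (integer-year classes).

## Pedigree machinery

Pedigrees are validated (cycle detection by topological sorting, ties
broken by birth date then input order), closed over parents, and recoded so
every parent precedes its offspring.  The additive relationship matrix A is
built dense by the tabular method; inbreeding coefficients are F =
diag(A) − 1; the sparse A⁻¹ is assembled by Henderson's rules with
Mendelian-sampling variances adjusted for parental inbreeding
(d = ½ − ¼(F_s + F_d) with both parents known, ¾ − ¼F_p with one, 1 with
none).  At the intended scale (≲ 5000 animals) the dense A costs a few
hundred MB at most and a fraction of a second.

The *parent subset* — animals that appear as sire or dam — is closed under
ancestry (a parent's parents are parents), so the subset pedigree is itself
a valid pedigree and its relationship matrix equals the corresponding
submatrix of A; its sparse inverse is again Henderson's construction.

## Linear animal model (AI-REML)

y = Xβ + Za + e with a ~ N(0, σ²ₐA), e ~ N(0, σ²ₑI), y the 0/1 diagnosis.
Three fixed-effect structures: (1) sex + age classes, (2) sex +
diagnosis-year classes + age classes, (3) sex + year classes + a linear
age-at-diagnosis covariate.  Designs are full-rank (reference level
absorbed into an intercept; single-level factors dropped; residual exact
collinearity removed by pivoted QR).  Variance-component estimates are
invariant to the reparameterisation.

With one record per animal the record covariance V = σ²ₐA₍obs₎ + σ²ₑI is
n × n, so the restricted likelihood, its exact score and the
average-information (AI) matrix are evaluated from one dense Cholesky of V
per iteration — no N × N object beyond the already-dense A.  Updates are
AI (Newton) steps with step-halving, falling back on the EM-like
fixed-point update σ²ᵢ ← σ²ᵢ · (y′PVᵢPy)/tr(PVᵢ) whenever a Newton step
leaves the parameter space or lowers the likelihood (its fixed points are
the REML equations and it preserves positivity).  Convergence: relative
parameter change < 1e-8 and score norm < 1e-6, maximum 200 iterations;
start values σ²ₐ = σ²ₑ = var(y)/2; a variance pinned within a factor ~10 of
the floor (1e-8·var(y)) is flagged as a boundary solution.  Standard errors
come from the inverse AI matrix; the h² SE by the delta method.  EBVs for
every pedigree animal are â = σ²ₐ A[:, obs] Py, which is algebraically the
mixed-model-equation BLUP at the converged variances (the test suite
verifies the MME residuals directly).

The bivariate sex model treats the diagnosis in males and in females as two
traits; each animal records exactly one, so the residual covariance is
structurally zero and fixed there.  The REML surface is maximised directly
over (log σ²ₐ₁, log σ²ₐ₂, atanh r_g, log σ²ₑ₁, log σ²ₑ₂) with BFGS
(Nelder–Mead fallback); the SE of r_g is obtained from a numerical Hessian
in the unconstrained space and the delta method.  Cross-sex genetic
information comes only from opposite-sex relative pairs and is weak at a
few hundred records — SEs near 0.2 are normal, as the tests acknowledge.

## Threshold animal model (Gibbs sampler)

The diagnosis is the sign of a latent liability l = Xβ + a + e with
threshold 0 and residual variance fixed at 1 (identifiability); per stored
sample h² = σ²ₐ/(σ²ₐ + 1).  Each round updates, in order: the fixed
effects (joint Gaussian draw under independent N(0, 5²) priors), then for
every animal in pedigree code order a *collapsed* pair update — for a
recorded animal the liability is drawn from its truncated-normal
conditional with the animal's own breeding value integrated out (variance
1 + σ²ₐ/Q_ii, Q = A⁻¹), then the breeding value given that liability —
and finally the genetic variance.  The collapsed pair update removes the
slow two-step random walk that (lᵢ, aᵢ) otherwise performs when each
animal carries a single binary record; it roughly doubles the effective
sample size at no cost.  Truncated normals are drawn by exact rejection
(plain rejection near the bulk, Robert's exponential-envelope rejection in
the tail).  All draws use a single seeded generator inside the compiled
kernel, so runs are bit-for-bit reproducible.

**Variance update (parents-only).**  With one record per animal the exact
posterior of this model is degenerate: as σ²ₐ → ∞ the model turns into a
saturated family-sign fit whose likelihood does not vanish, so the
marginal likelihood of σ²ₐ need not decay and chains of an exact sampler
migrate to h² → 1 (the package's `variance_update="reduced"` mode, an
exact reduced-animal-model sampler with slice and parameter-expansion
updates, demonstrates this).  The default therefore samples σ²ₐ from the
quadratic form of the breeding values of *animals with offspring* only,
over the inverse relationship matrix of the subset pedigree — the
parents-based scheme used in threshold-model practice for single-record
data.  It deliberately shields the variance update from the saturating
likelihood contribution of non-parents; parameter-recovery experiments,
not algebra, are its justification, and they are part of the acceptance
suite.  The textbook all-animals update is available for comparison.

**Priors.**  The default prior on σ²ₐ is uniform on h² = σ²ₐ/(σ²ₐ+1),
i.e. p(σ²ₐ) = (1 + σ²ₐ)⁻²: proper, knob-free, flat on the quantity being
inferred, and with exactly enough tail decay to make the degenerate
large-variance regime repelling (a flat-on-σ² prior is improper here and
the conjugate draw has an intrinsic upward log-drift of order 1/n_parents
per round once the likelihood saturates, so escape would be absorbing).
The draw stays conjugate via a one-line Metropolis correction: propose
from the flat-σ² inverse-chi-square draw, accept with the prior ratio.  A
scaled inverse chi-square prior (`prior="inv_chi2"`, default ν=1,
S²=0.1) is available, including the improper flat choice ν=−2, S²=0.
Fixed effects carry independent N(0, 5²) priors; without them a fixed-
effect class containing only affected (or only unaffected) animals — the
extreme-category problem, which arises naturally when age at diagnosis is
late for affected animals — drives its effect and with it the genetic
variance to infinity.  On the liability scale (residual SD 1) real
sex/age/year effects are well below 1, so SD 5 is weakly informative.

Default chain settings mirror a production run: 1,100,000 rounds, 100,000
burn-in, thinning 10.  When a linear-model fit is available (as in
`recovery_experiment`), the chain warm-starts at the converted REML
estimate — standard practice that shortens the transient without changing
the stationary distribution.  The validation experiments use 55,000/5,000/10,
which at n ≈ 1500 records runs in ~20 s and yields effective sample sizes
of a few hundred for h².

## Scale conversion

Dempster–Lerner: h²_l = h²_o · p(1−p)/z², with p the trait frequency and
z = φ(Φ⁻¹(1−p)) the standard-normal ordinate at the threshold; the SE
scales by the same factor.  `z_override` exists because published tables
are sometimes computed with a rounded z (0.227 at p = 0.145 rather than
0.2279), and reproducing them requires the stated value.

The relation is first-order.  The exact observed-scale covariance between
relatives is Φ₂(τ,τ;ρh²_l) − p², which is convex in the liability
correlation, so close relatives resemble each other *more* on the 0/1
scale than z²h²_l per unit relationship: at h²_l = 0.65, p = 0.145 the
exact parent-offspring regression implies an observed-scale slope of
0.325 against the first-order 0.272.  Consequently linear-model REML
estimates of "observed-scale h²" sit a few hundredths above
h²_l·z²/(p(1−p)), and their Dempster–Lerner conversions sit above the
liability-scale truth by roughly the same relative amount.  This is a
property of the estimator, not a bug; the recovery experiments quantify
it.

## Diagnostics

ESS uses n/(1 + 2Σρ̂_k) with Geyer's initial-positive-sequence truncation
of paired autocorrelations (FFT-based autocovariances); a constant chain
is reported as ESS = n with a degeneracy warning.  HPD intervals are the
empirical shortest interval containing ⌈level·n⌉ order statistics,
leftmost on ties.  Both are cross-checked against arviz in the test suite.

## Synthetic data generator

The generator emulates a kennel-club screening data set: founders plus
litter generations with a popular-sire mating structure (a quarter of the
previous generation's males sire all litters; litter sizes are shifted
negative binomial with mean 4); breeding values follow a ~ N(0, σ²ₐA)
exactly, realised founder-by-founder and by Mendelian sampling with
parental-inbreeding-adjusted segregation variance — the same genetic model
the estimators assume; liability adds sex (0.05), age-slope (0.02/yr) and
year (SD 0.05) effects plus a residual scaled so the liability h² equals
the configured value; the threshold is the Gaussian quantile of the target
prevalence (0.145), so realized prevalence is random exactly as in real
data.  Examinations: every animal is examined once, then again with
probability 0.48 per exam (≈1.9 exams/animal); early exams of an affected
animal read unaffected with probability 0.30 (conflicts are false-negative
only); dates go missing with probability 0.005.  These defaults are the
study conditions: roughly a thousand-to-three-thousand animal pedigree,
prevalence ~14.5%, a strong excess of unaffected→affected over
affected→unaffected first-vs-last transitions, and a handful of animals
lost to missing dates.  Structure and genetics use separate RNG streams so
a fixed `structure_seed` re-draws genetics on an identical pedigree.

What the generator does *not* emulate: selective screening (every animal
is examined, whereas real registries screen a third of registered dogs,
mostly breeding candidates), selection and assortative mating across
generations, litter/maternal environmental effects, and grading-severity
genetics (grades are drawn independently of liability).  Passing recovery
tests therefore show the estimators are correct under the stated genetic
model at the study's scale — not that real screening data are free of
ascertainment bias.

One interaction deserves note: because affected animals are dated at first
*affected* exam, their retained ages extend beyond the first-exam age
range, so the oldest age classes contain only affected animals.  This is a
faithful feature of the cleaning rule, and it is exactly what makes the
fixed-effect priors in the threshold sampler necessary.

## Validation experiment sizes

The test suite's replicated experiments use: 50 replicates at ~1000
animals for REML observed-scale recovery; 20 replicates at ~1500 animals
with 55,000-round chains for HPD calibration; ten of those replicates
carry both estimators for the liability-scale agreement and EBV-
correlation checks; balanced half-sib designs up to 100 sires × 20
offspring for the REML-vs-ANOVA oracle.  These sizes put every experiment
at the same order as the study data while keeping a full run of the suite
in the tens of minutes on one core.

## Known limitations

* The parents-only variance update is a validated approximation, not an
  exact posterior sampler.  Its point estimates recover the generating
  heritability well, but its HPD intervals are narrower than the
  across-replicate spread of its own estimates (the replicated calibration
  experiment in the test suite measures this directly), so interval
  coverage falls short of nominal; occasional chains still migrate to the
  degenerate high-heritability regime despite the priors.
* The bivariate sex model reports delta-method SEs that are unreliable
  when r̂_g sits at ±1.
* The linear model treats a Bernoulli response as Gaussian by design
  (matching the analysis it implements); its SEs inherit that
  approximation.
* Age-class designs can be ill-conditioned in small samples; class merging
  (`min_class_size`) is available but off by default.
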