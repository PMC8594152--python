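# liabped

Heritability analysis of a binary (threshold) trait on a dog pedigree —
built around the eye-screening registries used in companion-animal
genetics, where repeated examinations yield one affected/unaffected
diagnosis per dog and a kennel-club pedigree ties the dogs together.

The package covers the full analysis chain:

* **cleaning** repeated examination records into one row per animal
  ("once affected = affected", worst grade kept, undated records and
  dateless animals dropped, age at diagnosis computed);
* **descriptive statistics** — prevalence with confidence interval, sex
  contingency test, grading proportions, screening coverage;
* **pedigree machinery** — validation and topological recoding, inbreeding
  coefficients, the additive relationship matrix A and its sparse inverse
  by Henderson's rules;
* **linear animal model** on the 0/1 diagnosis, fitted by AI-REML, with
  observed-scale heritability, standard errors and BLUP breeding values;
* **Bayesian threshold (liability) animal model** by Gibbs sampling, with
  the residual variance restricted to 1, the genetic variance sampled from
  the parents-only quadratic form, posterior means, HPD regions and
  effective sample sizes;
* **scale conversion** between the observed 0/1 scale and the liability
  scale by the Dempster–Lerner formula
  h²ₗ = h²ₒ · p(1−p)/z², and Pearson/Spearman comparison of breeding-value
  sets;
* a **synthetic-data generator** that simulates litter-structured
  pedigrees and examination records under the exact genetic model the
  estimators assume, so every stage is validated by parameter recovery.

The model at the core is the animal model

    y = Xβ + Za + e,   a ~ N(0, σ²ₐ A),   e ~ N(0, σ²ₑ I)

fitted directly to the 0/1 diagnosis (linear route, h²ₒ = σ²ₐ/(σ²ₐ+σ²ₑ)),
and its threshold counterpart in which y = 1 exactly when a latent
liability l = Xβ + a + e exceeds 0, with σ²ₑ ≡ 1 and h² = σ²ₐ/(σ²ₐ+1).
`docs/methods.md` describes both fits, the priors, and the numerical
choices in detail.

## Worked example

```python
import liabped as lp

# simulate a screening data set: ~1000-animal pedigree, liability h2 0.65,
# prevalence 14.5%, repeated exams with occasional early false negatives
pop = lp.simulate(lp.SimulationConfig.sized(1000, seed=7))
clean, report = lp.clean_records(pop.records, pop.pedigree)
print(report.n_raw, "->", report.n_final, "animals;",
      report.n_unaffected_to_affected, "went unaffected->affected")

prev = lp.prevalence(int(clean["y"].sum()), len(clean))
print(f"prevalence {100*prev.p_hat:.1f}% "
      f"(95% CI {100*prev.ci_low:.1f}-{100*prev.ci_high:.1f}%)")

# linear animal model (model 1: sex + age classes), AI-REML
fit = lp.LinearAnimalModel(clean, pop.pedigree, model=1).fit()
print(fit.summary())
print(fit.to_liability())

# Bayesian threshold model, short exploratory chain
res = lp.ThresholdAnimalModel(clean, pop.pedigree, model=1).fit(
    n_rounds=55_000, burn_in=5_000, thin=10, seed=7
)
print(res.summary())
print(lp.compare_ebv(fit.ebv, res.ebv))
```

Output of this exact script (seed 7, warnings suppressed):

```
1957 -> 971 animals; 24 went unaffected->affected
prevalence 15.6% (95% CI 13.3-17.8%)
Linear animal model 1 (AI-REML)
============================================
records: 971   pedigree animals: 972
converged: True in 10 iterations (|grad| = 3.78e-08)
--------------------------------------------
genetic variance     0.0318  (0.0080)
residual variance    0.0931  (0.0066)
h2 (observed 0/1)    0.2546  (0.0572)
--------------------------------------------
fixed effects:
  intercept             0.1583
  sex[male]             0.0340
  ...
h2 observed 0.255 (SE 0.057) -> liability 0.586 (SE 0.132) at p=0.156, z=0.2388
Threshold animal model 1 (Gibbs sampler)
========================================================
rounds 55000, burn-in 5000, thin 10, seed 7; stored 5000 samples
variance update: parents_only; residual variance fixed at 1
--------------------------------------------------------
parameter        mean     95% HPD            ESS
genetic var     1.410   (0.622, 2.459)      486.2
h2              0.569   (0.415, 0.740)      472.9
EBVComparison(pearson=0.979..., spearman=0.992..., n_animals=972)
```

Read: the generating liability heritability was 0.65; the 0/1-scale REML
estimate 0.255 converts to 0.586 on the liability scale, agreeing with the
threshold model's posterior mean 0.569 (95% HPD 0.42–0.74), and the two
model families rank animals almost identically (EBV correlations
0.98/0.99).

A thin CLI wraps the same functions
(`liabped simulate | pedigree | clean | describe | reml | remlsex |
gibbs | diag | convert | compare | recover`); every subcommand has
`--help`.

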