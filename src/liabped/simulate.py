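"""Synthetic pedigree and examination-record generator.

Emulates a kennel-club style screening data set: a multi-generation,
litter-structured pedigree; an additive genetic liability a ~ N(0, s2a*A)
realised by Mendelian sampling down the pedigree (with parental-inbreeding
adjusted segregation variance, the same genetic model the estimators
assume); small sex/age/year fixed effects on the liability scale; a binary
diagnosis from thresholding the liability at the quantile matching a
target prevalence; repeated examinations with occasional false-negative
early exams (conflicting results); and sporadic missing dates.

The generator returns the truth (breeding values, liabilities, final
status) alongside the raw records so that every pipeline stage — cleaning,
REML, Gibbs sampling, scale conversion — can be validated by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from scipy import stats

__all__ = ["SimulationConfig", "SimulatedPopulation", "simulate", "recovery_experiment"]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated population.

    Defaults mirror a Havanese-like screening data set: moderate pedigree
    (~1000 animals over 4 litter generations), liability heritability 0.65,
    prevalence 14.5%, small sex/age/year effects, frequent re-examination
    (about 1.9 exams per animal) and occasional early false negatives.
    """

    n_founders: int = 80
    n_generations: int = 4
    litters_per_generation: int = 58
    litter_size_mean: float = 4.0
    litter_size_dispersion: float = 10.0  # neg-binomial k; large ~ Poisson
    sex_ratio: float = 0.5               # P(male)
    h2: float = 0.65                     # liability-scale heritability
    prevalence: float = 0.145
    sex_effect: float = 0.05             # male - female shift, liability SD units
    age_slope: float = 0.02              # per year of age at examination
    year_sd: float = 0.05                # SD of diagnosis-year effects
    reexam_prob: float = 0.48            # P(another exam after each exam)
    conflict_prob: float = 0.30          # P(early exam of an affected dog reads clean)
    missing_date_prob: float = 0.005
    base_year: int = 2005
    generation_years: int = 2
    seed: int = 0
    structure_seed: int | None = None  # fix the pedigree while genetics vary

    def __post_init__(self):
        for name in ("sex_ratio", "prevalence", "reexam_prob", "conflict_prob",
                     "missing_date_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must lie in [0, 1)")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.litters_per_generation < 1 or self.n_generations < 1:
            raise ValueError("need at least one generation of litters")

    @classmethod
    def sized(cls, n_animals: int, **overrides) -> "SimulationConfig":
        """Config whose expected pedigree size is about ``n_animals``."""
        base = {k: v for k, v in overrides.items()}
        n_gen = base.pop("n_generations", 4)
        litter_mean = base.pop("litter_size_mean", 4.0)
        n_found = base.pop("n_founders", max(30, int(round(0.08 * n_animals))))
        per_gen = max(1, int(round((n_animals - n_found) / (n_gen * litter_mean))))
        return cls(
            n_founders=n_found,
            n_generations=n_gen,
            litters_per_generation=per_gen,
            litter_size_mean=litter_mean,
            **base,
        )


@dataclass
class SimulatedPopulation:
    """A generated population with full truth tables."""

    pedigree: Pedigree
    records: pd.DataFrame          # animal, exam_date, diagnosis, grade
    truth: pd.DataFrame            # animal, breeding_value, liability, affected, ...
    realized_prevalence: float
    config: SimulationConfig

    @property
    def true_breeding_values(self) -> pd.Series:
        return self.truth.set_index("animal")["breeding_value"]


def _litter_sizes(rng, n, mean, dispersion):
    m = max(mean - 1.0, 1e-6)  # at least one pup per litter
    p = dispersion / (dispersion + m)
    return 1 + rng.negative_binomial(dispersion, p, size=n)


def simulate(cfg: SimulationConfig) -> SimulatedPopulation:
    """Generate one population under the configured study conditions.

    Two independent RNG streams are used: one for the pedigree structure
    (litters, matings, sexes, birth dates) and one for genetics and
    examinations, so a fixed ``structure_seed`` re-draws genetic values on
    an identical pedigree.
    """
    struct_seed = cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    rng_s = np.random.default_rng([struct_seed, 0])
    rng = np.random.default_rng([cfg.seed, 1])
    s2a = cfg.h2
    s2e = 1.0 - cfg.h2

    # ---- pedigree structure -------------------------------------------
    ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    sexes: list[str] = []
    byears: list[int] = []
    gen_of: list[int] = []

    def add(animal, sire, dam, sex, year, gen):
        ids.append(animal)
        sires.append(sire)
        dams.append(dam)
        sexes.append(sex)
        byears.append(year)
        gen_of.append(gen)

    for i in range(cfg.n_founders):
        sex = "male" if rng_s.random() < cfg.sex_ratio else "female"
        add(f"G0-{i:04d}", None, None, sex, cfg.base_year, 0)

    counter = cfg.n_founders
    for g in range(1, cfg.n_generations + 1):
        prev = [i for i, gg in enumerate(gen_of) if gg == g - 1]
        males = [i for i in prev if sexes[i] == "male"]
        females = [i for i in prev if sexes[i] == "female"]
        if not males or not females:
            raise ValueError(
                f"generation {g - 1} lacks one sex; increase n_founders or litter sizes"
            )
        # popular-sire structure: a minority of males sire most litters
        n_sires = max(1, len(males) // 4)
        sire_pool = rng_s.choice(males, size=n_sires, replace=False)
        year = cfg.base_year + g * cfg.generation_years
        sizes = _litter_sizes(
            rng_s, cfg.litters_per_generation, cfg.litter_size_mean,
            cfg.litter_size_dispersion,
        )
        for lit, size in enumerate(sizes):
            sire = ids[rng_s.choice(sire_pool)]
            dam = ids[rng_s.choice(females)]
            for _ in range(size):
                sex = "male" if rng_s.random() < cfg.sex_ratio else "female"
                add(f"G{g}-{counter:05d}", sire, dam, sex, year, g)
                counter += 1

    month = rng_s.integers(1, 13, size=len(ids))
    day = rng_s.integers(1, 29, size=len(ids))
    bdates = pd.to_datetime(
        pd.DataFrame({"year": byears, "month": month, "day": day})
    )
    ped = Pedigree(
        pd.DataFrame(
            {"id": ids, "sire": sires, "dam": dams, "sex": sexes, "birth_date": bdates}
        )
    )

    # ---- breeding values down the ordered pedigree --------------------
    F = ped.inbreeding()
    n = ped.n
    a = np.zeros(n)
    z = rng.standard_normal(n)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            var_ms = 0.5 * s2a * (1.0 - 0.5 * (F[s] + F[d]))
            a[i] = 0.5 * (a[s] + a[d]) + np.sqrt(var_ms) * z[i]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            var_ms = 0.75 * s2a - 0.25 * s2a * F[p]
            a[i] = 0.5 * a[p] + np.sqrt(var_ms) * z[i]
        else:
            a[i] = np.sqrt(s2a) * z[i]

    # ---- examinations and liabilities ---------------------------------
    tab = ped.table
    sex_arr = tab["sex"].to_numpy()
    birth = tab["birth_date"]
    e = rng.standard_normal(n) * np.sqrt(s2e)

    first_age = rng.uniform(0.8, 6.0, size=n)
    mean_age = (0.8 + 6.0) / 2
    exam_year_first = birth.dt.year.to_numpy() + first_age
    years_all = np.arange(int(exam_year_first.min()), int(exam_year_first.max()) + 12)
    year_eff = dict(zip(years_all, rng.normal(0.0, cfg.year_sd, size=len(years_all))))

    sex_term = np.where(sex_arr == "male", 0.5, -0.5) * cfg.sex_effect
    age_term = cfg.age_slope * (first_age - mean_age)
    yr = exam_year_first.astype(int)
    year_term = np.array([year_eff[y] for y in yr])

    liab = a + e + sex_term + age_term + year_term
    tau = stats.norm.isf(cfg.prevalence)
    affected = liab > tau

    rec_rows = []
    for i in range(n):
        animal = tab["id"].iloc[i]
        ages = [first_age[i]]
        while rng.random() < cfg.reexam_prob:
            ages.append(ages[-1] + rng.uniform(0.7, 2.0))
        n_ex = len(ages)
        for k, age in enumerate(ages):
            if affected[i]:
                last = k == n_ex - 1
                reads_affected = last or (rng.random() >= cfg.conflict_prob)
            else:
                reads_affected = False
            if reads_affected:
                u = rng.random()
                grade = (
                    "mild" if u < 0.87 else
                    "none" if u < 0.97 else
                    "moderate" if u < 0.995 else "severe"
                )
            else:
                grade = "none"
            date = birth.iloc[i] + pd.Timedelta(days=round(age * 365.25))
            if rng.random() < cfg.missing_date_prob:
                date = pd.NaT
            rec_rows.append(
                {
                    "animal": animal,
                    "exam_date": date,
                    "diagnosis": "affected" if reads_affected else "unaffected",
                    "grade": grade,
                }
            )
    records = pd.DataFrame(rec_rows)

    truth = pd.DataFrame(
        {
            "animal": tab["id"].to_numpy(),
            "breeding_value": a,
            "residual": e,
            "liability": liab,
            "affected": affected,
            "generation": tab["id"].map(dict(zip(ids, gen_of))).to_numpy(),
        }
    )
    return SimulatedPopulation(
        pedigree=ped,
        records=records,
        truth=truth,
        realized_prevalence=float(affected.mean()),
        config=cfg,
    )


def recovery_experiment(
    cfg: SimulationConfig,
    n_replicates: int,
    run_reml: bool = True,
    run_gibbs: bool = False,
    model: int = 1,
    gibbs_rounds: int = 55_000,
    gibbs_burn_in: int = 5_000,
    gibbs_thin: int = 10,
    hpd_level: float = 0.95,
    **gibbs_kwargs,
) -> pd.DataFrame:
    """Simulate -> clean -> estimate, repeatedly; one row per replicate.

    REML estimates are converted to the liability scale with the replicate's
    own prevalence (full-precision threshold ordinate); Gibbs summaries are
    the posterior mean and HPD interval of per-sample h2.  Replicate r uses
    seed ``cfg.seed + r`` for both the data and the sampler.
    """
    from .records import clean_records
    from .linear import LinearAnimalModel
    from .threshold import ThresholdAnimalModel

    rows = []
    for r in range(n_replicates):
        c = replace(cfg, seed=cfg.seed + r)
        pop = simulate(c)
        clean, _ = clean_records(pop.records, pop.pedigree)
        row: dict = {
            "replicate": r,
            "true_h2": c.h2,
            "n_records": len(clean),
            "prevalence": float(clean["y"].mean()),
        }
        if run_reml:
            fit = LinearAnimalModel(clean, pop.pedigree, model=model).fit()
            conv = fit.to_liability()
            row.update(
                reml_h2_obs=fit.h2_obs,
                reml_se_obs=fit.se_h2_obs,
                reml_h2_liab=conv.h2_liab,
                reml_converged=fit.converged,
            )
        if run_gibbs:
            kw = dict(gibbs_kwargs)
            if run_reml and "sigma2_a_init" not in kw:
                # warm-start the sampler at the REML liability estimate
                # (shortens the transient; the chain's target is unchanged)
                h0 = float(np.clip(conv.h2_liab, 0.05, 0.90))
                kw["sigma2_a_init"] = h0 / (1.0 - h0)
            res = ThresholdAnimalModel(clean, pop.pedigree, model=model).fit(
                n_rounds=gibbs_rounds,
                burn_in=gibbs_burn_in,
                thin=gibbs_thin,
                seed=c.seed,
                **kw,
            )
            s = res.summarize("h2", hpd_level=hpd_level)
            row.update(
                gibbs_h2_mean=s.posterior_mean,
                gibbs_hpd_low=s.hpd_low,
                gibbs_hpd_high=s.hpd_high,
                gibbs_ess_h2=s.ess,
                gibbs_covered=bool(s.hpd_low <= c.h2 <= s.hpd_high),
            )
        rows.append(row)
    return pd.DataFrame(rows)
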