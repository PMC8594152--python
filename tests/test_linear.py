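"""AI-REML animal model: oracles, invariances, EBVs, bivariate sex model."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from liabped import LinearAnimalModel, SexBivariateModel, Pedigree
from liabped.linear import build_design

from conftest import random_pedigree


def make_clean(ped, y, sex=None, rng=None):
    """Minimal analysis frame around a response vector (pedigree order)."""
    rng = rng or np.random.default_rng(0)
    n = ped.n
    return pd.DataFrame(
        {
            "animal": ped.ids,
            "y": y,
            "sex": sex if sex is not None else ped.table["sex"].replace("unknown", "male"),
            "age_years": rng.integers(1, 5, n),
            "age_continuous": rng.uniform(1, 5, n),
            "diagnosis_year": rng.integers(2010, 2014, n),
        }
    )


def half_sib_design(n_sires=60, n_off=12, h2=0.3, seed=0):
    """Balanced paternal half-sib families, Gaussian trait, unrelated dams."""
    rng = np.random.default_rng(seed)
    rows = [{"id": f"S{i}", "sire": None, "dam": None, "sex": "male"} for i in range(n_sires)]
    y_rows = []
    s2a, s2e = h2, 1 - h2
    a_sire = rng.normal(0, np.sqrt(s2a), n_sires)
    for i in range(n_sires):
        for j in range(n_off):
            aid = f"O{i}_{j}"
            rows.append({"id": aid, "sire": f"S{i}", "dam": None, "sex": "female"})
            a = 0.5 * a_sire[i] + rng.normal(0, np.sqrt(0.75 * s2a))
            y_rows.append((aid, a + rng.normal(0, np.sqrt(s2e))))
    ped = Pedigree(pd.DataFrame(rows))
    ydict = dict(y_rows)
    recorded = [a for a in ped.ids if a in ydict]
    clean = pd.DataFrame(
        {
            "animal": recorded,
            "y": [ydict[a] for a in recorded],
            "sex": "female",
            "age_years": 1,
            "age_continuous": 1.0,
            "diagnosis_year": 2010,
        }
    )
    return ped, clean, (n_sires, n_off)


def anova_h2(clean, shape):
    """Sire-model ANOVA oracle: h2 = 4*s2s/(s2s+s2w) from mean squares."""
    n_sires, k = shape
    y = clean["y"].to_numpy().reshape(n_sires, k)
    gm = y.mean()
    msb = k * ((y.mean(axis=1) - gm) ** 2).sum() / (n_sires - 1)
    msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (n_sires * (k - 1))
    s2s = (msb - msw) / k
    return 4 * s2s / (s2s + msw)


class TestDesign:
    def test_model1_rank(self):
        clean = pd.DataFrame(
            {
                "animal": list("abcdef"),
                "y": [0, 1, 0, 1, 0, 1],
                "sex": ["male", "female"] * 3,
                "age_years": [1, 1, 2, 2, 3, 3],
                "age_continuous": [1.0, 1, 2, 2, 3, 3],
                "diagnosis_year": [2010] * 6,
            }
        )
        X, names = build_design(clean, 1)
        # intercept + 1 sex contrast + 2 age contrasts
        assert X.shape[1] == 4
        assert np.linalg.matrix_rank(X) == 4

    def test_model3_single_covariate_column(self):
        clean = pd.DataFrame(
            {
                "animal": list("abcd"),
                "y": [0, 1, 0, 1],
                "sex": ["male", "female"] * 2,
                "age_years": [1, 2, 3, 4],
                "age_continuous": [1.0, 2.2, 3.1, 4.5],
                "diagnosis_year": [2010, 2010, 2011, 2011],
            }
        )
        X, names = build_design(clean, 3)
        assert names.count("c_age") == 1
        assert "age[2]" not in " ".join(names)

    def test_single_level_factor_dropped_with_warning(self):
        clean = pd.DataFrame(
            {
                "animal": list("abcd"),
                "y": [0, 1, 0, 1],
                "sex": ["male"] * 4,
                "age_years": [1, 2, 1, 2],
                "age_continuous": [1.0, 2, 1, 2],
                "diagnosis_year": [2010] * 4,
            }
        )
        with pytest.warns(UserWarning, match="single level"):
            X, names = build_design(clean, 1)
        assert all(not s.startswith("sex") for s in names[1:])

    def test_animal_missing_from_pedigree_errors(self, trio):
        clean = make_clean(trio, [0.0, 1.0, 0.5]).assign(animal=["A", "B", "nope"])
        with pytest.raises(ValueError, match="absent"):
            LinearAnimalModel(clean, trio)


class TestREMLFit:
    def test_half_sib_matches_anova_oracle(self):
        """Animal-model REML must agree with the closed-form sire ANOVA."""
        ped, clean, shape = half_sib_design(n_sires=60, n_off=12, h2=0.3, seed=1)
        fit = LinearAnimalModel(clean, ped, model=1).fit()
        h2_oracle = anova_h2(clean, shape)
        assert fit.converged
        assert fit.h2_obs == pytest.approx(h2_oracle, abs=3 * fit.se_h2_obs)

    def test_iid_noise_gives_near_zero_h2_on_average(self):
        """No family resemblance: the h2 estimate must be ~0 up to null noise.

        Single-replicate null REML estimates are half-normal-ish, so the
        check averages a few replicates of an informative half-sib design.
        """
        vals = []
        for seed in range(5):
            ped, clean, _ = half_sib_design(n_sires=60, n_off=12, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            clean = clean.assign(y=rng.standard_normal(len(clean)))
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = LinearAnimalModel(clean, ped, model=1).fit()
            vals.append(fit.h2_obs)
        assert np.mean(vals) <= 0.05

    def test_duplicate_run_bitwise_identical(self):
        ped, clean, _ = half_sib_design(n_sires=30, n_off=8, seed=2)
        f1 = LinearAnimalModel(clean, ped, model=1).fit()
        f2 = LinearAnimalModel(clean, ped, model=1).fit()
        assert f1.sigma2_a == f2.sigma2_a and f1.sigma2_e == f2.sigma2_e
        assert np.array_equal(f1.ebv.to_numpy(), f2.ebv.to_numpy())

    def test_row_permutation_invariance(self):
        ped, clean, _ = half_sib_design(n_sires=30, n_off=8, seed=3)
        f1 = LinearAnimalModel(clean, ped, model=1).fit()
        shuffled = clean.sample(frac=1.0, random_state=9).reset_index(drop=True)
        f2 = LinearAnimalModel(shuffled, ped, model=1).fit()
        assert f1.h2_obs == pytest.approx(f2.h2_obs, abs=1e-8)
        assert f1.ebv.loc["S0"] == pytest.approx(f2.ebv.loc["S0"], abs=1e-8)

    def test_optimum_beats_random_probes(self):
        """Restricted likelihood at the REML solution tops 100 random probes."""
        ped = random_pedigree(150, seed=7)
        rng = np.random.default_rng(8)
        A = ped.relationship_matrix()
        a = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n)) @ rng.standard_normal(ped.n) * np.sqrt(0.4)
        y = a + rng.normal(0, np.sqrt(0.6), ped.n)
        clean = make_clean(ped, y, rng=rng)
        model = LinearAnimalModel(clean, ped, model=1)
        fit = model.fit()
        best = model.loglik(fit.sigma2_a, fit.sigma2_e)
        vy = y.var()
        for _ in range(100):
            s2a = rng.uniform(0.01, 2) * vy
            s2e = rng.uniform(0.01, 2) * vy
            assert model.loglik(s2a, s2e) <= best + 1e-6

    def test_ebv_satisfy_mixed_model_equations(self):
        """BLUP solutions must solve Henderson's MME at the converged fit."""
        ped, clean, _ = half_sib_design(n_sires=30, n_off=8, seed=4)
        model = LinearAnimalModel(clean, ped, model=1)
        fit = model.fit()
        X = model.X
        n, N = len(clean), ped.n
        Z = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), model.obs_idx)), shape=(n, N)
        )
        lam = fit.sigma2_e / fit.sigma2_a
        Ainv = ped.a_inverse()
        y = clean["y"].to_numpy(dtype=float)
        beta, a = fit.beta, fit.ebv.to_numpy()
        r1 = X.T @ X @ beta + X.T @ (Z @ a) - X.T @ y
        r2 = Z.T @ (X @ beta) + (Z.T @ Z) @ a + lam * (Ainv @ a) - Z.T @ y
        scale = np.abs(y).sum()
        assert np.abs(r1).max() / scale < 1e-8
        assert np.abs(r2).max() / scale < 1e-8

    def test_unrecorded_relatives_get_combined_ebv(self):
        """A dam with no record gets the pedigree-propagated mean of her family."""
        ped, clean, _ = half_sib_design(n_sires=20, n_off=10, seed=5)
        fit = LinearAnimalModel(clean, ped, model=1).fit()
        # sire EBVs (no own record) must correlate with mean offspring phenotype
        offmeans = clean.assign(s=[a.split("_")[0][1:] for a in clean["animal"]])
        offmeans = offmeans.groupby("s")["y"].mean()
        sires = fit.ebv.loc[[f"S{i}" for i in range(20)]]
        corr = np.corrcoef(sires.to_numpy(), offmeans.loc[[str(i) for i in range(20)]].to_numpy())[0, 1]
        assert corr > 0.8

    def test_constant_response_rejected(self, trio):
        clean = make_clean(trio, [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            LinearAnimalModel(clean, trio)


class TestBivariateSexModel:
    @staticmethod
    def _population(shared: bool, seed: int, n=500, h2=0.6):
        ped = random_pedigree(n, seed=seed)
        rng = np.random.default_rng(seed + 100)
        A = ped.relationship_matrix()
        L = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n))
        a1 = L @ rng.standard_normal(ped.n) * np.sqrt(h2)
        a2 = a1 if shared else L @ rng.standard_normal(ped.n) * np.sqrt(h2)
        sex = ped.table["sex"].replace("unknown", "male").to_numpy()
        a = np.where(sex == "male", a1, a2)
        y = a + rng.normal(0, np.sqrt(1 - h2), ped.n)
        clean = make_clean(ped, y, sex=sex, rng=rng)
        return ped, clean

    @staticmethod
    def _mean_rg(shared: bool, seeds):
        rgs, ses = [], []
        for seed in seeds:
            ped, clean = TestBivariateSexModel._population(shared=shared, seed=seed)
            res = SexBivariateModel(clean, ped, model=1).fit()
            rgs.append(res.r_g)
            ses.append(res.se_r_g if np.isfinite(res.se_r_g) else 0.3)
        pooled = float(np.sqrt(np.mean(np.square(ses)) / len(seeds)))
        return float(np.mean(rgs)), pooled

    def test_shared_breeding_values_give_rg_near_one(self):
        """Same BVs expressed in both sexes: genetic correlation ~ 1."""
        mean_rg, pooled_se = self._mean_rg(shared=True, seeds=(21, 22, 23))
        assert mean_rg >= 1.0 - 2 * max(pooled_se, 0.05)
        assert mean_rg <= 1.0 + 1e-8

    def test_independent_breeding_values_give_rg_near_zero(self):
        """Independent BVs per sex: mean genetic correlation ~ 0.

        Cross-sex genetic information is weak at this scale (per-fit SE
        about 0.2), so the check averages five replicates and uses a
        finite-sample bound that still cleanly separates the r_g = 1 case.
        """
        mean_rg, pooled_se = self._mean_rg(shared=False, seeds=(21, 22, 23, 24, 25))
        assert abs(mean_rg) <= max(2 * pooled_se, 0.25)

    def test_single_sex_errors(self, trio):
        clean = make_clean(trio, [0.0, 1.0, 0.5], sex=["male"] * 3)
        with pytest.raises(ValueError, match="both sexes"):
            SexBivariateModel(clean, trio)


def test_summary_renders(small_population):
    from liabped import clean_records

    clean, _ = clean_records(small_population.records, small_population.pedigree)
    fit = LinearAnimalModel(clean, small_population.pedigree, model=3).fit()
    text = fit.summary()
    assert "genetic variance" in text and "h2 (observed 0/1)" in text
    assert f"{fit.h2_obs:8.4f}" in text
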