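"""Threshold-model Gibbs sampler: contracts, invariants, mixing properties."""

import numpy as np
import pandas as pd
import pytest

from liabped import ThresholdAnimalModel, SimulationConfig, simulate, clean_records


@pytest.fixture(scope="module")
def population():
    pop = simulate(SimulationConfig.sized(500, seed=77))
    clean, _ = clean_records(pop.records, pop.pedigree)
    return pop, clean


@pytest.fixture(scope="module")
def short_fit(population):
    pop, clean = population
    model = ThresholdAnimalModel(clean, pop.pedigree, model=1)
    return model, model.fit(n_rounds=3000, burn_in=1000, thin=5, seed=4)


class TestContracts:
    def test_same_seed_identical_chains(self, population):
        pop, clean = population
        model = ThresholdAnimalModel(clean, pop.pedigree, model=1)
        r1 = model.fit(n_rounds=1500, burn_in=500, thin=5, seed=11)
        r2 = model.fit(n_rounds=1500, burn_in=500, thin=5, seed=11)
        assert np.array_equal(r1.chain["sigma2_a"], r2.chain["sigma2_a"])
        assert np.array_equal(r1.ebv.to_numpy(), r2.ebv.to_numpy())

    def test_stored_length_and_h2_identity(self, short_fit):
        _, res = short_fit
        assert len(res.chain) == (3000 - 1000) // 5
        s2a = res.chain["sigma2_a"].to_numpy()
        assert np.array_equal(res.chain["h2"].to_numpy(), s2a / (s2a + 1.0))

    def test_liability_signs_match_diagnoses(self, short_fit):
        model, res = short_fit
        assert np.all((res.final_liabilities > 0) == (model.y == 1))

    def test_posterior_mean_h2_not_plugin_of_mean_variance(self, short_fit):
        # Jensen: E[s2/(1+s2)] != E[s2]/(1+E[s2]) for a non-degenerate chain
        _, res = short_fit
        plugin = res.posterior_mean_sigma2_a / (1 + res.posterior_mean_sigma2_a)
        assert res.posterior_mean_h2 != pytest.approx(plugin, abs=1e-6)

    def test_all_affected_rejected(self, population):
        pop, clean = population
        bad = clean.copy()
        bad["y"] = 1
        with pytest.raises(ValueError, match="threshold"):
            ThresholdAnimalModel(bad, pop.pedigree)

    def test_burnin_and_thin_validation(self, population):
        pop, clean = population
        m = ThresholdAnimalModel(clean, pop.pedigree)
        with pytest.raises(ValueError, match="burn_in"):
            m.fit(n_rounds=100, burn_in=100)
        with pytest.raises(ValueError, match="thin"):
            m.fit(n_rounds=100, burn_in=10, thin=0)

    def test_unknown_variance_update_rejected(self, population):
        pop, clean = population
        m = ThresholdAnimalModel(clean, pop.pedigree)
        with pytest.raises(ValueError, match="variance_update"):
            m.fit(n_rounds=200, burn_in=100, variance_update="nope")

    def test_founders_only_pedigree_needs_all_animals_mode(self):
        from liabped import Pedigree

        n = 60
        ped = Pedigree(
            pd.DataFrame(
                {"id": [f"A{i}" for i in range(n)], "sire": [None] * n,
                 "dam": [None] * n, "sex": ["male", "female"] * (n // 2)}
            )
        )
        rng = np.random.default_rng(0)
        clean = pd.DataFrame(
            {
                "animal": ped.ids,
                "y": rng.integers(0, 2, n),
                "sex": ped.table["sex"],
                "age_years": 2,
                "age_continuous": 2.0,
                "diagnosis_year": 2012,
            }
        )
        m = ThresholdAnimalModel(clean, ped, model=1)
        with pytest.raises(ValueError, match="all_animals"):
            m.fit(n_rounds=300, burn_in=100)

    def test_chain_csv_round_trip(self, short_fit, tmp_path):
        _, res = short_fit
        f = tmp_path / "chain.csv"
        res.to_csv(f)
        back = pd.read_csv(f)
        assert list(back.columns) == ["round", "sigma2_a", "h2"]
        assert len(back) == len(res.chain)

    def test_summary_and_trace_plot(self, short_fit, tmp_path):
        _, res = short_fit
        assert "variance update: parents_only" in res.summary()
        fig = res.plot_trace(tmp_path / "trace.png")
        assert (tmp_path / "trace.png").exists()


class TestSamplingBehaviour:
    def test_parents_only_mixes_no_worse_than_all_animals(self):
        """The parents-based variance update must not mix worse than the
        all-animals update on a deep pedigree with single records."""
        pop = simulate(SimulationConfig.sized(700, seed=31))
        clean, _ = clean_records(pop.records, pop.pedigree)
        model = ThresholdAnimalModel(clean, pop.pedigree, model=1)
        kw = dict(n_rounds=16000, burn_in=3000, thin=10, seed=5)
        ess_p = model.fit(variance_update="parents_only", **kw).summarize("sigma2_a").ess
        ess_a = model.fit(variance_update="all_animals", **kw).summarize("sigma2_a").ess
        assert ess_p >= ess_a

    def test_posterior_mean_monotone_in_true_h2(self):
        """Doubling the simulated liability h2 must raise the posterior mean."""
        means = []
        for h2 in (0.2, 0.5, 0.8):
            pop = simulate(SimulationConfig.sized(700, seed=60, h2=h2))
            clean, _ = clean_records(pop.records, pop.pedigree)
            res = ThresholdAnimalModel(clean, pop.pedigree, model=1).fit(
                n_rounds=16000, burn_in=3000, thin=10, seed=6
            )
            means.append(res.posterior_mean_h2)
        assert means[0] < means[1] < means[2]

    def test_null_heritability_recovered_small(self):
        """h2 = 0 data: posterior mean must collapse toward zero."""
        pop = simulate(SimulationConfig.sized(900, seed=61, h2=0.0))
        clean, _ = clean_records(pop.records, pop.pedigree)
        res = ThresholdAnimalModel(clean, pop.pedigree, model=1).fit(
            n_rounds=16000, burn_in=3000, thin=10, seed=7
        )
        assert res.posterior_mean_h2 < 0.15
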