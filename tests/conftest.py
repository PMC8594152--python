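"""Shared fixtures: small hand-built pedigrees and random pedigree generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from liabped import Pedigree, SimulationConfig, simulate


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and their offspring."""
    return Pedigree(
        pd.DataFrame(
            {"id": ["A", "B", "C"], "sire": [None, None, "A"], "dam": [None, None, "B"]}
        )
    )


@pytest.fixture
def inbred_line() -> Pedigree:
    """Sire mated to his own daughter; grand-offspring has F = 0.25."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["S", "D", "X", "Y"],
                "sire": [None, None, "S", "S"],
                "dam": [None, None, "D", "X"],
            }
        )
    )


def random_pedigree(n: int, seed: int, n_founders: int | None = None) -> Pedigree:
    """Random litter-structured pedigree of about n animals (possibly inbred)."""
    rng = np.random.default_rng(seed)
    nf = n_founders or max(8, n // 8)
    rows = [
        {"id": f"F{i}", "sire": None, "dam": None,
         "sex": "male" if i % 2 else "female"}
        for i in range(nf)
    ]
    males = [r["id"] for r in rows if r["sex"] == "male"]
    females = [r["id"] for r in rows if r["sex"] == "female"]
    k = 0
    while len(rows) < n:
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        if sire == dam:
            continue
        for _ in range(int(rng.integers(1, 5))):
            sex = "male" if rng.random() < 0.5 else "female"
            aid = f"X{k}"
            rows.append({"id": aid, "sire": sire, "dam": dam, "sex": sex})
            (males if sex == "male" else females).append(aid)
            k += 1
    return Pedigree(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_population():
    """One simulated population reused by read-only tests."""
    return simulate(SimulationConfig.sized(500, seed=123))
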