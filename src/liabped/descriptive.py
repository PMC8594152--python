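"""Descriptive statistics for a screened binary trait.

Prevalence with a normal-approximation confidence interval, a sex
contingency test, grading proportions among affected animals, and
screening-coverage percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PrevalenceResult",
    "ContingencyTest",
    "prevalence",
    "sex_chi2",
    "grading_summary",
    "coverage",
]


@dataclass
class PrevalenceResult:
    n_affected: int
    n_total: int
    p_hat: float
    ci_low: float
    ci_high: float
    conf: float = 0.95
    method: str = "wald"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ContingencyTest:
    table: np.ndarray
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "table": np.asarray(self.table).tolist(),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


def prevalence(
    n_affected: int, n_total: int, conf: float = 0.95, method: str = "wald"
) -> PrevalenceResult:
    """Sample prevalence with a 95% (by default) confidence interval.

    The default Wald interval is p +/- z * sqrt(p(1-p)/n), lower bound
    clipped at 0, upper at 1; ``method="wilson"`` gives the Wilson score
    interval instead.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_affected <= n_total:
        raise ValueError("need 0 <= n_affected <= n_total")
    p = n_affected / n_total
    z = stats.norm.ppf(0.5 + conf / 2)
    if method == "wald":
        half = z * np.sqrt(p * (1 - p) / n_total)
        lo, hi = p - half, p + half
    elif method == "wilson":
        denom = 1 + z**2 / n_total
        centre = (p + z**2 / (2 * n_total)) / denom
        half = z * np.sqrt(p * (1 - p) / n_total + z**2 / (4 * n_total**2)) / denom
        lo, hi = centre - half, centre + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return PrevalenceResult(
        n_affected=int(n_affected),
        n_total=int(n_total),
        p_hat=p,
        ci_low=max(0.0, lo),
        ci_high=min(1.0, hi),
        conf=conf,
        method=method,
    )


def sex_chi2(table) -> ContingencyTest:
    """Pearson chi-squared test (df=1, no continuity correction) on a 2x2 table.

    Rows are groups (e.g. males/females), columns affected/unaffected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell count")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("a margin of the table is zero")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyTest(table=t.astype(int), chi2=float(chi2), df=int(df), p_value=float(p))


def grading_summary(clean: pd.DataFrame) -> dict:
    """Grade distribution among affected animals.

    Returns counts plus percentages among all affected animals and, for the
    graded classes, percentages among graded animals only.  With no affected
    animals the percentage entries are absent.
    """
    affected = clean[clean["y"] == 1] if "y" in clean.columns else clean[
        clean["final_diagnosis"] == "affected"
    ]
    counts = {
        g: int((affected["final_grade"] == g).sum())
        for g in ("mild", "moderate", "severe")
    }
    counts["ungraded"] = int((affected["final_grade"] == "none").sum())
    out: dict = {"counts": counts, "n_affected": int(len(affected))}
    if len(affected):
        out["pct_among_affected"] = {
            g: 100.0 * c / len(affected) for g, c in counts.items()
        }
        n_graded = len(affected) - counts["ungraded"]
        out["n_graded"] = n_graded
        if n_graded:
            out["pct_among_graded"] = {
                g: 100.0 * counts[g] / n_graded for g in ("mild", "moderate", "severe")
            }
    return out


def coverage(n_screened: int, n_registered: int) -> float:
    """Screening coverage as a percentage of registered animals (or litters)."""
    if n_registered <= 0:
        raise ValueError("n_registered must be positive")
    return 100.0 * n_screened / n_registered
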