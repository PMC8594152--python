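"""Observed-scale to liability-scale heritability conversion, and EBV comparison.

A binary trait analysed by a linear model on 0/1 observations yields a
heritability on the observed scale (h2_o).  Under the threshold model the
trait reflects an underlying Gaussian liability, and Dempster & Lerner's
classic transformation maps the observed-scale estimate to that scale:

    h2_l = h2_o * p * (1 - p) / z**2

where p is the trait frequency and z the standard-normal density at the
threshold corresponding to p.  The standard error scales by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "LiabilityConversion",
    "EBVComparison",
    "z_ordinate",
    "dempster_lerner",
    "compare_ebv",
]


@dataclass
class LiabilityConversion:
    h2_obs: float
    se_obs: float
    p: float
    z_ord: float
    h2_liab: float
    se_liab: float

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        return (
            f"h2 observed {self.h2_obs:.3f} (SE {self.se_obs:.3f}) -> "
            f"liability {self.h2_liab:.3f} (SE {self.se_liab:.3f}) "
            f"at p={self.p:.3f}, z={self.z_ord:.4f}"
        )


@dataclass
class EBVComparison:
    pearson: float
    spearman: float
    n_animals: int

    def to_dict(self) -> dict:
        return asdict(self)


def z_ordinate(p: float) -> float:
    """Standard-normal density at the threshold with upper-tail mass p.

    phi(Phi^-1(1 - p)); evaluated via the inverse survival function so
    extreme frequencies stay finite.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    return float(stats.norm.pdf(stats.norm.isf(p)))


def dempster_lerner(
    h2_obs: float,
    se_obs: float,
    p: float,
    z_override: float | None = None,
) -> LiabilityConversion:
    """Convert an observed-scale heritability (and SE) to the liability scale.

    ``z_override`` substitutes a stated threshold ordinate for the
    full-precision value — useful to reproduce published tables computed
    with a rounded z.
    """
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    z = z_ordinate(p) if z_override is None else float(z_override)
    if z <= 0:
        raise ValueError("threshold ordinate must be positive")
    factor = p * (1 - p) / z**2
    h2_l = h2_obs * factor
    se_l = se_obs * factor
    if h2_l > 1:
        import warnings

        warnings.warn(
            f"liability-scale heritability {h2_l:.3f} exceeds 1", stacklevel=2
        )
    return LiabilityConversion(
        h2_obs=float(h2_obs),
        se_obs=float(se_obs),
        p=float(p),
        z_ord=z,
        h2_liab=float(h2_l),
        se_liab=float(se_l),
    )


def compare_ebv(set1, set2) -> EBVComparison:
    """Pearson and Spearman correlation of two breeding-value sets.

    Accepts pandas Series indexed by animal id (compared on the
    intersection) or plain aligned arrays.
    """
    import pandas as pd

    if isinstance(set1, pd.Series) and isinstance(set2, pd.Series):
        common = set1.index.intersection(set2.index)
        a = set1.loc[common].to_numpy(dtype=float)
        b = set2.loc[common].to_numpy(dtype=float)
    else:
        a = np.asarray(set1, dtype=float)
        b = np.asarray(set2, dtype=float)
        if a.shape != b.shape:
            raise ValueError("EBV arrays must align (or pass id-indexed Series)")
    if len(a) < 3:
        raise ValueError("need at least 3 common animals")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in an EBV set; correlation undefined")
    pear = float(stats.pearsonr(a, b).statistic)
    spear = float(stats.spearmanr(a, b).statistic)
    return EBVComparison(pearson=pear, spearman=spear, n_animals=int(len(a)))
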