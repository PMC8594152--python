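"""Bayesian threshold (liability) animal model via Gibbs sampling.

The binary diagnosis is modelled as the sign of a latent Gaussian
liability l = X beta + a + e with the threshold fixed at 0 and the
residual variance restricted to 1 for identifiability.  Each Gibbs round
cycles through

1. the latent liabilities (truncated normals on the side the diagnosis
   dictates),
2. the fixed effects (joint Gaussian draw),
3. the breeding values (single-site updates over the sparse A-inverse
   neighbourhood, in pedigree code order),
4. the genetic variance, by default from the quadratic form over the
   breeding values of animals that have offspring only — with one record
   per animal this parents-based update shields the variance from the
   degenerate large-variance regime that the exact full conditional
   cannot rule out (see the fit() docstring and docs/methods.md).

Per stored sample the heritability is h2 = s2a / (s2a + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .linear import build_design, MODEL_IDS
from .diagnostics import summarize, PosteriorSummary
from ._gibbs_kernel import gibbs_kernel, ram_kernel

__all__ = ["ThresholdAnimalModel", "GibbsResults"]


@dataclass
class GibbsResults:
    """Stored chain and posterior summaries of a threshold-model run."""

    model: int
    chain: pd.DataFrame          # columns: round, sigma2_a, h2
    beta_samples: np.ndarray     # (n_store, p)
    beta_names: list[str]
    ebv: pd.Series               # posterior-mean breeding values, all animals
    n_rounds: int
    burn_in: int
    thin: int
    seed: int
    variance_update: str
    final_liabilities: np.ndarray = field(repr=False, default=None)
    _summaries: dict = field(default_factory=dict, repr=False)

    def summarize(self, parameter: str = "h2", hpd_level: float = 0.95) -> PosteriorSummary:
        key = (parameter, hpd_level)
        if key not in self._summaries:
            if parameter not in ("h2", "sigma2_a"):
                raise ValueError("parameter must be 'h2' or 'sigma2_a'")
            self._summaries[key] = summarize(
                self.chain[parameter].to_numpy(), name=parameter, hpd_level=hpd_level
            )
        return self._summaries[key]

    @property
    def posterior_mean_h2(self) -> float:
        return float(self.chain["h2"].mean())

    @property
    def posterior_mean_sigma2_a(self) -> float:
        return float(self.chain["sigma2_a"].mean())

    def summary(self) -> str:
        s_va = self.summarize("sigma2_a")
        s_h2 = self.summarize("h2")
        return "\n".join(
            [
                f"Threshold animal model {self.model} (Gibbs sampler)",
                "=" * 56,
                f"rounds {self.n_rounds}, burn-in {self.burn_in}, thin {self.thin}, "
                f"seed {self.seed}; stored {len(self.chain)} samples",
                f"variance update: {self.variance_update}; residual variance fixed at 1",
                "-" * 56,
                "parameter        mean     95% HPD            ESS",
                f"genetic var   {s_va.posterior_mean:7.3f}   "
                f"({s_va.hpd_low:.3f}, {s_va.hpd_high:.3f})   {s_va.ess:8.1f}",
                f"h2            {s_h2.posterior_mean:7.3f}   "
                f"({s_h2.hpd_low:.3f}, {s_h2.hpd_high:.3f})   {s_h2.ess:8.1f}",
            ]
        )

    def plot_trace(self, path=None):
        """Trace plots of h2 and the genetic variance (matplotlib Figure)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
        for ax, col, label in zip(axes, ("h2", "sigma2_a"), ("$h^2$", r"$\sigma_a^2$")):
            ax.plot(self.chain["round"], self.chain[col], lw=0.3)
            ax.set_ylabel(label)
        axes[1].set_xlabel("round")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def to_csv(self, path) -> None:
        self.chain.to_csv(path, index=False)


class ThresholdAnimalModel:
    """Threshold liability animal model for a binary diagnosis.

    Parameters mirror :class:`liabped.LinearAnimalModel`: a one-row-per-
    animal analysis set, a pedigree covering every recorded animal, and
    the fixed-effect structure (model 1, 2 or 3).
    """

    def __init__(
        self,
        clean: pd.DataFrame,
        pedigree: Pedigree,
        model: int = 1,
        min_class_size: int = 1,
    ):
        if model not in MODEL_IDS:
            raise ValueError(f"model must be one of {MODEL_IDS}")
        if clean["animal"].duplicated().any():
            raise ValueError("clean data must hold one row per animal")
        missing = [a for a in clean["animal"] if a not in pedigree]
        if missing:
            raise ValueError(f"{len(missing)} recorded animal(s) absent from pedigree")
        y = clean["y"].to_numpy(dtype=np.int8)
        if y.min() == y.max():
            raise ValueError(
                "all animals share one diagnosis; the threshold is unidentifiable"
            )
        self.clean = clean.reset_index(drop=True)
        self.pedigree = pedigree
        self.model = model
        self.y = y
        self.X, self.beta_names = build_design(self.clean, model, min_class_size)
        self.obs_idx = pedigree.positions(self.clean["animal"])

    def fit(
        self,
        n_rounds: int = 1_100_000,
        burn_in: int = 100_000,
        thin: int = 10,
        seed: int = 0,
        variance_update: str = "parents_only",
        prior: str = "uniform_h2",
        prior_nu: float = 1.0,
        prior_s2: float = 0.1,
        beta_prior_sd: float = 5.0,
        sigma2_a_init: float = 1.0,
    ) -> GibbsResults:
        """Run the Gibbs sampler and return the stored chain.

        The default chain length matches a production run (1,100,000
        rounds, 100,000 burn-in, thinning 10); pass shorter values for
        exploratory work.

        ``variance_update`` selects the genetic-variance sampling scheme:

        * ``"parents_only"`` (default): quadratic form over the breeding
          values of animals with offspring, using the inverse relationship
          matrix of their subset pedigree.  With one record per animal this
          shields the variance update from the degenerate large-variance
          regime (where the model turns into a saturated family-sign fit)
          and is the scheme of record for this analysis.
        * ``"all_animals"``: the textbook full conditional over every
          breeding value; prone to drifting into the degenerate regime.
        * ``"reduced"``: an exact reduced-animal-model sampler (non-parent
          breeding values integrated out, slice updates for the variance).
          It samples the mathematically exact posterior — and thereby
          exposes its degeneracy on single-record data; useful for
          validation on small, well-conditioned data sets.

        The genetic-variance prior defaults to ``"uniform_h2"``: uniform
        on the heritability h2 = s2a/(s2a+1), i.e. p(s2a) = (1+s2a)^-2 — a
        proper, knob-free reference prior whose tail keeps chains out of
        the degenerate large-variance regime that single-record binary
        data cannot rule out.  ``prior="inv_chi2"`` selects a scaled
        inverse chi-square with ``prior_nu``/``prior_s2`` (``prior_nu=-2,
        prior_s2=0`` is the improper flat-on-s2a prior).  Fixed effects
        carry independent N(0, beta_prior_sd^2) priors so that
        extreme-category classes (all-affected or all-unaffected cells)
        cannot drive their effects, and with them the genetic variance,
        to infinity.
        """
        if not burn_in < n_rounds:
            raise ValueError("burn_in must be smaller than n_rounds")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        if variance_update not in ("parents_only", "all_animals", "reduced"):
            raise ValueError(
                "variance_update must be 'parents_only', 'all_animals' or 'reduced'"
            )
        if prior not in ("uniform_h2", "inv_chi2"):
            raise ValueError("prior must be 'uniform_h2' or 'inv_chi2'")
        prior_kind = 1 if prior == "uniform_h2" else 0

        ped = self.pedigree
        beta_prec = 1.0 / beta_prior_sd**2
        if variance_update == "reduced":
            s2a, h2, betas, ebv, liab = self._run_reduced(
                n_rounds, burn_in, thin, seed, prior_kind, prior_nu, prior_s2,
                beta_prec, sigma2_a_init,
            )
        else:
            s2a, h2, betas, ebv, liab = self._run_full(
                n_rounds, burn_in, thin, seed, prior_kind, prior_nu, prior_s2,
                beta_prec, sigma2_a_init,
                parents_only=variance_update == "parents_only",
            )
        n_store = (n_rounds - burn_in) // thin
        rounds = burn_in + thin * np.arange(1, n_store + 1)
        chain = pd.DataFrame({"round": rounds, "sigma2_a": s2a, "h2": h2})
        if n_store < 100:
            warnings.warn(
                f"only {n_store} stored samples; posterior summaries need >= 100",
                stacklevel=2,
            )
        return GibbsResults(
            model=self.model,
            chain=chain,
            beta_samples=betas,
            beta_names=list(self.beta_names),
            ebv=ebv,
            n_rounds=n_rounds,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            variance_update=variance_update,
            final_liabilities=liab,
        )

    # ------------------------------------------------------------------
    def _run_full(self, n_rounds, burn_in, thin, seed, prior_kind, prior_nu,
                  prior_s2, beta_prec, s2a_init, parents_only=True):
        """Full animal-model sampler: breeding values for every pedigree
        animal.  With ``parents_only`` the genetic-variance update uses the
        quadratic form over animals with offspring and the inverse
        relationship matrix of their subset pedigree; otherwise it uses all
        animals (the textbook full conditional)."""
        ped = self.pedigree
        ainv = ped.a_inverse().tocsr()
        rec_of = np.full(ped.n, -1, dtype=np.int64)
        rec_of[self.obs_idx] = np.arange(len(self.y))
        XtX = self.X.T @ self.X + beta_prec * np.eye(self.X.shape[1])
        XtX_L = np.linalg.cholesky(XtX)
        if parents_only:
            sub, _ = ped.parent_subpedigree()
            if sub.n == 0:
                raise ValueError(
                    "no animal has offspring; use variance_update='all_animals'"
                )
            if sub.n + prior_nu <= 0:
                raise ValueError(
                    f"parent subset too small ({sub.n}) for prior df {prior_nu}"
                )
            parent_pos = ped.positions(sub.ids).astype(np.int64)
            par_inv = sub.a_inverse().tocsr()
            par_indptr = par_inv.indptr.astype(np.int64)
            par_indices = par_inv.indices.astype(np.int64)
            par_data = par_inv.data
        else:
            if ped.n + prior_nu <= 0:
                raise ValueError("pedigree too small for the prior degrees of freedom")
            parent_pos = np.zeros(0, dtype=np.int64)
            par_indptr = np.zeros(1, dtype=np.int64)
            par_indices = np.zeros(0, dtype=np.int64)
            par_data = np.zeros(0)
        s2a, h2, betas, ebv_mean, liab = gibbs_kernel(
            np.int64(seed),
            np.int64(n_rounds),
            np.int64(burn_in),
            np.int64(thin),
            self.y,
            self.obs_idx.astype(np.int64),
            np.ascontiguousarray(self.X),
            XtX_L,
            ainv.indptr.astype(np.int64),
            ainv.indices.astype(np.int64),
            ainv.data,
            par_indptr,
            par_indices,
            par_data,
            parent_pos,
            rec_of,
            np.int64(prior_kind),
            float(prior_nu),
            float(prior_s2),
            parents_only,
            float(s2a_init),
        )
        ebv = pd.Series(ebv_mean, index=ped.ids, name="ebv")
        return s2a, h2, betas, ebv, liab

    def _run_reduced(self, n_rounds, burn_in, thin, seed, prior_kind, prior_nu,
                     prior_s2, beta_prec, s2a_init):
        """Reduced animal model: breeding values only for animals with
        offspring; recorded non-parents enter through liabilities with
        Mendelian-sampling variance folded into the residual; the genetic
        variance is slice-sampled from its exact full conditional."""
        ped = self.pedigree
        sub, _ = ped.parent_subpedigree()
        if sub.n == 0:
            raise ValueError(
                "no animal has offspring; use variance_update='all_animals'"
            )
        parent_pos = ped.positions(sub.ids)          # subset row -> pedigree pos
        par_inv = sub.a_inverse().tocsr()
        nP = sub.n
        par_idx_of = np.full(ped.n, -1, dtype=np.int64)
        par_idx_of[parent_pos] = np.arange(nP)

        n = len(self.y)
        F = ped.inbreeding()
        is_par = np.zeros(n, dtype=np.int8)
        par_of_rec = np.full(n, -1, dtype=np.int64)
        np_sire = np.full(n, -1, dtype=np.int64)
        np_dam = np.full(n, -1, dtype=np.int64)
        d_np = np.ones(n)
        own_rec = np.full(nP, -1, dtype=np.int64)
        off_lists: list[list[tuple[int, int]]] = [[] for _ in range(nP)]

        for r, pos in enumerate(self.obs_idx):
            pi = par_idx_of[pos]
            if pi >= 0:
                is_par[r] = 1
                par_of_rec[r] = pi
                own_rec[pi] = r
                continue
            s, d = ped.sire_idx[pos], ped.dam_idx[pos]
            si = par_idx_of[s] if s >= 0 else -1
            di = par_idx_of[d] if d >= 0 else -1
            np_sire[r] = si
            np_dam[r] = di
            if si >= 0 and di >= 0:
                d_np[r] = 0.5 - 0.25 * (F[s] + F[d])
            elif si >= 0 or di >= 0:
                p = s if si >= 0 else d
                d_np[r] = 0.75 - 0.25 * F[p]
            else:
                d_np[r] = 1.0
            if si >= 0:
                off_lists[si].append((r, di))
            if di >= 0:
                off_lists[di].append((r, si))

        off_indptr = np.zeros(nP + 1, dtype=np.int64)
        for i in range(nP):
            off_indptr[i + 1] = off_indptr[i] + len(off_lists[i])
        off_rec = np.empty(off_indptr[-1], dtype=np.int64)
        off_mate = np.empty(off_indptr[-1], dtype=np.int64)
        k = 0
        for i in range(nP):
            for r, m in off_lists[i]:
                off_rec[k] = r
                off_mate[k] = m
                k += 1

        s2a, h2, betas, ebv_par, ebv_rec, liab = ram_kernel(
            np.int64(seed),
            np.int64(n_rounds),
            np.int64(burn_in),
            np.int64(thin),
            self.y,
            np.ascontiguousarray(self.X),
            is_par,
            par_of_rec,
            np_sire,
            np_dam,
            d_np,
            par_inv.indptr.astype(np.int64),
            par_inv.indices.astype(np.int64),
            par_inv.data,
            own_rec,
            off_indptr,
            off_rec,
            off_mate,
            np.int64(prior_kind),
            float(prior_nu),
            float(prior_s2),
            float(beta_prec),
            float(s2a_init),
        )
        # assemble posterior-mean genetic values for every pedigree animal:
        # parents directly, recorded non-parents from the kernel, unrecorded
        # non-parents as the mean parent average
        ebv_all = np.zeros(ped.n)
        ebv_all[parent_pos] = ebv_par
        rec_mask = np.zeros(ped.n, dtype=bool)
        rec_mask[self.obs_idx] = True
        ebv_all[self.obs_idx] = np.where(
            is_par == 1, ebv_all[self.obs_idx], ebv_rec
        )
        for pos in range(ped.n):
            if par_idx_of[pos] >= 0 or rec_mask[pos]:
                continue
            s, d = ped.sire_idx[pos], ped.dam_idx[pos]
            g = 0.0
            if s >= 0:
                g += 0.5 * ebv_all[s]
            if d >= 0:
                g += 0.5 * ebv_all[d]
            ebv_all[pos] = g
        ebv = pd.Series(ebv_all, index=ped.ids, name="ebv")
        return s2a, h2, betas, ebv, liab
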