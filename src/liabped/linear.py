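"""Linear animal model fitted by AI-REML, and the bivariate sex model.

The linear animal model treats the 0/1 diagnosis y directly as a Gaussian
response:

    y = X beta + Z a + e,   a ~ N(0, s2a * A),   e ~ N(0, s2e * I)

with A the pedigree additive relationship matrix.  Three fixed-effect
structures are supported:

* model 1: Sex + Age (integer-year classes)
* model 2: Sex + R_Year (diagnosis-year classes) + Age
* model 3: Sex + R_Year + b * C_Age (continuous age covariate)

Variance components are estimated by average-information REML with an
EM-style fixed-point fallback whenever a Newton step leaves the parameter
space; standard errors come from the inverse average-information matrix,
the heritability SE by the delta method, and breeding values (BLUP/EBV)
for every pedigree animal from the converged fit.

With one record per animal the marginal covariance of the records,
V = s2a * A_obs + s2e * I, is only n x n, so the restricted likelihood,
its exact gradient and the AI matrix are evaluated from a dense Cholesky
factorisation of V; the resulting EBVs are algebraically the mixed-model
equation solutions.

``SexBivariateModel`` treats the diagnosis of each sex as a separate trait
(each animal records exactly one trait, so the residual covariance is
structurally zero) and estimates the genetic correlation between them by
direct REML maximisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .pedigree import Pedigree
from .conversion import dempster_lerner, LiabilityConversion

__all__ = ["LinearAnimalModel", "REMLResults", "SexBivariateModel", "BivariateResults"]

MODEL_IDS = (1, 2, 3)


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------

def _merge_small_classes(values: pd.Series, min_size: int) -> pd.Series:
    """Merge factor levels with < min_size records into the nearest level.

    Levels must be numeric (years).  min_size=1 leaves classes untouched.
    """
    if min_size <= 1:
        return values
    vals = values.copy()
    while True:
        counts = vals.value_counts()
        small = counts[counts < min_size]
        if small.empty or len(counts) == 1:
            break
        lvl = small.index[0]
        others = np.array([v for v in counts.index if v != lvl])
        nearest = others[np.argmin(np.abs(others - lvl))]
        vals = vals.replace(lvl, nearest)
    return vals


def build_design(
    clean: pd.DataFrame, model: int, min_class_size: int = 1
) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effects design for one of the three models.

    Class effects enter as dummy columns with the first level dropped (an
    intercept carries the reference cell); model 3's continuous age is
    centred.  Factors left with a single level are dropped with a warning;
    any remaining exact collinearity is removed by pivoted QR.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"model must be one of {MODEL_IDS}")
    n = len(clean)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    def add_factor(series: pd.Series, label: str) -> None:
        levels = sorted(series.unique())
        if len(levels) < 2:
            warnings.warn(f"factor {label} has a single level; dropped", stacklevel=3)
            return
        for lvl in levels[1:]:
            cols.append((series == lvl).to_numpy(dtype=float))
            names.append(f"{label}[{lvl}]")

    add_factor(clean["sex"].astype(str), "sex")
    if model == 2 or model == 3:
        add_factor(clean["diagnosis_year"].astype(int), "year")
    if model == 1 or model == 2:
        age = _merge_small_classes(clean["age_years"].astype(int), min_class_size)
        add_factor(age, "age")
    if model == 3:
        cage = clean["age_continuous"].to_numpy(dtype=float)
        cols.append(cage - cage.mean())
        names.append("c_age")

    X = np.column_stack(cols)
    # drop exactly collinear columns (pivoted QR)
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep_rank = int((diag > diag[0] * 1e-10).sum())
    if keep_rank < X.shape[1]:
        keep = np.sort(piv[:keep_rank])
        dropped = [names[j] for j in piv[keep_rank:]]
        warnings.warn(f"dropped collinear design column(s): {dropped}", stacklevel=2)
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


# ----------------------------------------------------------------------
# REML machinery
# ----------------------------------------------------------------------

def _reml_pieces(theta, y, X, A_obs):
    """Restricted log-likelihood (up to a constant) and working quantities."""
    s2a, s2e = theta
    n = len(y)
    V = s2a * A_obs + s2e * np.eye(n)
    L = linalg.cholesky(V, lower=True)
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    ViX = linalg.cho_solve((L, True), X)
    Viy = linalg.cho_solve((L, True), y)
    XtViX = X.T @ ViX
    Lx = linalg.cholesky(XtViX, lower=True)
    logdetX = 2.0 * np.log(np.diag(Lx)).sum()
    beta = linalg.cho_solve((Lx, True), X.T @ Viy)
    Py = Viy - ViX @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (logdetV + logdetX + yPy)
    return ll, L, ViX, XtViX, Lx, beta, Py


def _reml_loglik(theta, y, X, A_obs) -> float:
    return _reml_pieces(theta, y, X, A_obs)[0]


def _grad_ai(theta, y, X, A_obs, L, ViX, Lx, Py):
    """Score vector and average-information matrix for (s2a, s2e)."""
    n = len(y)
    Vi, info = linalg.lapack.dpotri(L, lower=1)
    if info != 0:  # pragma: no cover - fallback path
        Vi = linalg.cho_solve((L, True), np.eye(n))
    else:
        Vi = Vi + np.tril(Vi, -1).T
    W = linalg.cho_solve((Lx, True), ViX.T)
    P = Vi - ViX @ W
    trPA = float(np.sum(P * A_obs))  # A symmetric
    trP = float(np.trace(P))
    fa = A_obs @ Py
    fe = Py
    yPAPy = float(fa @ Py)
    yPPy = float(fe @ Py)
    score = np.array([-0.5 * (trPA - yPAPy), -0.5 * (trP - yPPy)])
    Pfa = P @ fa
    ai = 0.5 * np.array(
        [[fa @ Pfa, fe @ Pfa], [fe @ Pfa, fe @ (P @ fe)]]
    )
    return score, ai, {"trPA": trPA, "trP": trP, "yPAPy": yPAPy, "yPPy": yPPy}


@dataclass
class REMLResults:
    """AI-REML estimates for one linear animal model."""

    model: int
    sigma2_a: float
    sigma2_e: float
    se_sigma2_a: float
    se_sigma2_e: float
    h2_obs: float
    se_h2_obs: float
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    boundary: bool
    beta: np.ndarray
    beta_names: list[str]
    ebv: pd.Series
    cov_theta: np.ndarray
    n_records: int
    n_pedigree: int
    prevalence: float = field(default=np.nan)

    def to_liability(
        self, p: float | None = None, z_override: float | None = None
    ) -> LiabilityConversion:
        """Dempster-Lerner conversion of h2 (and SE) to the liability scale."""
        p = self.prevalence if p is None else p
        return dempster_lerner(self.h2_obs, self.se_h2_obs, p, z_override=z_override)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "sigma2_a": self.sigma2_a,
            "sigma2_e": self.sigma2_e,
            "se_sigma2_a": self.se_sigma2_a,
            "se_sigma2_e": self.se_sigma2_e,
            "h2_obs": self.h2_obs,
            "se_h2_obs": self.se_h2_obs,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "boundary": self.boundary,
            "n_records": self.n_records,
            "n_pedigree": self.n_pedigree,
        }

    def summary(self) -> str:
        lines = [
            f"Linear animal model {self.model} (AI-REML)",
            "=" * 44,
            f"records: {self.n_records}   pedigree animals: {self.n_pedigree}",
            f"converged: {self.converged} in {self.n_iter} iterations "
            f"(|grad| = {self.grad_norm:.2e})"
            + ("   [variance at boundary]" if self.boundary else ""),
            "-" * 44,
            f"genetic variance   {self.sigma2_a:8.4f}  ({self.se_sigma2_a:.4f})",
            f"residual variance  {self.sigma2_e:8.4f}  ({self.se_sigma2_e:.4f})",
            f"h2 (observed 0/1)  {self.h2_obs:8.4f}  ({self.se_h2_obs:.4f})",
            "-" * 44,
            "fixed effects:",
        ]
        for nm, b in zip(self.beta_names, self.beta):
            lines.append(f"  {nm:<18} {b:9.4f}")
        return "\n".join(lines)


class LinearAnimalModel:
    """Gaussian animal model on a 0/1 diagnosis, one record per animal.

    Parameters
    ----------
    clean : DataFrame
        One-row-per-animal analysis set (see :func:`liabped.clean_records`):
        columns ``animal``, ``y``, ``sex``, ``age_years``,
        ``age_continuous``, ``diagnosis_year``.
    pedigree : Pedigree
        Must contain every recorded animal.
    model : {1, 2, 3}
        Fixed-effect structure (see module docstring).
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
        missing = [a for a in clean["animal"] if a not in pedigree]
        if missing:
            raise ValueError(
                f"{len(missing)} recorded animal(s) absent from pedigree, "
                f"e.g. {missing[:5]}"
            )
        if clean["animal"].duplicated().any():
            raise ValueError("clean data must hold one row per animal")
        self.clean = clean.reset_index(drop=True)
        self.pedigree = pedigree
        self.model = model
        self.y = self.clean["y"].to_numpy(dtype=float)
        if len(np.unique(self.y)) < 2:
            raise ValueError("response is constant; variance components unidentifiable")
        self.X, self.beta_names = build_design(self.clean, model, min_class_size)
        self.obs_idx = pedigree.positions(self.clean["animal"])

    # .................................................................
    def loglik(self, sigma2_a: float, sigma2_e: float) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        A_obs = self._A_obs()
        return _reml_loglik((sigma2_a, sigma2_e), self.y, self.X, A_obs)

    def _A_obs(self) -> np.ndarray:
        A = self.pedigree.relationship_matrix()
        return A[np.ix_(self.obs_idx, self.obs_idx)]

    # .................................................................
    def fit(
        self,
        max_iter: int = 200,
        tol_param: float = 1e-8,
        tol_grad: float = 1e-6,
        start: tuple[float, float] | None = None,
        verbose: bool = False,
    ) -> REMLResults:
        y, X = self.y, self.X
        A_obs = self._A_obs()
        vy = float(np.var(y))
        floor = max(vy, 1e-8) * 1e-8
        theta = np.array(start) if start is not None else np.array([vy / 2, vy / 2])

        ll, L, ViX, XtViX, Lx, beta, Py = _reml_pieces(theta, y, X, A_obs)
        score = np.full(2, np.inf)
        ai = np.eye(2)
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            score, ai, tr = _grad_ai(theta, y, X, A_obs, L, ViX, Lx, Py)
            gnorm = float(np.linalg.norm(score))
            # AI (Newton) proposal with EM-style fixed-point fallback
            try:
                step = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                step = None
            new = None
            if step is not None:
                cand = theta + step
                frac = 1.0
                for _ in range(12):
                    cand = theta + frac * step
                    if (cand > floor).all():
                        ll_c = _reml_loglik(cand, y, X, A_obs)
                        if ll_c >= ll - 1e-10:
                            new = cand
                            break
                    frac *= 0.5
            if new is None:
                # fixed-point update: s2_i <- s2_i * yPViPy / tr(PVi)
                new = np.array(
                    [
                        theta[0] * tr["yPAPy"] / max(tr["trPA"], 1e-300),
                        theta[1] * tr["yPPy"] / max(tr["trP"], 1e-300),
                    ]
                )
                new = np.maximum(new, floor)
            rel = float(np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1e-12)))
            theta = new
            ll, L, ViX, XtViX, Lx, beta, Py = _reml_pieces(theta, y, X, A_obs)
            if verbose:
                print(f"iter {it:3d}  ll={ll:.6f}  theta={theta}  |g|={gnorm:.2e}")
            at_floor = bool((theta <= floor * 1.0001).any())
            if rel < tol_param and (gnorm < tol_grad or at_floor):
                converged = True
                break

        score, ai, _ = _grad_ai(theta, y, X, A_obs, L, ViX, Lx, Py)
        gnorm = float(np.linalg.norm(score))
        if not converged:
            warnings.warn(
                f"AI-REML did not converge in {max_iter} iterations "
                f"(|grad| = {gnorm:.2e})",
                stacklevel=2,
            )
        boundary = bool((theta <= floor * 10).any())
        if boundary:
            warnings.warn("a variance component is pinned at the boundary", stacklevel=2)
        try:
            cov = np.linalg.inv(ai)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        s2a, s2e = map(float, theta)
        h2 = s2a / (s2a + s2e)
        g = np.array([s2e, -s2a]) / (s2a + s2e) ** 2
        se_h2 = float(np.sqrt(max(g @ cov @ g, 0.0)))

        # EBVs for every pedigree animal: a_hat = s2a * A[:, obs] Py
        A_full = self.pedigree.relationship_matrix()
        a_hat = s2a * (A_full[:, self.obs_idx] @ Py)
        ebv = pd.Series(a_hat, index=self.pedigree.ids, name="ebv")

        return REMLResults(
            model=self.model,
            sigma2_a=s2a,
            sigma2_e=s2e,
            se_sigma2_a=float(np.sqrt(max(cov[0, 0], 0.0))),
            se_sigma2_e=float(np.sqrt(max(cov[1, 1], 0.0))),
            h2_obs=float(h2),
            se_h2_obs=se_h2,
            loglik=float(ll),
            converged=converged,
            n_iter=it,
            grad_norm=gnorm,
            boundary=boundary,
            beta=np.asarray(beta, dtype=float),
            beta_names=list(self.beta_names),
            ebv=ebv,
            cov_theta=cov,
            n_records=len(y),
            n_pedigree=self.pedigree.n,
            prevalence=float(np.mean(self.y)),
        )


# ----------------------------------------------------------------------
# bivariate sex model
# ----------------------------------------------------------------------

@dataclass
class BivariateResults:
    """Genetic correlation between the trait expressed in each sex."""

    sigma2_a: tuple[float, float]
    sigma_a12: float
    r_g: float
    se_r_g: float
    sigma2_e: tuple[float, float]
    loglik: float
    converged: bool
    n_records: tuple[int, int]

    def summary(self) -> str:
        return (
            "Bivariate sex-as-two-traits animal model (REML)\n"
            + "=" * 48
            + f"\nrecords: males {self.n_records[0]}, females {self.n_records[1]}"
            f"\ngenetic variance (m, f): {self.sigma2_a[0]:.4f}, {self.sigma2_a[1]:.4f}"
            f"\ngenetic covariance:      {self.sigma_a12:.4f}"
            f"\ngenetic correlation r_g: {self.r_g:.3f} ({self.se_r_g:.3f})"
            f"\nresidual variance (m,f): {self.sigma2_e[0]:.4f}, {self.sigma2_e[1]:.4f}"
            "\nresidual covariance fixed at 0 (no animal records both traits)"
        )


class SexBivariateModel:
    """Two-trait animal model with the diagnosis per sex as separate traits.

    Every animal has a record for exactly one trait, so the residual
    covariance is structurally zero and fixed there.  Fixed effects are
    those of the chosen univariate model, nested within trait, with sex
    itself absorbed by the per-trait intercepts.
    """

    def __init__(self, clean: pd.DataFrame, pedigree: Pedigree, model: int = 1):
        sexes = set(clean["sex"])
        if not {"male", "female"} <= sexes:
            raise ValueError("both sexes must be present with records")
        keep = clean[clean["sex"].isin(["male", "female"])].reset_index(drop=True)
        self.clean = keep
        self.pedigree = pedigree
        self.model = model
        self.trait = (keep["sex"] == "female").to_numpy(dtype=int)  # 0 = male
        self.y = keep["y"].to_numpy(dtype=float)
        self.obs_idx = pedigree.positions(keep["animal"])
        # per-trait designs (model's fixed effects minus Sex), block-nested
        Xs = []
        names: list[str] = []
        for t, label in ((0, "m"), (1, "f")):
            sub = keep[self.trait == t].copy()
            sub["sex"] = label  # single level; Sex factor drops within trait
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Xt, nm = build_design(sub, model)
            Xs.append(Xt)
            names += [f"{label}:{x}" for x in nm]
        n = len(keep)
        p0, p1 = Xs[0].shape[1], Xs[1].shape[1]
        X = np.zeros((n, p0 + p1))
        X[self.trait == 0, :p0] = Xs[0]
        X[self.trait == 1, p0:] = Xs[1]
        self.X = X
        self.beta_names = names
        A = pedigree.relationship_matrix()
        self.A_obs = A[np.ix_(self.obs_idx, self.obs_idx)]

    # parameterisation: (log s2a_m, log s2a_f, atanh rg, log s2e_m, log s2e_f)
    def _unpack(self, u):
        s2a1, s2a2 = np.exp(u[0]), np.exp(u[1])
        rg = np.tanh(u[2])
        s2e1, s2e2 = np.exp(u[3]), np.exp(u[4])
        return s2a1, s2a2, rg, s2e1, s2e2

    def _neg_loglik(self, u) -> float:
        s2a1, s2a2, rg, s2e1, s2e2 = self._unpack(u)
        t = self.trait
        g = np.where(t == 0, np.sqrt(s2a1), np.sqrt(s2a2))
        # genetic covariance kernel: G0[ti,tj] * A = (g_i g_j) * (rg off-diag)
        corr = np.where(t[:, None] == t[None, :], 1.0, rg)
        V = (g[:, None] * g[None, :]) * corr * self.A_obs
        V[np.diag_indices_from(V)] += np.where(t == 0, s2e1, s2e2)
        try:
            L = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError:
            return 1e12
        ViX = linalg.cho_solve((L, True), self.X)
        Viy = linalg.cho_solve((L, True), self.y)
        XtViX = self.X.T @ ViX
        try:
            Lx = linalg.cholesky(XtViX, lower=True)
        except linalg.LinAlgError:
            return 1e12
        beta = linalg.cho_solve((Lx, True), self.X.T @ Viy)
        yPy = float(self.y @ Viy - (self.X.T @ Viy) @ beta)
        ll = -0.5 * (
            2 * np.log(np.diag(L)).sum() + 2 * np.log(np.diag(Lx)).sum() + yPy
        )
        return -ll

    def fit(self, start_h2: float = 0.2, start_rg: float = 0.0) -> BivariateResults:
        vy = float(np.var(self.y))
        u0 = np.array(
            [
                np.log(vy * start_h2),
                np.log(vy * start_h2),
                np.arctanh(np.clip(start_rg, -0.99, 0.99)),
                np.log(vy * (1 - start_h2)),
                np.log(vy * (1 - start_h2)),
            ]
        )
        res = optimize.minimize(
            self._neg_loglik, u0, method="BFGS",
            options={"gtol": 1e-6, "maxiter": 500},
        )
        if not np.isfinite(res.fun) or res.fun > 1e11:
            res = optimize.minimize(
                self._neg_loglik, u0, method="Nelder-Mead",
                options={"maxiter": 3000, "xatol": 1e-8, "fatol": 1e-10},
            )
        u = res.x
        s2a1, s2a2, rg, s2e1, s2e2 = self._unpack(u)
        # SE of r_g: numerical Hessian in the unconstrained space, delta method
        se_rg = np.nan
        f0 = self._neg_loglik(u)
        try:
            h = 1e-4
            k = len(u)
            H = np.zeros((k, k))
            for i in range(k):
                for j in range(i, k):
                    ei = np.eye(k)[i] * h
                    ej = np.eye(k)[j] * h
                    H[i, j] = H[j, i] = (
                        self._neg_loglik(u + ei + ej)
                        - self._neg_loglik(u + ei - ej)
                        - self._neg_loglik(u - ei + ej)
                        + self._neg_loglik(u - ei - ej)
                    ) / (4 * h * h)
            cov_u = np.linalg.inv(H)
            se_u2 = np.sqrt(max(cov_u[2, 2], 0.0))
            se_rg = float((1 - rg**2) * se_u2)  # d tanh(u)/du = 1 - tanh^2
        except np.linalg.LinAlgError:
            pass
        return BivariateResults(
            sigma2_a=(float(s2a1), float(s2a2)),
            sigma_a12=float(rg * np.sqrt(s2a1 * s2a2)),
            r_g=float(rg),
            se_r_g=se_rg,
            sigma2_e=(float(s2e1), float(s2e2)),
            loglik=float(-res.fun),
            converged=bool(np.isfinite(f0) and f0 < 1e11),
            n_records=(int((self.trait == 0).sum()), int((self.trait == 1).sum())),
        )
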