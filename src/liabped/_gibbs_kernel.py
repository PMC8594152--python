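"""Compiled inner loop of the threshold-model Gibbs sampler.

Everything here is numba-jitted and operates on plain arrays: truncated
normal draws by exact rejection sampling, small triangular solves for the
fixed-effect block, single-site breeding-value updates over the sparse
rows of the relationship-matrix inverse, and the scaled inverse chi-square
draw for the genetic variance.  The RNG is numba's own; seeding happens
inside the kernel, so a given seed reproduces the chain bit for bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# switch point between plain normal rejection and Robert's exponential
# rejection for lower-truncated standard normal draws
_TAIL_SWITCH = 0.45


@njit(cache=True, inline="always")
def _randu() -> float:
    # uniform on (0, 1]; avoids log(0)
    return 1.0 - np.random.random()


@njit(cache=True)
def _trunc_std_normal_lower(alpha: float) -> float:
    """Draw z ~ N(0,1) conditional on z > alpha (exact rejection)."""
    if alpha <= _TAIL_SWITCH:
        while True:
            z = np.random.standard_normal()
            if z > alpha:
                return z
    lam = 0.5 * (alpha + np.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha - np.log(_randu()) / lam
        d = z - lam
        if np.log(_randu()) <= -0.5 * d * d:
            return z


@njit(cache=True)
def _chol_solve(L: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Solve (L L^T) x = v for small dense lower-triangular L."""
    p = L.shape[0]
    w = np.empty(p)
    for i in range(p):
        s = v[i]
        for j in range(i):
            s -= L[i, j] * w[j]
        w[i] = s / L[i, i]
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = w[i]
        for j in range(i + 1, p):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _solve_lower_T(L: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Solve L^T x = z (back substitution)."""
    p = L.shape[0]
    x = np.empty(p)
    for i in range(p - 1, -1, -1):
        s = z[i]
        for j in range(i + 1, p):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _csr_quad_form(indptr, indices, data, v) -> float:
    """v^T Q v for CSR Q."""
    total = 0.0
    for i in range(len(v)):
        row = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            row += data[k] * v[indices[k]]
        total += v[i] * row
    return total


@njit(cache=True)
def _chol_small(M: np.ndarray) -> np.ndarray:
    """In-place-free Cholesky of a small dense SPD matrix."""
    p = M.shape[0]
    L = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1):
            s = M[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L


@njit(cache=True)
def _log_sigma2_conditional(
    t, ss_p, n_p, r_np, d_np, prior_kind, nu, s2_prior,
):
    """Log full conditional of t = log(sigma2_a) in the reduced model.

    Terms: parents' Gaussian prior quadratic, recorded non-parents'
    marginal liability residuals (variance 1 + d*sigma2), and the
    scaled-inverse-chi-square prior (including the Jacobian of the log
    transform; nu = -2, S2 = 0 reproduces a flat prior on sigma2).
    """
    s2 = np.exp(t)
    out = -0.5 * n_p * t - 0.5 * ss_p / s2
    for j in range(r_np.shape[0]):
        v = 1.0 + d_np[j] * s2
        out += -0.5 * np.log(v) - 0.5 * r_np[j] * r_np[j] / v
    if prior_kind == 0:
        out += -0.5 * nu * t - 0.5 * nu * s2_prior / s2
    else:
        # uniform on h2: p(s2) = (1+s2)^-2, plus the Jacobian e^t
        out += t - 2.0 * np.log1p(s2)
    return out


@njit(cache=True)
def ram_kernel(
    seed,
    n_rounds,
    burn_in,
    thin,
    y,             # (n,) int8 diagnoses, one record per recorded animal
    X,             # (n, p) fixed-effect design
    is_par,        # (n,) int8: record belongs to an animal with offspring
    par_of_rec,    # (n,) int64: parent-vector index of the record's animal (-1)
    np_sire,       # (n,) int64: parent-vector index of the record's sire (-1)
    np_dam,        # (n,) int64: likewise for the dam
    d_np,          # (n,) Mendelian-sampling variance coefficient (non-parents)
    pp_indptr,
    pp_indices,
    pp_data,       # CSR inverse relationship matrix of the parent subset
    own_rec,       # (nP,) record index of each parent, -1 if unrecorded
    off_indptr,    # (nP+1,) offspring adjacency: recorded non-parent children
    off_rec,       # record index of each such child
    off_mate,      # parent-vector index of the other parent (-1 unknown)
    prior_kind,    # 0: scaled inverse chi-square(nu, s2); 1: uniform on h2
    nu,
    s2_prior,
    beta_prec,
    sigma2_a_init,
):
    """Threshold-model Gibbs sampler on the reduced animal model.

    Breeding values are kept only for animals with offspring; recorded
    non-parents contribute through liabilities whose residual variance is
    1 + d*sigma2_a (Mendelian deviation integrated out).  sigma2_a is
    updated by slice sampling on log(sigma2_a) from its exact full
    conditional.  Residual variance is fixed at 1; threshold at 0.

    Returns (sigma2_a chain, h2 chain, beta chain, posterior-mean genetic
    values of parents, posterior-mean genetic values of records, final
    liabilities).
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    nP = own_rec.shape[0]
    n_store = (n_rounds - burn_in) // thin

    out_s2a = np.empty(n_store)
    out_h2 = np.empty(n_store)
    out_beta = np.empty((n_store, p))
    ebv_par_sum = np.zeros(nP)
    ebv_rec_sum = np.zeros(n)

    beta = np.zeros(p)
    a = np.zeros(nP)
    liab = np.zeros(n)
    xb = np.zeros(n)
    s2a = sigma2_a_init
    stored = 0

    mean_rec = np.zeros(n)  # conditional liability mean per record
    var_rec = np.ones(n)    # conditional liability variance per record

    for rnd in range(1, n_rounds + 1):
        # conditional mean/variance of each record's liability
        for i in range(n):
            if is_par[i] == 1:
                mean_rec[i] = xb[i] + a[par_of_rec[i]]
                var_rec[i] = 1.0
            else:
                g = 0.0
                if np_sire[i] >= 0:
                    g += 0.5 * a[np_sire[i]]
                if np_dam[i] >= 0:
                    g += 0.5 * a[np_dam[i]]
                mean_rec[i] = xb[i] + g
                var_rec[i] = 1.0 + d_np[i] * s2a

        # (i) liabilities: truncated normals at threshold 0
        for i in range(n):
            sd = np.sqrt(var_rec[i])
            alpha = -mean_rec[i] / sd
            if y[i] == 1:
                liab[i] = mean_rec[i] + sd * _trunc_std_normal_lower(alpha)
            else:
                liab[i] = mean_rec[i] - sd * _trunc_std_normal_lower(-alpha)

        # (ii) fixed effects by weighted least squares draw
        XtWX = np.zeros((p, p))
        XtWr = np.zeros(p)
        for i in range(n):
            w = 1.0 / var_rec[i]
            gen = mean_rec[i] - xb[i]  # genetic part of the mean
            r = liab[i] - gen
            for u in range(p):
                XtWr[u] += w * X[i, u] * r
                for v in range(u, p):
                    XtWX[u, v] += w * X[i, u] * X[i, v]
        for u in range(p):
            XtWX[u, u] += beta_prec  # weakly-informative N(0, 1/beta_prec) prior
            for v in range(u):
                XtWX[u, v] = XtWX[v, u]
        Lw = _chol_small(XtWX)
        mu = _chol_solve(Lw, XtWr)
        z = np.random.standard_normal(p)
        beta = mu + _solve_lower_T(Lw, z)
        xb = X @ beta

        # (iii) single-site updates of parents' breeding values
        for i in range(nP):
            dii = 0.0
            s = 0.0
            for k in range(pp_indptr[i], pp_indptr[i + 1]):
                j = pp_indices[k]
                if j == i:
                    dii = pp_data[k]
                else:
                    s += pp_data[k] * a[j]
            prec = dii / s2a
            num = -s / s2a
            ri = own_rec[i]
            if ri >= 0:
                prec += 1.0
                num += liab[ri] - xb[ri]
            for k in range(off_indptr[i], off_indptr[i + 1]):
                j = off_rec[k]
                v = 1.0 + d_np[j] * s2a
                other = 0.0
                m = off_mate[k]
                if m >= 0:
                    other = 0.5 * a[m]
                prec += 0.25 / v
                num += 0.5 * (liab[j] - xb[j] - other) / v
            a[i] = num / prec + np.random.standard_normal() / np.sqrt(prec)

        # (iv) sigma2_a by slice sampling on log sigma2_a
        ss_p = 0.0
        for i in range(nP):
            row = 0.0
            for k in range(pp_indptr[i], pp_indptr[i + 1]):
                row += pp_data[k] * a[pp_indices[k]]
            ss_p += a[i] * row
        # residuals of recorded non-parents at current parent averages
        n_np = 0
        for i in range(n):
            if is_par[i] == 0:
                n_np += 1
        r_np = np.empty(n_np)
        dd = np.empty(n_np)
        kk = 0
        for i in range(n):
            if is_par[i] == 0:
                g = 0.0
                if np_sire[i] >= 0:
                    g += 0.5 * a[np_sire[i]]
                if np_dam[i] >= 0:
                    g += 0.5 * a[np_dam[i]]
                r_np[kk] = liab[i] - xb[i] - g
                dd[kk] = d_np[i]
                kk += 1
        # the variance block is repeated a few times per round (each pass
        # costs O(n)); the extra passes sharpen sigma2_a mixing
        for _rep in range(3):
            # (iv-a) parameter-expansion move: jointly rescale (a_P, sigma2_a)
            # by (sqrt(c), c).  Breaks the slow coupled random walk of the
            # breeding values and the variance that single-site updates suffer
            # from with one record per animal; Metropolis acceptance on the
            # exact joint keeps the posterior invariant.
            c = np.exp(0.5 * np.random.standard_normal())
            sq = np.sqrt(c)
            log_acc = (0.5 * nP + 1.0) * np.log(c)
            # parents' prior (SS/sigma2 invariant) and variance prior
            log_acc += -(0.5 * nP) * np.log(c)
            if prior_kind == 0:
                log_acc += -(1.0 + 0.5 * nu) * np.log(c) - 0.5 * nu * s2_prior * (
                    1.0 / (c * s2a) - 1.0 / s2a
                )
            else:
                log_acc += np.log(c) - 2.0 * (np.log1p(c * s2a) - np.log1p(s2a))
            for i in range(nP):
                ri = own_rec[i]
                if ri >= 0:
                    e0 = liab[ri] - xb[ri] - a[i]
                    e1 = liab[ri] - xb[ri] - sq * a[i]
                    log_acc += -0.5 * (e1 * e1 - e0 * e0)
            kk = 0
            for i in range(n):
                if is_par[i] == 0:
                    g = 0.0
                    if np_sire[i] >= 0:
                        g += 0.5 * a[np_sire[i]]
                    if np_dam[i] >= 0:
                        g += 0.5 * a[np_dam[i]]
                    r0 = liab[i] - xb[i] - g
                    r1 = liab[i] - xb[i] - sq * g
                    v0 = 1.0 + d_np[i] * s2a
                    v1 = 1.0 + d_np[i] * c * s2a
                    log_acc += -0.5 * (np.log(v1) - np.log(v0)) - 0.5 * (
                        r1 * r1 / v1 - r0 * r0 / v0
                    )
                    kk += 1
            if np.log(_randu()) <= log_acc:
                s2a = c * s2a
                for i in range(nP):
                    a[i] = sq * a[i]
                ss_p = c * ss_p

            # (iv-b) slice update of sigma2_a from its exact full conditional
            kk = 0
            for i in range(n):
                if is_par[i] == 0:
                    g = 0.0
                    if np_sire[i] >= 0:
                        g += 0.5 * a[np_sire[i]]
                    if np_dam[i] >= 0:
                        g += 0.5 * a[np_dam[i]]
                    r_np[kk] = liab[i] - xb[i] - g
                    kk += 1
            t0 = np.log(s2a)
            f0 = _log_sigma2_conditional(t0, ss_p, nP, r_np, dd, prior_kind, nu, s2_prior)
            logy = f0 + np.log(_randu())
            w = 1.0
            lo = t0 - w * np.random.random()
            hi = lo + w
            for _ in range(50):
                if _log_sigma2_conditional(lo, ss_p, nP, r_np, dd, prior_kind, nu, s2_prior) < logy:
                    break
                lo -= w
            for _ in range(50):
                if _log_sigma2_conditional(hi, ss_p, nP, r_np, dd, prior_kind, nu, s2_prior) < logy:
                    break
                hi += w
            t1 = t0
            for _ in range(100):
                t1 = lo + (hi - lo) * np.random.random()
                if _log_sigma2_conditional(t1, ss_p, nP, r_np, dd, prior_kind, nu, s2_prior) >= logy:
                    break
                if t1 < t0:
                    lo = t1
                else:
                    hi = t1
            s2a = np.exp(t1)

        if rnd > burn_in and (rnd - burn_in) % thin == 0:
            out_s2a[stored] = s2a
            out_h2[stored] = s2a / (s2a + 1.0)
            out_beta[stored] = beta
            ebv_par_sum += a
            # conditional-mean genetic value per record
            for i in range(n):
                if is_par[i] == 1:
                    ebv_rec_sum[i] += a[par_of_rec[i]]
                else:
                    g = 0.0
                    if np_sire[i] >= 0:
                        g += 0.5 * a[np_sire[i]]
                    if np_dam[i] >= 0:
                        g += 0.5 * a[np_dam[i]]
                    v = 1.0 + d_np[i] * s2a
                    g += (d_np[i] * s2a / v) * (liab[i] - xb[i] - g)
                    ebv_rec_sum[i] += g
            stored += 1

    denom = max(stored, 1)
    return (
        out_s2a,
        out_h2,
        out_beta,
        ebv_par_sum / denom,
        ebv_rec_sum / denom,
        liab,
    )


@njit(cache=True)
def gibbs_kernel(
    seed,
    n_rounds,
    burn_in,
    thin,
    y,            # (n,) int8 0/1 diagnoses
    obs_ped,      # (n,) int64 pedigree position of each record
    X,            # (n, p) fixed-effect design
    XtX_L,        # (p, p) lower Cholesky of X'X
    ainv_indptr,
    ainv_indices,
    ainv_data,    # CSR of the full A^-1 (N x N)
    par_indptr,
    par_indices,
    par_data,     # CSR of the parent-subset A^-1 (nP x nP)
    parent_pos,   # (nP,) pedigree positions aligned with the subset rows
    rec_of,       # (N,) record index per animal, -1 if unrecorded
    prior_kind,   # 0: scaled inverse chi-square(nu, s2); 1: uniform on h2
    nu,
    s2_prior,
    use_parents,  # bool: variance update on animals with offspring only
    sigma2_a_init,
):
    """Run the threshold-model Gibbs sampler; residual variance fixed at 1.

    Returns (sigma2_a chain, h2 chain, beta chain, posterior-mean breeding
    values, final liabilities).
    """
    np.random.seed(seed)
    n = y.shape[0]
    N = rec_of.shape[0]
    p = X.shape[1]
    nP = parent_pos.shape[0]
    n_store = (n_rounds - burn_in) // thin

    out_s2a = np.empty(n_store)
    out_h2 = np.empty(n_store)
    out_beta = np.empty((n_store, p))
    ebv_sum = np.zeros(N)

    beta = np.zeros(p)
    a = np.zeros(N)
    liab = np.zeros(n)
    xb = np.zeros(n)
    s2a = sigma2_a_init
    aP = np.empty(nP)
    stored = 0

    for rnd in range(1, n_rounds + 1):
        # (i) fixed effects: beta ~ N((X'X)^-1 X'(l - a_obs), (X'X)^-1)
        # (first round uses the zero-initialised liabilities)
        resid = np.empty(n)
        for i in range(n):
            resid[i] = liab[i] - a[obs_ped[i]]
        v = X.T @ resid
        mu = _chol_solve(XtX_L, v)
        z = np.random.standard_normal(p)
        beta = mu + _solve_lower_T(XtX_L, z)
        xb = X @ beta

        # (ii)+(iii) collapsed (liability, breeding value) updates in
        # pedigree code order.  For a recorded animal the liability is
        # drawn with its own breeding value integrated out
        # (variance 1 + s2a/Q_ii), then the breeding value given that
        # liability; the collapsing removes the slow two-step random walk
        # the (l_i, a_i) pair otherwise performs.
        for i in range(N):
            dii = 0.0
            s = 0.0
            for k in range(ainv_indptr[i], ainv_indptr[i + 1]):
                j = ainv_indices[k]
                if j == i:
                    dii = ainv_data[k]
                else:
                    s += ainv_data[k] * a[j]
            prior_prec = dii / s2a
            prior_mean = -s / dii
            ri = rec_of[i]
            prec = prior_prec
            num = -s / s2a
            if ri >= 0:
                m = xb[ri] + prior_mean
                sd = np.sqrt(1.0 + 1.0 / prior_prec)
                alpha = -m / sd
                if y[ri] == 1:
                    liab[ri] = m + sd * _trunc_std_normal_lower(alpha)
                else:
                    liab[ri] = m - sd * _trunc_std_normal_lower(-alpha)
                prec += 1.0
                num += liab[ri] - xb[ri]
            a[i] = num / prec + np.random.standard_normal() / np.sqrt(prec)

        # (iv) genetic variance update from the parents' (or all animals')
        # quadratic form
        if use_parents:
            for k in range(nP):
                aP[k] = a[parent_pos[k]]
            ss = _csr_quad_form(par_indptr, par_indices, par_data, aP)
            q = nP
        else:
            ss = _csr_quad_form(ainv_indptr, ainv_indices, ainv_data, a)
            q = N
        if prior_kind == 0:
            # conjugate scaled inverse chi-square draw
            s2a = (ss + nu * s2_prior) / np.random.chisquare(q + nu)
        else:
            # uniform prior on h2 = s2a/(1+s2a): propose from the flat-s2a
            # conjugate draw, Metropolis-correct by the prior density
            # (1+s2a)^-2
            cand = ss / np.random.chisquare(q - 2)
            lr = 2.0 * (np.log1p(s2a) - np.log1p(cand))
            if np.log(_randu()) <= lr:
                s2a = cand
        if s2a < 1e-12:
            s2a = 1e-12
        elif s2a > 1e12:
            s2a = 1e12

        if rnd > burn_in and (rnd - burn_in) % thin == 0:
            out_s2a[stored] = s2a
            out_h2[stored] = s2a / (s2a + 1.0)
            out_beta[stored] = beta
            ebv_sum += a
            stored += 1

    ebv_mean = ebv_sum / max(stored, 1)
    return out_s2a, out_h2, out_beta, ebv_mean, liab
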