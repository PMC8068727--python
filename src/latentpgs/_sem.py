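"""Internal SEM engine.

Implements maximum-likelihood estimation of confirmatory factor models on raw
data (complete-data Wishart form or full-information ML over missingness
patterns), with analytic gradients, sandwich (robust) standard errors and a
mean-scaled (Satorra-Bentler-type) chi-square. The genomic-SEM module reuses
the parameter layout and model-implied-moment machinery with a different
discrepancy (DWLS on a genetic covariance matrix).

Conventions (recorded in fit metadata): the complete-data chi-square uses the
unbiased sample covariance and an (n_g - 1) multiplier per group; FIML groups
use the casewise likelihood-ratio against an EM-fitted saturated model.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from scipy import optimize

from .model_spec import FactorModelSpec, GROUP_CONSTRAINT_LEVELS


# ---------------------------------------------------------------------------
# half-vectorization helpers

def vech_indices(p: int):
    """Row/column indices of the lower triangle (including diagonal)."""
    rows, cols = np.tril_indices(p)
    return rows, cols


def vech(a: np.ndarray) -> np.ndarray:
    r, c = vech_indices(a.shape[0])
    return a[r, c]


def duplication_matrix(p: int) -> np.ndarray:
    """D_p with vec(A) = D_p @ vech(A) for symmetric A."""
    r, c = vech_indices(p)
    q = len(r)
    D = np.zeros((p * p, q))
    for k, (i, j) in enumerate(zip(r, c)):
        D[i * p + j, k] = 1.0
        D[j * p + i, k] = 1.0
    return D


# ---------------------------------------------------------------------------
# parameter layout

class ParamLayout:
    """Maps the free-parameter vector to per-group (Lambda, Psi, theta, nu, alpha).

    Cross-group equality constraints (the invariance ladder) are realized by
    assigning the same free-parameter slot to entries in several groups.
    """

    def __init__(self, spec: FactorModelSpec, n_groups: int):
        self.spec = spec
        self.n_groups = n_groups
        p, m = spec.n_indicators, spec.n_factors
        self.p, self.m = p, m
        lvl = GROUP_CONSTRAINT_LEVELS.index(spec.group_constraints)
        share_load, share_int, share_res = lvl >= 1, lvl >= 2, lvl >= 3
        fixed = spec.fixed_map()
        mean = spec.mean_structure

        labels: dict = {}
        names: list = []

        def slot(label, name):
            if label not in labels:
                labels[label] = len(names)
                names.append(name)
            return labels[label]

        # templates of fixed values and free-entry index lists per group
        self.lam_fix = [np.zeros((p, m)) for _ in range(n_groups)]
        self.psi_fix = [np.eye(m) if m else np.zeros((0, 0)) for _ in range(n_groups)]
        self.theta_fix = [np.zeros(p) for _ in range(n_groups)]
        self.nu_fix = [np.zeros(p) for _ in range(n_groups)]
        self.alpha_fix = [np.zeros(m) for _ in range(n_groups)]
        # free entries: (mat, g) -> (rows, cols, slots, mult)
        self.free: dict = {}
        ent = {g: {"lambda": [], "psi": [], "theta": [], "nu": [], "alpha": []}
               for g in range(n_groups)}

        fac_ix = {f: j for j, f in enumerate(spec.factors)}
        first_ind = {}  # factor -> first indicator loading on it
        for i, ind in enumerate(spec.indicators):
            for f in spec.loading_pattern[ind]:
                first_ind.setdefault(f, i)

        for g in range(n_groups):
            gl = "" if n_groups == 1 else f"|g{g + 1}"
            # loadings
            for i, ind in enumerate(spec.indicators):
                for f in spec.loading_pattern[ind]:
                    j = fac_ix[f]
                    key = ("lambda", i, j)
                    if key in fixed:
                        self.lam_fix[g][i, j] = fixed[key]
                        continue
                    if spec.identification == "loading" and first_ind[f] == i:
                        self.lam_fix[g][i, j] = 1.0
                        continue
                    lab = ("lambda", i, j) if share_load else ("lambda", g, i, j)
                    tag = "" if share_load else gl
                    k = slot(lab, f"lambda[{ind},{f}]{tag}")
                    ent[g]["lambda"].append((i, j, k, 1.0))
            # factor variances
            for j, f in enumerate(spec.factors):
                key = ("psi", j, j)
                if key in fixed:
                    self.psi_fix[g][j, j] = fixed[key]
                    continue
                if spec.identification == "variance":
                    # fixed to 1 in group 1; freed in later groups once
                    # loadings are constrained equal (standard ladder practice)
                    if g == 0 or not share_load:
                        self.psi_fix[g][j, j] = 1.0
                        continue
                k = slot(("psi", g, j, j), f"psi[{f},{f}]{gl}")
                ent[g]["psi"].append((j, j, k, 1.0))
            # factor covariances (never constrained by the ladder)
            for j in range(m):
                for l in range(j + 1, m):
                    key = ("psi", j, l)
                    key2 = ("psi", l, j)
                    if key in fixed or key2 in fixed:
                        v = fixed.get(key, fixed.get(key2))
                        self.psi_fix[g][j, l] = self.psi_fix[g][l, j] = v
                        continue
                    if spec.factor_covariances == "fixed":
                        continue  # stays 0
                    k = slot(("psi", g, j, l),
                             f"psi[{spec.factors[j]},{spec.factors[l]}]{gl}")
                    ent[g]["psi"].append((j, l, k, 2.0))
            # residual variances
            for i, ind in enumerate(spec.indicators):
                key = ("theta", i, i)
                if key in fixed:
                    self.theta_fix[g][i] = fixed[key]
                    continue
                lab = ("theta", i) if share_res else ("theta", g, i)
                tag = "" if share_res else gl
                k = slot(lab, f"theta[{ind}]{tag}")
                ent[g]["theta"].append((i, 0, k, 1.0))
            if mean:
                for i, ind in enumerate(spec.indicators):
                    key = ("nu", i, 0)
                    if key in fixed:
                        self.nu_fix[g][i] = fixed[key]
                        continue
                    lab = ("nu", i) if share_int else ("nu", g, i)
                    tag = "" if share_int else gl
                    k = slot(lab, f"nu[{ind}]{tag}")
                    ent[g]["nu"].append((i, 0, k, 1.0))
                for j, f in enumerate(spec.factors):
                    key = ("alpha", j, 0)
                    if key in fixed:
                        self.alpha_fix[g][j] = fixed[key]
                        continue
                    # factor means identified only relative to group 1
                    if g == 0 or not share_int:
                        continue  # fixed at 0
                    k = slot(("alpha", g, j), f"alpha[{f}]{gl}")
                    ent[g]["alpha"].append((j, 0, k, 1.0))

        self.names = names
        self.n_free = len(names)
        for g in range(n_groups):
            for mat, lst in ent[g].items():
                if lst:
                    arr = np.array(lst)
                    self.free[(mat, g)] = (
                        arr[:, 0].astype(int), arr[:, 1].astype(int),
                        arr[:, 2].astype(int), arr[:, 3].astype(float),
                    )
                else:
                    z = np.zeros(0, dtype=int)
                    self.free[(mat, g)] = (z, z, z, np.zeros(0))

    # -- assembly ----------------------------------------------------------

    def unpack(self, theta: np.ndarray, g: int):
        Lam = self.lam_fix[g].copy()
        i, j, k, _ = self.free[("lambda", g)]
        Lam[i, j] = theta[k]
        Psi = self.psi_fix[g].copy()
        i, j, k, _ = self.free[("psi", g)]
        Psi[i, j] = theta[k]
        Psi[j, i] = theta[k]
        Th = self.theta_fix[g].copy()
        i, _, k, _ = self.free[("theta", g)]
        Th[i] = theta[k]
        nu = self.nu_fix[g].copy()
        i, _, k, _ = self.free[("nu", g)]
        nu[i] = theta[k]
        al = self.alpha_fix[g].copy()
        i, _, k, _ = self.free[("alpha", g)]
        al[i] = theta[k]
        return Lam, Psi, Th, nu, al

    def implied(self, theta: np.ndarray, g: int):
        Lam, Psi, Th, nu, al = self.unpack(theta, g)
        Sigma = Lam @ Psi @ Lam.T + np.diag(Th)
        mu = nu + Lam @ al
        return Sigma, mu

    def gather_grad(self, grad, theta_unused, g, w, gLam, gPsi_full, gTheta, gnu, galpha):
        """Accumulate w * dF/dtheta from per-matrix gradient blocks."""
        i, j, k, _ = self.free[("lambda", g)]
        np.add.at(grad, k, w * gLam[i, j])
        i, j, k, mult = self.free[("psi", g)]
        np.add.at(grad, k, w * mult * gPsi_full[i, j])
        i, _, k, _ = self.free[("theta", g)]
        np.add.at(grad, k, w * gTheta[i])
        i, _, k, _ = self.free[("nu", g)]
        if len(k):
            np.add.at(grad, k, w * gnu[i])
        i, _, k, _ = self.free[("alpha", g)]
        if len(k):
            np.add.at(grad, k, w * galpha[i])

    def dsigma_dmu(self, theta: np.ndarray, g: int):
        """Dense derivative tensors dSigma/dtheta (K,p,p) and dmu/dtheta (K,p)."""
        p, m, K = self.p, self.m, self.n_free
        Lam, Psi, Th, nu, al = self.unpack(theta, g)
        M = Lam @ Psi
        dS = np.zeros((K, p, p))
        dmu = np.zeros((K, p))
        i, j, k, _ = self.free[("lambda", g)]
        for a, b, kk in zip(i, j, k):
            dS[kk, a, :] += M[:, b]
            dS[kk, :, a] += M[:, b]
            dmu[kk, a] += al[b]
        i, j, k, _ = self.free[("psi", g)]
        for a, b, kk in zip(i, j, k):
            if a == b:
                dS[kk] += np.outer(Lam[:, a], Lam[:, a])
            else:
                dS[kk] += np.outer(Lam[:, a], Lam[:, b]) + np.outer(Lam[:, b], Lam[:, a])
        i, _, k, _ = self.free[("theta", g)]
        for a, kk in zip(i, k):
            dS[kk, a, a] += 1.0
        i, _, k, _ = self.free[("nu", g)]
        for a, kk in zip(i, k):
            dmu[kk, a] += 1.0
        i, _, k, _ = self.free[("alpha", g)]
        for a, kk in zip(i, k):
            dmu[kk] += Lam[:, a]
        return dS, dmu


# ---------------------------------------------------------------------------
# data containers

@dataclass
class PatternStats:
    obs: np.ndarray          # indices of observed variables
    w: float                 # n_pattern / n_group
    S: np.ndarray            # within-pattern covariance (biased for FIML)
    mean: np.ndarray


@dataclass
class GroupData:
    n: int
    patterns: list
    F_sat: float             # saturated discrepancy offset
    mult: float              # chi-square multiplier (n-1 complete, n FIML)
    rows: np.ndarray         # raw data, NaN for missing
    complete: bool
    S_full: np.ndarray = None     # complete-data unbiased covariance
    mean_full: np.ndarray = None
    loglik_sat: float = 0.0       # casewise saturated log-likelihood


def _em_saturated(rows: np.ndarray, tol=1e-10, max_iter=500):
    """EM for the unstructured (mu, Sigma) of a normal sample with MCAR holes."""
    n, p = rows.shape
    obs = ~np.isnan(rows)
    mu = np.nanmean(rows, axis=0)
    filled = np.where(obs, rows, mu)
    Sigma = np.cov(filled, rowvar=False, bias=True) + 1e-6 * np.eye(p)
    for _ in range(max_iter):
        ex = np.zeros(p)
        exx = np.zeros((p, p))
        for key, idx in _pattern_groups(obs).items():
            o = np.flatnonzero(np.array(key))
            mi = np.flatnonzero(~np.array(key))
            X = rows[idx][:, o]
            k = len(idx)
            if len(mi) == 0:
                ex += X.sum(0)
                exx += X.T @ X
                continue
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(mi, o)]
            B = np.linalg.solve(Soo, Smo.T).T          # regression of mis on obs
            cond_cov = Sigma[np.ix_(mi, mi)] - B @ Smo.T
            Xm = mu[mi] + (X - mu[o]) @ B.T
            full = np.zeros((k, p))
            full[:, o] = X
            full[:, mi] = Xm
            ex += full.sum(0)
            exx += full.T @ full
            exx[np.ix_(mi, mi)] += k * cond_cov
        mu_new = ex / n
        Sigma_new = exx / n - np.outer(mu_new, mu_new)
        if np.max(np.abs(Sigma_new - Sigma)) < tol and np.max(np.abs(mu_new - mu)) < tol:
            mu, Sigma = mu_new, Sigma_new
            break
        mu, Sigma = mu_new, Sigma_new
    return mu, Sigma


def _pattern_groups(obs_mask: np.ndarray) -> dict:
    pats: dict = {}
    for i, row in enumerate(map(tuple, obs_mask)):
        pats.setdefault(row, []).append(i)
    return {k: np.array(v) for k, v in pats.items()}


def _loglik_patterns(patterns, n, mu, Sigma):
    ll = 0.0
    for pat in patterns:
        o = pat.obs
        k = pat.w * n
        So = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(So)
        if sign <= 0:
            return -np.inf
        Si = np.linalg.inv(So)
        d = pat.mean - mu[o]
        ll += -0.5 * k * (len(o) * np.log(2 * np.pi) + logdet
                          + np.trace(pat.S @ Si) + d @ Si @ d)
    return ll


def prepare_group(rows: np.ndarray, mean_structure: bool) -> GroupData:
    """Sufficient statistics for one group; FIML patterns if data has holes."""
    rows = np.asarray(rows, dtype=float)
    n, p = rows.shape
    has_missing = bool(np.isnan(rows).any())
    if not has_missing:
        if n < 2:
            raise ValueError("need at least 2 rows per group")
        mean = rows.mean(0)
        S = np.cov(rows, rowvar=False, bias=False)
        S = np.atleast_2d(S)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance is singular")
        pat = PatternStats(obs=np.arange(p), w=1.0, S=S, mean=mean)
        F_sat = p * np.log(2 * np.pi) + logdet + p
        Sb = S * (n - 1) / n
        ll_sat = -0.5 * n * (p * np.log(2 * np.pi) + np.linalg.slogdet(Sb)[1] + p)
        return GroupData(n=n, patterns=[pat], F_sat=F_sat, mult=float(n - 1),
                         rows=rows, complete=True, S_full=S, mean_full=mean,
                         loglik_sat=ll_sat)
    obs = ~np.isnan(rows)
    if (obs.sum(1) == 0).any():
        raise ValueError("rows with no observed indicators present")
    pats = []
    for key, idx in _pattern_groups(obs).items():
        o = np.flatnonzero(np.array(key))
        X = rows[idx][:, o]
        k = len(idx)
        mean = X.mean(0)
        S = (X - mean).T @ (X - mean) / k
        pats.append(PatternStats(obs=o, w=k / n, S=np.atleast_2d(S), mean=mean))
    mu_s, Sig_s = _em_saturated(rows)
    ll_sat = _loglik_patterns(pats, n, mu_s, Sig_s)
    F_sat = -2.0 * ll_sat / n
    return GroupData(n=n, patterns=pats, F_sat=F_sat, mult=float(n),
                     rows=rows, complete=False, loglik_sat=ll_sat)


# ---------------------------------------------------------------------------
# discrepancy function

def total_discrepancy(theta, layout: ParamLayout, groups: list, want_grad=True):
    """Weighted ML discrepancy F and its gradient.

    F = sum_g (mult_g / M) * F_g with F_g the (Wishart or FIML) discrepancy;
    the model chi-square is M * F at the optimum, M = sum_g mult_g.
    """
    M = sum(g.mult for g in groups)
    mean_structure = layout.spec.mean_structure
    F = 0.0
    grad = np.zeros(layout.n_free) if want_grad else None
    for g, gd in enumerate(groups):
        Sigma, mu = layout.implied(theta, g)
        A = np.zeros((layout.p, layout.p))
        gmu = np.zeros(layout.p)
        Fg = 0.0
        for pat in gd.patterns:
            o = pat.obs
            So = Sigma[np.ix_(o, o)]
            sign, logdet = np.linalg.slogdet(So)
            if sign <= 0:
                return (np.inf, np.zeros_like(grad)) if want_grad else np.inf
            Si = np.linalg.inv(So)
            raw = len(o) * np.log(2 * np.pi) + logdet + np.trace(pat.S @ Si)
            if mean_structure:
                d = pat.mean - mu[o]
                Sid = Si @ d
                raw += d @ Sid
            Fg += pat.w * raw
            if want_grad:
                Ao = Si @ (So - pat.S) @ Si
                if mean_structure:
                    Ao -= np.outer(Sid, Sid)
                    gmu[o] += pat.w * (-2.0 * Sid)
                A[np.ix_(o, o)] += pat.w * Ao
        if not mean_structure:
            # drop the 2*pi and mean terms consistently with F_sat
            pass
        Fg -= gd.F_sat
        F += gd.mult / M * Fg
        if want_grad:
            Lam, Psi, Th, nu, al = layout.unpack(theta, g)
            Mmat = Lam @ Psi
            gLam = 2.0 * (A @ Mmat)
            if mean_structure and np.any(al):
                gLam += np.outer(gmu, al)
            gPsi = Lam.T @ A @ Lam
            gTheta = np.diag(A).copy()
            galpha = Lam.T @ gmu if mean_structure else np.zeros(layout.m)
            layout.gather_grad(grad, theta, g, gd.mult / M, gLam, gPsi,
                               gTheta, gmu, galpha)
    return (F, grad) if want_grad else F


def casewise_loglik(theta, layout, groups):
    ll = 0.0
    for g, gd in enumerate(groups):
        Sigma, mu = layout.implied(theta, g)
        if gd.complete:
            # casewise likelihood uses the biased covariance
            n, p = gd.n, layout.p
            Sb = gd.S_full * (n - 1) / n
            sign, logdet = np.linalg.slogdet(Sigma)
            if sign <= 0:
                return -np.inf
            Si = np.linalg.inv(Sigma)
            d = (gd.mean_full - mu) if layout.spec.mean_structure else np.zeros(p)
            ll += -0.5 * n * (p * np.log(2 * np.pi) + logdet
                              + np.trace(Sb @ Si) + d @ Si @ d)
        else:
            ll += _loglik_patterns(gd.patterns, gd.n, mu, Sigma)
    return ll


# ---------------------------------------------------------------------------
# fitting

@dataclass
class RawFit:
    theta: np.ndarray
    F: float
    chi2: float
    df: int
    n_free: int
    pstar: int
    converged: bool
    grad_norm: float
    layout: ParamLayout
    groups: list
    loglik: float
    heywood: list = field(default_factory=list)


def start_values(layout: ParamLayout, groups: list) -> np.ndarray:
    theta = np.zeros(layout.n_free)
    spec = layout.spec
    filled = np.zeros(layout.n_free, dtype=bool)
    for g, gd in enumerate(groups):
        if gd.complete:
            s = np.diag(gd.S_full)
            mn = gd.mean_full
        else:
            s = np.nanvar(gd.rows, axis=0, ddof=1)
            mn = np.nanmean(gd.rows, axis=0)
        i, j, k, _ = layout.free[("lambda", g)]
        theta[k[~filled[k]]] = 0.7 * np.sqrt(s[i])[~filled[k]]
        filled[k] = True
        i, j, k, _ = layout.free[("psi", g)]
        sel = ~filled[k]
        theta[k[sel]] = np.where(i == j, 1.0, 0.3)[sel]
        filled[k] = True
        i, _, k, _ = layout.free[("theta", g)]
        theta[k[~filled[k]]] = 0.5 * s[i][~filled[k]]
        filled[k] = True
        i, _, k, _ = layout.free[("nu", g)]
        if len(k):
            theta[k[~filled[k]]] = mn[i][~filled[k]]
            filled[k] = True
    return theta


def fit_ml(spec: FactorModelSpec, groups: list, start=None,
           maxiter=1000, gtol=1e-7) -> RawFit:
    layout = ParamLayout(spec, len(groups))
    p = layout.p
    pstar = sum(p * (p + 1) // 2 + (p if spec.mean_structure else 0)
                for _ in groups)
    df = pstar - layout.n_free
    if df < 0:
        raise ValueError(
            f"model not identified: {layout.n_free} free parameters exceed "
            f"{pstar} sample moments")
    theta0 = np.asarray(start, float) if start is not None else start_values(layout, groups)

    if layout.n_free == 0:
        theta = theta0
        F = total_discrepancy(theta, layout, groups, want_grad=False)
        Mtot = sum(g.mult for g in groups)
        ll = casewise_loglik(theta, layout, groups)
        return RawFit(theta=theta, F=F, chi2=max(Mtot * F, 0.0), df=pstar,
                      n_free=0, pstar=pstar, converged=True, grad_norm=0.0,
                      layout=layout, groups=groups, loglik=ll)

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(4):
        x0 = theta0 if attempt == 0 else theta0 * (1 + 0.2 * rng.standard_normal(theta0.shape)) + 0.05 * rng.standard_normal(theta0.shape)
        res = optimize.minimize(
            total_discrepancy, x0, args=(layout, groups, True), jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.fun < np.inf and np.linalg.norm(best.jac, np.inf) < 1e-5:
            break
    res = best
    theta = res.x

    # Newton polish: a just-identified complete-data model reproduces the
    # sample moments exactly; drive the moment residuals to machine precision.
    if df == 0 and len(groups) == 1 and groups[0].complete:
        theta = _newton_exact(layout, groups[0], theta)

    F, grad = total_discrepancy(theta, layout, groups, want_grad=True)
    Mtot = sum(g.mult for g in groups)
    chi2 = max(Mtot * F, 0.0)
    gn = float(np.linalg.norm(grad, np.inf))
    converged = bool(np.isfinite(F)) and (gn < 1e-3 or df == 0)
    heywood = []
    for g in range(len(groups)):
        _, _, Th, _, _ = layout.unpack(theta, g)
        i, _, k, _ = layout.free[("theta", g)]
        for a in i[Th[i] < 0]:
            heywood.append((g, spec.indicators[a]))
    ll = casewise_loglik(theta, layout, groups)
    return RawFit(theta=theta, F=F, chi2=chi2, df=df, n_free=layout.n_free,
                  pstar=pstar, converged=converged, grad_norm=gn,
                  layout=layout, groups=groups, loglik=ll, heywood=heywood)


def _moment_vector(layout, gd: GroupData):
    if layout.spec.mean_structure:
        return np.concatenate([gd.mean_full, vech(gd.S_full)])
    return vech(gd.S_full)


def _model_moments(layout, theta, g):
    Sigma, mu = layout.implied(theta, g)
    if layout.spec.mean_structure:
        return np.concatenate([mu, vech(Sigma)])
    return vech(Sigma)


def _delta_matrix(layout, theta, g):
    dS, dmu = layout.dsigma_dmu(theta, g)
    r, c = vech_indices(layout.p)
    dv = dS[:, r, c]                       # (K, pstar_cov)
    if layout.spec.mean_structure:
        return np.hstack([dmu, dv]).T      # (pm, K)
    return dv.T


def _newton_exact(layout, gd: GroupData, theta, max_iter=30):
    s_obs = _moment_vector(layout, gd)
    for _ in range(max_iter):
        resid = s_obs - _model_moments(layout, theta, 0)
        if np.max(np.abs(resid)) < 1e-13:
            break
        Dl = _delta_matrix(layout, theta, 0)
        try:
            step = np.linalg.solve(Dl, resid)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(Dl, resid, rcond=None)
        ns = np.linalg.norm(step)
        if ns > 10:
            step *= 10 / ns
        theta = theta + step
    return theta


# ---------------------------------------------------------------------------
# standard errors and robust corrections

def observed_information(fit: RawFit, eps=1e-6):
    """Numerical Hessian of the negative casewise log-likelihood."""
    layout, groups = fit.layout, fit.groups
    K = layout.n_free

    def score(th):
        # gradient of -loglik via the discrepancy machinery: for casewise
        # likelihood each group contributes (n_g/2) * dF_raw/dtheta with
        # biased within-pattern stats; reuse total_discrepancy on biased stats
        g = np.zeros(K)
        for gi, gd in enumerate(groups):
            sub = [_biased_group(gd)]
            lay1 = _single_group_view(layout, gi)
            _, gg = total_discrepancy(th, lay1, sub, want_grad=True)
            g += 0.5 * gd.n * gg
        return g

    base = score(fit.theta)
    H = np.zeros((K, K))
    for k in range(K):
        h = eps * (1 + abs(fit.theta[k]))
        th = fit.theta.copy()
        th[k] += h
        H[:, k] = (score(th) - base) / h
    return 0.5 * (H + H.T)


def _biased_group(gd: GroupData) -> GroupData:
    if not gd.complete:
        return GroupData(n=gd.n, patterns=gd.patterns, F_sat=gd.F_sat,
                         mult=float(gd.n), rows=gd.rows, complete=False,
                         loglik_sat=gd.loglik_sat)
    n, p = gd.n, gd.S_full.shape[0]
    Sb = gd.S_full * (n - 1) / n
    pat = PatternStats(obs=np.arange(p), w=1.0, S=Sb, mean=gd.mean_full)
    return GroupData(n=n, patterns=[pat], F_sat=0.0, mult=float(n),
                     rows=gd.rows, complete=True, S_full=gd.S_full,
                     mean_full=gd.mean_full)


class _single_group_view:
    """Present one group of a multi-group layout as a standalone objective."""

    def __init__(self, layout: ParamLayout, g: int):
        self.layout = layout
        self.g = g
        self.spec = layout.spec
        self.p, self.m, self.n_free = layout.p, layout.m, layout.n_free

    def implied(self, theta, _g):
        return self.layout.implied(theta, self.g)

    def unpack(self, theta, _g):
        return self.layout.unpack(theta, self.g)

    def gather_grad(self, grad, theta, _g, w, *blocks):
        self.layout.gather_grad(grad, theta, self.g, w, *blocks)


def score_outer_product(fit: RawFit):
    """B = sum_i s_i s_i' of per-row log-likelihood scores."""
    layout, groups = fit.layout, fit.groups
    K = layout.n_free
    B = np.zeros((K, K))
    mean_structure = layout.spec.mean_structure
    for g, gd in enumerate(groups):
        Sigma, mu = layout.implied(fit.theta, g)
        dS, dmu = layout.dsigma_dmu(fit.theta, g)
        obs_mask = ~np.isnan(gd.rows)
        for key, idx in _pattern_groups(obs_mask).items():
            o = np.flatnonzero(np.array(key))
            X = gd.rows[idx][:, o]
            So = Sigma[np.ix_(o, o)]
            Si = np.linalg.inv(So)
            d = X - mu[o]
            q = d @ Si                                     # (n_pat, p_o)
            Dk = dS[:, np.ix_(o, o)[0], np.ix_(o, o)[1]]    # (K,p_o,p_o)
            tr_term = -0.5 * np.einsum("pq,kqp->k", Si, Dk)
            quad = 0.5 * np.einsum("ip,kpq,iq->ik", q, Dk, q)
            s = quad + tr_term
            if mean_structure:
                s = s + q @ dmu[:, o].T
            B += s.T @ s
    return B


def normal_theory_weight(Sigma, mean_structure):
    p = Sigma.shape[0]
    Si = np.linalg.inv(Sigma)
    D = duplication_matrix(p)
    Wc = 0.5 * D.T @ np.kron(Si, Si) @ D
    if not mean_structure:
        return Wc
    W = np.zeros((p + Wc.shape[0], p + Wc.shape[0]))
    W[:p, :p] = Si
    W[p:, p:] = Wc
    return W


def _gamma_complete(rows, mean_structure):
    """Asymptotic covariance of the sample moment vector from complete rows."""
    Z = rows[~np.isnan(rows).any(axis=1)]
    n, p = Z.shape
    xbar = Z.mean(0)
    dc = Z - xbar
    r, c = vech_indices(p)
    y_cov = dc[:, r] * dc[:, c]
    y = np.hstack([Z, y_cov]) if mean_structure else y_cov
    yc = y - y.mean(0)
    return yc.T @ yc / n, n


def satorra_bentler_scale(fit: RawFit):
    """Mean-scaling factor c for the chi-square; 1.0 when df == 0.

    Computed from complete rows' fourth moments (documented approximation
    under FIML).
    """
    if fit.df == 0:
        return 1.0
    layout, groups = fit.layout, fit.groups
    mean_structure = layout.spec.mean_structure
    Mtot = sum(g.mult for g in groups)
    Ws, Deltas, Gammas, cs = [], [], [], []
    for g, gd in enumerate(groups):
        Sigma, _ = layout.implied(fit.theta, g)
        Ws.append(normal_theory_weight(Sigma, mean_structure))
        Deltas.append(_delta_matrix(layout, fit.theta, g))
        Gam, n_c = _gamma_complete(gd.rows, mean_structure)
        if n_c < layout.p + 2:
            return 1.0
        Gammas.append(Gam)
        cs.append(gd.mult / Mtot)
    Wb = _block_diag([c * W for c, W in zip(cs, Ws)])
    Delta = np.vstack(Deltas)
    Gb = _block_diag([G / c for c, G in zip(cs, Gammas)])
    WD = Wb @ Delta
    try:
        inner = np.linalg.solve(Delta.T @ WD, WD.T)
    except np.linalg.LinAlgError:
        return 1.0
    U = Wb - WD @ inner
    c = float(np.trace(U @ Gb)) / fit.df
    return max(c, 1e-8)


def _block_diag(mats):
    sizes = [m.shape[0] for m in mats]
    out = np.zeros((sum(sizes), sum(sizes)))
    at = 0
    for m in mats:
        out[at:at + m.shape[0], at:at + m.shape[0]] = m
        at += m.shape[0]
    return out


def parameter_covariance(fit: RawFit, robust: bool):
    A = observed_information(fit)
    try:
        Ai = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ai = np.linalg.pinv(A)
    if not robust:
        return Ai
    B = score_outer_product(fit)
    return Ai @ B @ Ai
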