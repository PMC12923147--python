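"""Linear mixed models with random intercepts: REML/ML fitting and
Satterthwaite inference.

The models handled here are of the variance-component form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),   e ~ N(0, s2_e I),

where each Z_k is the indicator matrix of a grouping factor (e.g. session,
session:trial, role).  Crossed groupings are allowed.  The implied marginal
covariance is V(th) = s2_e I + sum_k s2_k Z_k Z_k' with th the vector of
variance components.

Estimation maximizes the profiled (over b) Gaussian log-likelihood — the ML
criterion

    -2 lML(th)  = n log 2pi + log|V| + r' V^-1 r,      r = y - X bhat(th),

or the REML criterion

    -2 lREML(th) = (n-p) log 2pi + log|V| + log|X' V^-1 X| + r' V^-1 r,

by bounded L-BFGS-B over th >= 0 with analytic gradients

    d(-2l)/dth_k = tr(P G_k) - u' G_k u,   u = V^-1 r,  G_k = Z_k Z_k',

where P = V^-1 for ML and P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 for REML.

Inference on fixed effects uses the Satterthwaite approximation: for a
contrast c, the variance phi(th) = c'(X'V^-1X)^-1 c is treated as a scaled
chi-square with

    df = 2 phi^2 / (g' A g),

g the gradient of phi at the estimate (finite differences) and A the
asymptotic covariance of th, A = 2 H^-1 with H the Hessian of the REML
criterion (finite differences of the analytic gradient; one-sided at the
boundary th_k = 0).  Multi-degree-of-freedom F tests combine per-eigencontrast
Satterthwaite dfs in the usual way (harmonic pooling of d/(d-2)).

Problem sizes here are small (hundreds of rows), so all linear algebra is
dense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class LMMResult:
    """A fitted variance-component mixed model."""

    method: str                        # "reml" or "ml"
    beta: np.ndarray                   # fixed-effect estimates
    cov_beta: np.ndarray               # (X'V^-1X)^-1 at the estimate
    theta: np.ndarray                  # variance components, resid last
    vc_names: list[str]                # names for theta[:-1]
    neg2ll: float                      # criterion value at the optimum
    n: int
    exog_names: list[str]
    converged: bool
    boundary: bool                     # any variance at (numerical) zero
    _X: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)
    _Gs: list[np.ndarray] = field(repr=False)

    @property
    def p(self) -> int:
        return self._X.shape[1]

    @property
    def k_params(self) -> int:
        """Total parameter count: fixed effects + variance components."""
        return self.p + len(self.theta)

    @property
    def loglik(self) -> float:
        return -0.5 * self.neg2ll

    @property
    def aic(self) -> float:
        """AIC from the (ML) likelihood: -2 logLik + 2 * n_params."""
        return self.neg2ll + 2.0 * self.k_params

    @property
    def sigma2_resid(self) -> float:
        return float(self.theta[-1])

    @property
    def vcomp(self) -> dict[str, float]:
        return {nm: float(v) for nm, v in zip(self.vc_names, self.theta[:-1])}

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def fixef_table(self) -> pd.DataFrame:
        """Coefficient table with Satterthwaite df, t and p per coefficient."""
        ses = self.se()
        dfs = satterthwaite_df_multi(self, np.eye(self.p))
        t = self.beta / ses
        pvals = 2.0 * stats.t.sf(np.abs(t), dfs)
        return pd.DataFrame(
            {"term": self.exog_names, "estimate": self.beta, "se": ses,
             "df": dfs, "t": t, "p": pvals}
        )


def _groups_to_G(codes: np.ndarray) -> np.ndarray:
    """Z Z' for a grouping factor given integer codes per observation."""
    codes = np.asarray(codes)
    return (codes[:, None] == codes[None, :]).astype(float)


def _crit_grad(theta, y, X, Gs, reml: bool):
    """(criterion, gradient) of -2 log-likelihood at theta (resid var last)."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t_k, G in zip(theta[:-1], Gs):
        V += t_k * G
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    cf = linalg.cho_factor(XtViX, check_finite=False)
    beta = linalg.cho_solve(cf, ViX.T @ y, check_finite=False)
    r = y - X @ beta
    u = Vinv @ r
    quad = float(r @ u)
    if reml:
        logdetXtViX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        crit = (n - p) * _LOG2PI + logdetV + logdetXtViX + quad
        P = Vinv - ViX @ linalg.cho_solve(cf, ViX.T, check_finite=False)
    else:
        crit = n * _LOG2PI + logdetV + quad
        P = Vinv
    grad = np.empty(len(theta))
    for k, G in enumerate(Gs):
        grad[k] = float(np.sum(P * G)) - float(u @ G @ u)
    grad[-1] = float(np.trace(P)) - float(u @ u)
    return crit, grad, beta, XtViX


def _cov_beta(theta, y, X, Gs) -> np.ndarray:
    n = X.shape[0]
    V = theta[-1] * np.eye(n)
    for t_k, G in zip(theta[:-1], Gs):
        V += t_k * G
    c = linalg.cho_factor(V, lower=True, check_finite=False)
    ViX = linalg.cho_solve(c, X, check_finite=False)
    return np.linalg.inv(X.T @ ViX)


def fit_lmm(
    y,
    X,
    vc: dict[str, np.ndarray],
    method: str = "reml",
    exog_names: list[str] | None = None,
    theta0: np.ndarray | None = None,
) -> LMMResult:
    """Fit a random-intercept mixed model.

    Parameters
    ----------
    y, X
        Response vector (n,) and fixed-effect design (n, p), full rank.
    vc
        Mapping from variance-component name to integer (or hashable) group
        codes per observation; each contributes a random intercept.
    method
        ``"reml"`` (default, for reported estimates) or ``"ml"`` (for
        likelihood-ratio tests and AIC).
    theta0
        Optional warm start for the variance components (resid last).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("fixed-effect design is rank deficient")
    names = list(vc)
    Gs = []
    for nm in names:
        codes = pd.factorize(np.asarray(vc[nm]))[0]
        Gs.append(_groups_to_G(codes))
    reml = method == "reml"

    # scale-aware start: split the OLS residual variance across components
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = float(np.var(y - X @ bhat, ddof=min(p, n - 1)))
    s2 = max(s2, 1e-10)
    if theta0 is None:
        theta0 = np.full(len(Gs) + 1, s2 / (len(Gs) + 1.0))
        theta0[-1] = s2 / 2.0
    lb = 1e-10 * s2
    res = optimize.minimize(
        lambda th: _crit_grad(th, y, X, Gs, reml)[:2],
        x0=np.maximum(theta0, lb),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lb, None)] * (len(Gs) + 1),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = res.x
    crit, _, beta, XtViX = _crit_grad(theta, y, X, Gs, reml)
    boundary = bool(np.any(theta[:-1] <= lb * 10))
    return LMMResult(
        method=method,
        beta=beta,
        cov_beta=np.linalg.inv(XtViX),
        theta=theta,
        vc_names=names,
        neg2ll=crit,
        n=n,
        exog_names=exog_names or [f"x{i}" for i in range(p)],
        converged=bool(res.success),
        boundary=boundary,
        _X=X,
        _y=y,
        _Gs=Gs,
    )


# ---------------------------------------------------------------------------
# Satterthwaite machinery
# ---------------------------------------------------------------------------

def _steps(theta: np.ndarray) -> np.ndarray:
    scale = max(float(np.max(theta)), 1e-8)
    return np.maximum(1e-7 * scale, 1e-4 * theta)


def _theta_cov(res: LMMResult) -> np.ndarray:
    """Asymptotic covariance of the variance components (REML information)."""
    theta = res.theta
    h = _steps(theta)
    m = len(theta)
    H = np.zeros((m, m))
    reml = res.method == "reml"
    for i in range(m):
        hi = h[i]
        if theta[i] - hi > 0:
            gp = _crit_grad(_bump(theta, i, +hi), res._y, res._X, res._Gs, reml)[1]
            gm = _crit_grad(_bump(theta, i, -hi), res._y, res._X, res._Gs, reml)[1]
            H[i] = (gp - gm) / (2.0 * hi)
        else:  # one-sided at the boundary
            g0 = _crit_grad(theta, res._y, res._X, res._Gs, reml)[1]
            gp = _crit_grad(_bump(theta, i, +hi), res._y, res._X, res._Gs, reml)[1]
            H[i] = (gp - g0) / hi
    H = 0.5 * (H + H.T)
    return 2.0 * np.linalg.pinv(H)


def _bump(theta, i, d):
    t = theta.copy()
    t[i] += d
    return t


def satterthwaite_df_multi(res: LMMResult, C: np.ndarray) -> np.ndarray:
    """Satterthwaite denominator df for each contrast row of C."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    A = _theta_cov(res)
    theta = res.theta
    h = _steps(theta)
    phi0 = np.einsum("ij,jk,ik->i", C, res.cov_beta, C)
    grads = np.zeros((C.shape[0], len(theta)))
    for i in range(len(theta)):
        hi = h[i]
        covp = _cov_beta(_bump(theta, i, +hi), res._y, res._X, res._Gs)
        if theta[i] - hi > 0:
            covm = _cov_beta(_bump(theta, i, -hi), res._y, res._X, res._Gs)
            dcov = (covp - covm) / (2.0 * hi)
        else:
            dcov = (covp - res.cov_beta) / hi
        grads[:, i] = np.einsum("ij,jk,ik->i", C, dcov, C)
    denom = np.einsum("ri,ij,rj->r", grads, A, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * phi0**2 / denom
    df = np.where(np.isfinite(df) & (df > 0), df, np.inf)
    return np.clip(df, 1.0, 1e8)


def contrast_test(res: LMMResult, c: np.ndarray):
    """t test of a single contrast c'beta with Satterthwaite df.

    Returns (estimate, se, df, t, two-sided p).
    """
    c = np.asarray(c, dtype=float)
    est = float(c @ res.beta)
    se = float(np.sqrt(c @ res.cov_beta @ c))
    df = float(satterthwaite_df_multi(res, c[None, :])[0])
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return est, se, df, t, p


def wald_F(res: LMMResult, L: np.ndarray):
    """F test of the multi-row hypothesis L beta = 0.

    The denominator df pools per-eigencontrast Satterthwaite dfs following
    the standard mixed-model construction.  Returns (F, ndf, ddf, p).
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = np.linalg.matrix_rank(L)
    M = L @ res.cov_beta @ L.T
    evals, evecs = np.linalg.eigh(M)
    keep = evals > max(evals.max(), 0) * 1e-10
    U = (evecs[:, keep] / np.sqrt(evals[keep])).T  # rows: scaled eigencontrasts
    tvals = U @ (L @ res.beta)
    F = float(tvals @ tvals) / q
    Crows = U @ L
    dfs = satterthwaite_df_multi(res, Crows)
    # pool: E = sum d/(d-2); ddf = 2E/(E-q) when E > q
    d_ok = dfs[np.isfinite(dfs) & (dfs > 2)]
    if len(d_ok) == 0:
        ddf = np.inf
    else:
        E = float(np.sum(d_ok / (d_ok - 2.0)))
        ddf = 2.0 * E / (E - q) if E > q else np.inf
    p = float(stats.f.sf(F, q, ddf)) if np.isfinite(ddf) else float(stats.chi2.sf(F * q, q))
    return F, int(q), float(ddf), p


def lr_test(fit_small: LMMResult, fit_big: LMMResult, clamp: bool = True):
    """Likelihood-ratio chi-square between two ML fits.

    Returns (chi2, df, p).  ``clamp`` truncates a negative statistic (which
    can arise for non-nested pairs) at 0, matching the reporting convention
    of sequential ladder comparisons.
    """
    if fit_small.method != "ml" or fit_big.method != "ml":
        raise ValueError("likelihood-ratio tests require ML fits")
    chi2 = fit_small.neg2ll - fit_big.neg2ll
    if clamp:
        chi2 = max(chi2, 0.0)
    df = fit_big.k_params - fit_small.k_params
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return float(chi2), int(df), p
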