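"""Variance-component estimation for linear mixed models with crossed
random intercepts.

The model is

    y = X beta + sum_e Z_e u_e + eps,     u_e ~ N(0, sigma2_e I),
                                          eps ~ N(0, sigma2_r I),

with every random effect a vector of independent level intercepts.  Variance
components are estimated by REML with non-negativity constraints (L-BFGS-B on
the restricted log-likelihood with analytic gradient, started from the
method-of-moments solution and polished by active-set Newton steps).  A
closed-form method-of-moments (expected-mean-squares) estimator — solving the
linear system that equates between-level sums of squares to their
expectations — serves both as the starting point and as the fallback when
REML does not converge; on balanced designs it coincides with the classical
ANOVA estimator, and hence with REML whenever all estimates are interior.

Fixed-effect tests are Wald F statistics (1 df) with Satterthwaite
denominator degrees of freedom computed from the REML information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
import scipy.optimize
import scipy.stats

__all__ = [
    "VarCompFit",
    "build_random_design",
    "mom_fit",
    "reml_fit",
    "wald_f_test",
]

RESIDUAL = "Residual"


@dataclass
class VarCompFit:
    """Result of one variance-component fit."""

    effect_names: list          # random effects, residual last
    sigma2: np.ndarray          # same order, non-negative
    beta: np.ndarray
    cov_beta: np.ndarray        # (X' V^-1 X)^-1
    loglik: float               # restricted log-likelihood (up to constant)
    converged: bool
    backend: str                # "REML" or "MoM"

    def sigma2_dict(self) -> dict:
        return dict(zip(self.effect_names, self.sigma2))

    def fractions(self) -> dict:
        """Non-negative variance fractions summing to 1."""
        s = np.clip(self.sigma2, 0.0, None)
        total = s.sum()
        if total <= 0:
            out = {name: 0.0 for name in self.effect_names}
            out[RESIDUAL] = 1.0
            return out
        return dict(zip(self.effect_names, s / total))


def build_random_design(labels: dict) -> tuple[list, list]:
    """Indicator design matrices for each random effect.

    ``labels`` maps effect name -> per-observation level labels.  Returns
    ``(names, Z_list)`` with one dense 0/1 matrix (n x n_levels) per effect,
    levels in sorted order.
    """
    names, zs = [], []
    for name, lab in labels.items():
        lab = np.asarray(lab)
        levels, idx = np.unique(lab, return_inverse=True)
        Z = np.zeros((len(lab), len(levels)))
        Z[np.arange(len(lab)), idx] = 1.0
        names.append(name)
        zs.append(Z)
    return names, zs


def _grams(zs: list) -> list:
    return [Z @ Z.T for Z in zs]


# ---------------------------------------------------------------------------
# Method of moments (expected mean squares)
# ---------------------------------------------------------------------------

def mom_fit(y: np.ndarray, zs: list, X: np.ndarray | None = None) -> np.ndarray:
    """Expected-mean-squares estimator of (sigma2_effects..., sigma2_resid).

    Equates the between-level sum of squares of every effect, plus the total
    sum of squares, to their expectations under the model and solves the
    resulting linear system by non-negative least squares.  With fixed
    effects beyond the intercept, ``y`` is first residualized on ``X`` by
    ordinary least squares (the estimator is then approximate and used only
    as a starting value / fallback).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is not None and X.shape[1] > 1:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta + y.mean() * 0.0
    yc = y - y.mean()
    gs = _grams(zs)
    E = len(zs)
    # quadratic forms: A_e = M_e - J/n (between-level), A_tot = I - J/n
    ms = []
    for Z in zs:
        counts = Z.sum(axis=0)
        ms.append((Z / counts) @ Z.T)
    stats = []
    coefs = np.zeros((E + 1, E + 1))
    for i, M in enumerate(ms):
        stats.append(yc @ (M @ yc) - 0.0)  # (M - J/n) on centered y = M yc . yc
        for j, G in enumerate(gs):
            coefs[i, j] = np.einsum("ij,ji->", M, G) - G.mean() * n
        coefs[i, E] = np.trace(M) - 1.0
    stats.append(yc @ yc)
    for j, G in enumerate(gs):
        coefs[E, j] = np.trace(G) - G.mean() * n
    coefs[E, E] = n - 1.0
    stats = np.asarray(stats)
    sigma2, _ = scipy.optimize.nnls(coefs, stats)
    return sigma2


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _reml_nll_grad(theta, gs, X, y):
    """Negative restricted log-likelihood and gradient wrt variance params."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], gs):
        V += t * G
    try:
        cf = la.cho_factor(V, check_finite=False)
    except la.LinAlgError:
        return np.inf, np.zeros_like(theta)
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    Vi = la.cho_solve(cf, np.eye(n), check_finite=False)
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    C = np.linalg.inv(XtViX)
    P = Vi - ViX @ C @ ViX.T
    Py = P @ y
    nll = 0.5 * (logdet_v + logdet_x + y @ Py)
    grad = np.empty_like(theta)
    for e, G in enumerate(gs):
        grad[e] = 0.5 * (np.einsum("ij,ji->", P, G) - Py @ (G @ Py))
    grad[-1] = 0.5 * (np.trace(P) - Py @ Py)
    return nll, grad


def _newton_polish(theta, gs, X, y, tol=1e-10, max_iter=50):
    """Active-set Newton refinement of an L-BFGS-B solution."""
    theta = theta.copy()
    scale = max(theta.max(), 1e-12)
    nll, grad = _reml_nll_grad(theta, gs, X, y)
    for _ in range(max_iter):
        free = (theta > 1e-10 * scale) | (grad < 0)
        if not free.any() or np.abs(grad[free]).max() < tol:
            break
        idx = np.where(free)[0]
        h = 1e-6 * np.maximum(theta[idx], 1e-3 * scale)
        H = np.zeros((len(idx), len(idx)))
        for a, i in enumerate(idx):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[a]
            tm[i] = max(tm[i] - h[a], 0.0)
            _, gp = _reml_nll_grad(tp, gs, X, y)
            _, gm = _reml_nll_grad(tm, gs, X, y)
            H[a] = (gp[idx] - gm[idx]) / (tp[i] - tm[i])
        H = (H + H.T) / 2.0
        try:
            step = np.linalg.solve(H + 1e-12 * scale * np.eye(len(idx)), grad[idx])
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1, 0.01):
            cand = theta.copy()
            cand[idx] = np.clip(theta[idx] - damp * step, 0.0, None)
            nll_c, grad_c = _reml_nll_grad(cand, gs, X, y)
            if nll_c <= nll + 1e-12:
                theta, nll, grad = cand, nll_c, grad_c
                improved = True
                break
        if not improved:
            break
    return theta, nll, grad


def reml_fit(
    y: np.ndarray,
    zs: list,
    effect_names: list,
    X: np.ndarray | None = None,
    tol: float = 1e-8,
) -> VarCompFit:
    """Constrained REML fit; falls back to method of moments on failure."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    gs = _grams(zs)
    names = list(effect_names) + [RESIDUAL]

    sd = y.std()
    if sd == 0 or not np.isfinite(sd):
        # degenerate response: no information about any component
        return VarCompFit(
            effect_names=names,
            sigma2=np.zeros(len(names)),
            beta=np.full(X.shape[1], y[0] if n else np.nan),
            cov_beta=np.zeros((X.shape[1], X.shape[1])),
            loglik=np.nan,
            converged=False,
            backend="degenerate",
        )
    ys = y / sd

    mom = mom_fit(ys, zs, X)
    starts = [np.clip(mom, 1e-6, None)]
    starts.append(np.full(len(names), 1.0 / len(names)))
    best = None
    for start in starts:
        res = scipy.optimize.minimize(
            _reml_nll_grad,
            start,
            args=(gs, X, ys),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * len(start),
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta, nll, grad = _newton_polish(best.x, gs, X, ys)
    free = (theta > 1e-10) | (grad < 0)
    converged = bool(np.isfinite(nll)) and (
        not free.any() or np.abs(grad[free]).max() < max(tol, 1e-6)
    )

    if not converged and not best.success:
        theta = np.clip(mom, 0.0, None)
        backend = "MoM"
    else:
        backend = "REML"

    # GLS fixed effects and covariance at the final variance estimates
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], gs):
        V += t * G
    V += 1e-12 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    C = np.linalg.inv(XtViX)
    beta = C @ (X.T @ (Vi @ ys))
    return VarCompFit(
        effect_names=names,
        sigma2=theta * sd**2,
        beta=beta * sd,
        cov_beta=C * sd**2,
        loglik=float(-nll),
        converged=converged,
        backend=backend,
    )


# ---------------------------------------------------------------------------
# Satterthwaite F tests
# ---------------------------------------------------------------------------

def _information_matrix(theta, gs, X, y):
    """Observed REML information (numeric Jacobian of the analytic gradient)."""
    k = len(theta)
    scale = max(theta.max(), 1e-8)
    H = np.zeros((k, k))
    for i in range(k):
        h = 1e-6 * max(theta[i], 1e-3 * scale)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 0.0)
        _, gp = _reml_nll_grad(tp, gs, X, y)
        _, gm = _reml_nll_grad(tm, gs, X, y)
        H[i] = (gp - gm) / (tp[i] - tm[i])
    return (H + H.T) / 2.0


def _cov_contrast(theta, gs, X, contrast):
    n = X.shape[0]
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], gs):
        V += t * G
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    return contrast @ C @ contrast


def wald_f_test(fit: VarCompFit, zs: list, X: np.ndarray, y: np.ndarray, contrast):
    """1-df Wald F test with Satterthwaite denominator df.

    Returns ``(F, df_denominator, p_value)`` for ``H0: c' beta = 0``.
    """
    contrast = np.asarray(contrast, dtype=float)
    gs = _grams(zs)
    y = np.asarray(y, dtype=float)
    sd = y.std()
    ys = y / sd
    theta = fit.sigma2 / sd**2

    g = _cov_contrast(theta, gs, X, contrast)
    est = contrast @ (fit.beta / sd)
    F = est**2 / g

    # delta-method variance of g(theta)
    k = len(theta)
    scale = max(theta.max(), 1e-8)
    grad_g = np.zeros(k)
    for i in range(k):
        h = 1e-6 * max(theta[i], 1e-3 * scale)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 0.0)
        grad_g[i] = (
            _cov_contrast(tp, gs, X, contrast) - _cov_contrast(tm, gs, X, contrast)
        ) / (tp[i] - tm[i])
    info = _information_matrix(theta, gs, X, ys)
    cov_theta = np.linalg.pinv(info)
    var_g = grad_g @ cov_theta @ grad_g
    n, p = X.shape
    if var_g <= 0 or not np.isfinite(var_g):
        df = float(n - p)
    else:
        df = 2.0 * g**2 / var_g
        df = float(np.clip(df, 1.0, 1e6))
    p_value = float(scipy.stats.f.sf(F, 1, df))
    return float(F), df, p_value
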