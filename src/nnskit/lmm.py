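"""Random-intercept linear mixed model with Satterthwaite degrees of freedom.

Model: y = X beta + Z u + e, with one random intercept per subject,
u_i ~ N(0, sigma_b^2), e ~ N(0, sigma_e^2 I), estimated by REML.

The block structure of V = sigma_e^2 (I + lambda Z Z') with
lambda = sigma_b^2 / sigma_e^2 gives closed-form per-group inverses
(Sherman-Morrison), so the REML criterion is profiled down to a
one-dimensional search over lambda.  Denominator degrees of freedom for
t and multi-df F tests use the Satterthwaite approximation: for a
contrast l, df = 2 phi^2 / (g' W g) with phi = l' C(theta) l, g its
gradient in theta = (sigma_b^2, sigma_e^2), and W the inverse observed
REML information.  Multi-df F combines per-eigenvector Satterthwaite
df the standard way (sum of nu/(nu-2) terms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

_SINGULAR_LAMBDA = 1e-7


@dataclass
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: float
    p: float


@dataclass
class FTestResult:
    f: float
    df_num: float
    df_den: float
    p: float


@dataclass
class LMMFit:
    """Fitted random-intercept LMM (REML)."""

    beta: np.ndarray
    names: List[str]
    sigma2_b: float
    sigma2_e: float
    cov_beta: np.ndarray
    n_obs: int
    n_groups: int
    singular: bool
    warnings: List[str] = field(default_factory=list)
    _model: Optional["RandomInterceptLMM"] = None

    @property
    def lam(self) -> float:
        return self.sigma2_b / self.sigma2_e if self.sigma2_e > 0 else 0.0

    def contrast(self, l: Sequence[float]) -> ContrastResult:
        """t-test of a single contrast l' beta with Satterthwaite df."""
        l = np.asarray(l, dtype=float)
        est = float(l @ self.beta)
        var = float(l @ self.cov_beta @ l)
        se = np.sqrt(var)
        df = self._model.satterthwaite_df(l, self) if self._model else self.n_obs - len(self.beta)
        t = est / se if se > 0 else np.nan
        p = 2.0 * t_dist.sf(abs(t), df) if np.isfinite(t) else np.nan
        return ContrastResult(estimate=est, se=se, t=t, df=df, p=p)

    def wald_f(self, L: np.ndarray) -> FTestResult:
        """Multi-df Wald F of L beta = 0 with combined Satterthwaite df."""
        L = np.atleast_2d(np.asarray(L, dtype=float))
        M = L @ self.cov_beta @ L.T
        evals, evecs = np.linalg.eigh(M)
        tol = max(M.shape) * np.finfo(float).eps * max(evals.max(), 0.0)
        keep = evals > max(tol, 1e-14)
        q = int(keep.sum())
        if q == 0:
            raise ValueError("no contrast estimable (rank-zero hypothesis matrix)")
        t2 = []
        nus = []
        for j in np.nonzero(keep)[0]:
            lj = L.T @ evecs[:, j]  # contrast in beta space
            est = float(lj @ self.beta)
            t2.append(est**2 / evals[j])
            nu = self._model.satterthwaite_df(lj, self) if self._model else self.n_obs - len(self.beta)
            nus.append(nu)
        F = float(np.sum(t2)) / q
        nus = np.asarray(nus, dtype=float)
        if np.all(nus > 2):
            E = float(np.sum(nus / (nus - 2.0)))
            df_den = 2.0 * E / (E - q) if E > q else float(self.n_obs - len(self.beta))
        else:
            df_den = float(self.n_obs - len(self.beta))
        p = float(f_dist.sf(F, q, df_den))
        return FTestResult(f=F, df_num=float(q), df_den=df_den, p=p)


class RandomInterceptLMM:
    """REML estimation of a linear model with one random intercept per group."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: Sequence, names: Optional[List[str]] = None):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("y and X must be finite (drop missing rows upstream)")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("no contrast estimable: design matrix is rank deficient")
        self.y = y
        self.X = X
        self.names = names or [f"x{j}" for j in range(X.shape[1])]
        g = np.asarray(groups).astype(str)
        self.group_codes = np.searchsorted(np.unique(g), g)
        self.n_groups = int(self.group_codes.max()) + 1
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        self.n, self.p = X.shape
        # per-group sufficient statistics
        self.S_xx = X.T @ X
        self.S_xy = X.T @ y
        self.S_yy = float(y @ y)
        self.n_i = np.bincount(self.group_codes, minlength=self.n_groups).astype(float)
        self.a_i = np.zeros((self.n_groups, self.p))
        for j in range(self.p):
            self.a_i[:, j] = np.bincount(self.group_codes, weights=X[:, j], minlength=self.n_groups)
        self.b_i = np.bincount(self.group_codes, weights=y, minlength=self.n_groups)

    # -- core algebra ------------------------------------------------------

    def _parts(self, lam: float):
        c = lam / (1.0 + lam * self.n_i)
        A = self.S_xx - (self.a_i.T * c) @ self.a_i
        v = self.S_xy - self.a_i.T @ (c * self.b_i)
        q_yy = self.S_yy - float(c @ self.b_i**2)
        return A, v, q_yy, c

    def _profile(self, lam: float):
        A, v, q_yy, _ = self._parts(lam)
        beta = np.linalg.solve(A, v)
        q = q_yy - float(v @ beta)
        q = max(q, 1e-300)
        logdet_U = float(np.sum(np.log1p(lam * self.n_i)))
        sign, logdet_A = np.linalg.slogdet(A)
        return beta, q, logdet_U, logdet_A, A

    def _crit(self, lam: float) -> float:
        _, q, logdet_U, logdet_A, _ = self._profile(lam)
        r = self.n - self.p
        return r * np.log(q / r) + logdet_U + logdet_A

    def neg2_reml(self, sigma2_b: float, sigma2_e: float) -> float:
        """-2 x restricted log-likelihood at theta (up to an additive constant)."""
        lam = sigma2_b / sigma2_e
        _, q, logdet_U, logdet_A, _ = self._profile(lam)
        return (
            (self.n - self.p) * np.log(sigma2_e)
            + logdet_U
            + logdet_A
            + q / sigma2_e
        )

    # -- fitting -----------------------------------------------------------

    def fit(self, force_zero_variance: bool = False) -> LMMFit:
        msgs: List[str] = []
        if force_zero_variance:
            lam = 0.0
        else:
            res = optimize.minimize_scalar(
                lambda s: self._crit(np.exp(s)), bounds=(-14.0, 14.0), method="bounded",
                options={"xatol": 1e-8},
            )
            lam = float(np.exp(res.x))
            if self._crit(0.0) <= res.fun:
                lam = 0.0
        singular = lam < _SINGULAR_LAMBDA
        if singular and not force_zero_variance:
            msgs.append("singular fit: random-intercept variance estimated at the zero boundary")
            warnings.warn(msgs[-1], RuntimeWarning, stacklevel=2)
        beta, q, _, _, A = self._profile(lam)
        sigma2_e = q / (self.n - self.p)
        sigma2_b = lam * sigma2_e
        cov_beta = sigma2_e * np.linalg.inv(A)
        fit = LMMFit(
            beta=beta,
            names=list(self.names),
            sigma2_b=sigma2_b,
            sigma2_e=sigma2_e,
            cov_beta=cov_beta,
            n_obs=self.n,
            n_groups=self.n_groups,
            singular=singular,
            warnings=msgs,
            _model=self,
        )
        return fit

    # -- Satterthwaite -----------------------------------------------------

    def _phi(self, l: np.ndarray, sigma2_b: float, sigma2_e: float) -> float:
        lam = sigma2_b / sigma2_e
        A, _, _, _ = self._parts(lam)
        return float(sigma2_e * (l @ np.linalg.solve(A, l)))

    def satterthwaite_df(self, l: np.ndarray, fit: LMMFit) -> float:
        """Satterthwaite denominator df for the contrast l' beta."""
        resid_df = float(self.n - self.p)
        theta = np.array([fit.sigma2_b, fit.sigma2_e], dtype=float)
        if fit.singular or theta[0] <= 0:
            return resid_df
        try:
            H = _numeric_hessian(lambda th: self.neg2_reml(th[0], th[1]), theta)
            W = 2.0 * np.linalg.inv(H)  # asymptotic covariance of theta-hat
            g = _numeric_gradient(lambda th: self._phi(l, th[0], th[1]), theta)
            denom = float(g @ W @ g)
            phi = self._phi(l, theta[0], theta[1])
            if denom <= 0 or not np.isfinite(denom):
                return resid_df
            df = 2.0 * phi**2 / denom
        except np.linalg.LinAlgError:
            return resid_df
        if not np.isfinite(df) or df <= 1.0:
            return resid_df
        # the approximation cannot exceed the residual df by much on this design
        return min(df, resid_df)


def _steps(theta: np.ndarray) -> np.ndarray:
    return np.maximum(1e-4 * np.abs(theta), 1e-8)


def _numeric_gradient(f, theta: np.ndarray) -> np.ndarray:
    h = _steps(theta)
    g = np.zeros_like(theta)
    for j in range(theta.size):
        hp = theta.copy(); hp[j] += h[j]
        hm = theta.copy(); hm[j] = max(hm[j] - h[j], 1e-12)
        g[j] = (f(hp) - f(hm)) / (hp[j] - hm[j])
    return g


def _numeric_hessian(f, theta: np.ndarray) -> np.ndarray:
    h = _steps(theta)
    k = theta.size
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(np.maximum(theta - ei, 1e-12))) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(np.maximum(theta + ei - ej, 1e-12))
            fmp = f(np.maximum(theta - ei + ej, 1e-12))
            fmm = f(np.maximum(theta - ei - ej, 1e-12))
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H
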