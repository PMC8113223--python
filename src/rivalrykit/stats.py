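"""Inferential battery for within-subject rivalry designs.

Implements the classical repeated-measures ANOVA decomposition with
Greenhouse-Geisser sphericity correction, paired contrasts with Bonferroni
adjustment, the default JZS (Cauchy-prior) Bayes factor for paired designs,
a random-intercept logistic regression fitted by adaptive Gauss-Hermite
quadrature, and Pearson correlations.

All effects in the ANOVA are computed through orthonormal within-subject
contrast scores: for an effect with orthonormal contrast matrix C over the
cell means, the subject scores Z = Y C' give SS_effect = n * ||mean(Z)||^2
and the error SS as the residual variation of Z, while the covariance of Z
yields the Box/Greenhouse-Geisser epsilon for that effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps


# ---------------------------------------------------------------------------
# result containers

@dataclass
class EffectResult:
    name: str
    ss: float
    ss_error: float
    df_num: int
    df_den: int
    F: float
    p: float
    gg_epsilon: float | None = None
    df_num_gg: float | None = None
    df_den_gg: float | None = None
    p_gg: float | None = None


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    n_subjects: int
    within: list[str]
    levels: dict[str, list]
    dv: str

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append({
                "effect": e.name, "ss": e.ss, "ss_error": e.ss_error,
                "df_num": e.df_num, "df_den": e.df_den, "F": e.F, "p": e.p,
                "gg_epsilon": e.gg_epsilon, "df_num_gg": e.df_num_gg,
                "df_den_gg": e.df_den_gg, "p_gg": e.p_gg,
            })
        return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    d_z: float
    sided: str = "two"
    p_adjusted: float | None = None


@dataclass
class BFResult:
    bf10: float
    rscale: float
    error_bound: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass
class LogisticFit:
    beta: float
    se: float
    z: float
    p: float
    odds_ratio: float
    intercept: float
    sigma2_intercept: float
    n_obs: int
    n_subjects: int
    method: str
    n_quad: int = 0
    loglik: float = math.nan


@dataclass
class CorResult:
    r: float
    df: int
    p: float
    n: int


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the space orthogonal to the mean."""
    basis = np.zeros((k, k - 1))
    basis[:-1, :] = np.eye(k - 1)
    basis -= basis.mean(axis=0)
    q, _ = np.linalg.qr(basis)
    return q.T


def rm_anova(table: pd.DataFrame, dv: str, within: list[str] | str,
             subject: str = "subject") -> AnovaResult:
    """Classical fully-within-subject ANOVA for one or two factors.

    ``table`` is long-format with one row per subject x cell (subject means,
    not trial-level rows).  Every subject must have every cell exactly once;
    otherwise the offending subjects and cells are named in the error.  For
    any effect involving a factor with more than two levels, the
    Greenhouse-Geisser epsilon and corrected degrees of freedom and p-value
    are reported alongside the uncorrected test.
    """
    if isinstance(within, str):
        within = [within]
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports one or two within factors")
    levels = {f: sorted(table[f].unique()) for f in within}
    dup = table.duplicated(subset=[subject] + within)
    if dup.any():
        raise ValueError(f"duplicate subject x cell rows: "
                         f"{table.loc[dup, [subject] + within].to_dict('records')}")
    wide = table.pivot_table(index=subject, columns=within, values=dv)
    full_cols = (pd.MultiIndex.from_product([levels[f] for f in within])
                 if len(within) == 2 else pd.Index(levels[within[0]]))
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        missing = [(str(subj), col) for subj, row in wide.iterrows()
                   for col, v in row.items() if pd.isna(v)]
        raise ValueError(f"unbalanced design; missing subject x cell values: {missing}")
    Y = wide.to_numpy(dtype=float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")

    ks = [len(levels[f]) for f in within]
    qs = [_orthonormal_contrast(k) for k in ks]
    us = [np.full((1, k), 1.0 / math.sqrt(k)) for k in ks]

    effects_spec: list[tuple[str, np.ndarray, list[int]]] = []
    if len(within) == 1:
        effects_spec.append((within[0], qs[0], [ks[0]]))
    else:
        effects_spec.append((within[0], np.kron(qs[0], us[1]), [ks[0]]))
        effects_spec.append((within[1], np.kron(us[0], qs[1]), [ks[1]]))
        effects_spec.append((f"{within[0]}:{within[1]}", np.kron(qs[0], qs[1]),
                             [ks[0], ks[1]]))

    effects: dict[str, EffectResult] = {}
    for name, C, factor_ks in effects_spec:
        Z = Y @ C.T  # n x df subject contrast scores
        zbar = Z.mean(axis=0)
        ss = float(n * np.sum(zbar ** 2))
        resid = Z - zbar
        ss_err = float(np.sum(resid ** 2))
        df_num = C.shape[0]
        df_den = df_num * (n - 1)
        F = (ss / df_num) / (ss_err / df_den)
        p = float(sps.f.sf(F, df_num, df_den))
        res = EffectResult(name=name, ss=ss, ss_error=ss_err, df_num=df_num,
                           df_den=df_den, F=F, p=p)
        if any(k > 2 for k in factor_ks):
            sigma = np.cov(Z, rowvar=False, ddof=1)
            sigma = np.atleast_2d(sigma)
            eps = float(np.trace(sigma) ** 2 / (df_num * np.sum(sigma * sigma)))
            eps = min(1.0, max(1.0 / df_num, eps))
            res.gg_epsilon = eps
            res.df_num_gg = eps * df_num
            res.df_den_gg = eps * df_den
            res.p_gg = float(sps.f.sf(F, res.df_num_gg, res.df_den_gg))
        effects[name] = res
    return AnovaResult(effects=effects, n_subjects=n, within=list(within),
                       levels=levels, dv=dv)


def gg_epsilon(cell_covariance: np.ndarray, k: int | None = None) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-subject cell covariance.

    Computed on the double-centered covariance and clamped to
    [1/(k-1), 1]; equals 1 exactly under compound symmetry.
    """
    S = np.asarray(cell_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ValueError("need a k x k covariance with k >= 2")
    if k is None:
        k = S.shape[0]
    H = np.eye(k) - np.full((k, k), 1.0 / k)
    St = H @ S @ H
    denom = (k - 1) * np.sum(St * St)
    if denom <= 0:
        raise ValueError("degenerate covariance (double-centered matrix is zero)")
    eps = float(np.trace(St) ** 2 / denom)
    return min(1.0, max(1.0 / (k - 1), eps))


# ---------------------------------------------------------------------------
# paired t and adjustments

def paired_t(x, y, sided: str = "two") -> TTestResult:
    """Classical paired t-test with the standardized effect d_z.

    ``sided``: "two", "greater" (mean(x - y) > 0) or "less".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    if sided == "two":
        p = 2 * sps.t.sf(abs(t), df)
    elif sided == "greater":
        p = sps.t.sf(t, df)
    elif sided == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown sided {sided!r}")
    return TTestResult(t=float(t), df=df, p=float(p), mean_diff=float(d.mean()),
                       d_z=float(d.mean() / sd), sided=sided)


def bonferroni_adjust(pvals, m: int | None = None) -> list[float]:
    """min(1, p * m) for an explicit family size m (default: len(pvals))."""
    pvals = list(pvals)
    if m is None:
        m = len(pvals)
    if m < len(pvals):
        raise ValueError(f"family size m={m} smaller than number of p-values {len(pvals)}")
    if any(not 0 <= p <= 1 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in pvals]


# ---------------------------------------------------------------------------
# JZS Bayes factor (one-sample / paired)

def jzs_bf10_paired(t: float, n: int, rscale: float = math.sqrt(2) / 2) -> BFResult:
    """Default JZS Bayes factor BF10 for a paired/one-sample t statistic.

    The alternative places a Cauchy(0, rscale) prior on the standardized
    effect; integrating out the effect is equivalent to a one-dimensional
    integral over the g mixing variable (g ~ InverseGamma(1/2, rscale^2/2)),
    evaluated here in log space by adaptive quadrature.  The reported error
    bound is the quadrature's relative error estimate; values failing the
    1e-6 relative bound raise.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if rscale <= 0:
        raise ValueError("rscale must be > 0")
    nu = n - 1
    t2 = float(t) ** 2
    log_den = -(nu + 1) / 2 * math.log1p(t2 / nu)

    r2 = rscale ** 2

    def log_f(u: np.ndarray) -> np.ndarray:
        # integrand over u = log g, prior Jacobian included
        with np.errstate(over="ignore"):
            g = np.exp(u)
            return (-0.5 * np.log1p(n * g)
                    - (nu + 1) / 2 * np.log1p(t2 / (nu * (1.0 + n * g)))
                    + math.log(rscale) - 0.5 * math.log(2 * math.pi)
                    - 0.5 * u - r2 / 2.0 * np.exp(-u))

    grid = np.linspace(-30, 30, 2001)
    fmax = float(np.max(log_f(grid)))

    def integrand(u: float) -> float:
        return math.exp(float(log_f(np.asarray(u))) - fmax)

    val, err = integrate.quad(integrand, -np.inf, np.inf, limit=400,
                              epsabs=1e-12, epsrel=1e-10)
    if val <= 0 or not math.isfinite(val):
        raise RuntimeError(f"JZS integration failed (value {val})")
    rel_err = err / val
    if rel_err > 1e-6:
        raise RuntimeError(f"JZS integration did not reach 1e-6 relative error: {rel_err:.2e}")
    log_num = fmax + math.log(val)
    return BFResult(bf10=math.exp(log_num - log_den), rscale=rscale, error_bound=rel_err)


# ---------------------------------------------------------------------------
# random-intercept logistic regression (adaptive Gauss-Hermite)

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _suff_stats(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject (successes, trials) for free and blocked conditions."""
    grp = records.groupby("subject")
    kf, nf, kb, nb = [], [], [], []
    for _, g in grp:
        f = g[g["mimicry"] == "free"]
        b = g[g["mimicry"] == "blocked"]
        kf.append((f["ip"] == "happy").sum()); nf.append(len(f))
        kb.append((b["ip"] == "happy").sum()); nb.append(len(b))
    return (np.array(kf, float), np.array(nf, float),
            np.array(kb, float), np.array(nb, float))


def fit_ip_logistic(records: pd.DataFrame, *, n_quad: int = 25,
                    constrain_zero_variance: bool = False) -> LogisticFit:
    """Random-intercept logistic regression of initial percept on mimicry.

    ``records`` holds one row per coded trial with columns subject, mimicry
    (free/blocked) and ip; rows with ip = "none" are dropped.  The outcome is
    a happy IP, the free condition is the reference, so ``beta`` is the
    blocked-vs-free log-odds shift and ``odds_ratio`` = exp(beta).

    The marginal likelihood over the Gaussian subject intercept is evaluated
    by adaptive Gauss-Hermite quadrature (mode- and curvature-adapted nodes,
    default 25 per subject; ``n_quad=1`` reduces to the Laplace
    approximation).  With ``constrain_zero_variance`` the model collapses to
    ordinary logistic regression, fitted via statsmodels.
    """
    records = records[records["ip"].isin(["happy", "neutral"])]
    if records["subject"].nunique() < 2:
        raise ValueError("need at least two subjects for a random-intercept model")
    pooled = records.groupby("mimicry")["ip"].value_counts().unstack(fill_value=0)
    if (pooled == 0).any().any() or set(pooled.index) != {"free", "blocked"}:
        raise ValueError("complete separation or empty condition: a mimicry x IP "
                         f"cell has zero trials\n{pooled}")
    kf, nf, kb, nb = _suff_stats(records)
    n_obs = int((nf + nb).sum())
    n_subj = len(kf)

    if constrain_zero_variance:
        import statsmodels.api as sm
        y = (records["ip"] == "happy").astype(float).to_numpy()
        X = sm.add_constant((records["mimicry"] == "blocked").astype(float).to_numpy())
        fit = sm.Logit(y, X).fit(disp=0)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        return LogisticFit(beta=beta, se=se, z=beta / se,
                           p=float(2 * sps.norm.sf(abs(beta / se))),
                           odds_ratio=math.exp(beta), intercept=float(fit.params[0]),
                           sigma2_intercept=0.0, n_obs=n_obs, n_subjects=n_subj,
                           method="ml-logit", loglik=float(fit.llf))

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    def negloglik(theta: np.ndarray) -> float:
        b0, b1, ls = theta
        sigma2 = math.exp(2 * ls)
        # subject-wise mode of log integrand via Newton (concave)
        u = np.zeros(n_subj)
        for _ in range(60):
            p0 = _sigmoid(b0 + u)
            p1 = _sigmoid(b0 + b1 + u)
            grad = kf - nf * p0 + kb - nb * p1 - u / sigma2
            hess = nf * p0 * (1 - p0) + nb * p1 * (1 - p1) + 1.0 / sigma2
            step = grad / hess
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        p0 = _sigmoid(b0 + u)
        p1 = _sigmoid(b0 + b1 + u)
        c = nf * p0 * (1 - p0) + nb * p1 * (1 - p1) + 1.0 / sigma2

        def h(uu: np.ndarray) -> np.ndarray:
            # uu is (n_subj, n_quad)
            e0 = b0 + uu
            e1 = b0 + b1 + uu
            return (kf[:, None] * e0 - nf[:, None] * np.logaddexp(0, e0)
                    + kb[:, None] * e1 - nb[:, None] * np.logaddexp(0, e1)
                    - uu ** 2 / (2 * sigma2)
                    - 0.5 * math.log(2 * math.pi * sigma2))

        scale = np.sqrt(2.0 / c)  # per subject
        uu = u[:, None] + scale[:, None] * nodes[None, :]
        hvals = h(uu)
        hmax = hvals.max(axis=1, keepdims=True)
        li = (scale * np.exp(hmax[:, 0])
              * np.sum(weights[None, :] * np.exp(nodes[None, :] ** 2 + hvals - hmax), axis=1))
        if np.any(li <= 0) or not np.all(np.isfinite(li)):
            return 1e12
        return -float(np.sum(np.log(li)))

    from scipy.optimize import minimize
    p_f = (kf.sum() + 0.5) / (nf.sum() + 1.0)
    p_b = (kb.sum() + 0.5) / (nb.sum() + 1.0)
    x0 = np.array([math.log(p_f / (1 - p_f)),
                   math.log(p_b / (1 - p_b)) - math.log(p_f / (1 - p_f)),
                   math.log(0.5)])
    opt = minimize(negloglik, x0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    theta = opt.x
    H = _numeric_hessian(negloglik, theta)
    try:
        cov = np.linalg.inv(H)
        se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se = math.nan
    beta = float(theta[1])
    z = beta / se if se and se > 0 else math.nan
    return LogisticFit(beta=beta, se=se, z=z,
                       p=float(2 * sps.norm.sf(abs(z))) if math.isfinite(z) else math.nan,
                       odds_ratio=math.exp(beta), intercept=float(theta[0]),
                       sigma2_intercept=math.exp(2 * theta[2]), n_obs=n_obs,
                       n_subjects=n_subj, method="aghq", n_quad=n_quad,
                       loglik=-float(opt.fun))


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]; xpm[j] -= h[j]
                xmp[i] -= h[i]; xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# correlation

def pearson_cor(x, y) -> CorResult:
    """Pearson correlation with the r(df) reporting convention, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return CorResult(r=float(r), df=x.size - 2, p=float(p), n=x.size)
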