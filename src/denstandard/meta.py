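"""Weighted mixed-model meta-regression of log densities.

Study-level abundances (and hence densities) are approximately log-normal,
and the relative standard error se(D)/D is the standard error of log(D).
The model for record i in landscape l is

    log(D*_i) = x_i' beta + u_l + e_i,
    u_l ~ N(0, tau^2),   e_i ~ N(0, sigma_eps^2 * s_i^2),

i.e. a linear mixed model with a landscape random intercept and residuals
scaled by known relative SEs s_i (lme4-style "weights" w_i = 1/s_i^2: the
weights multiply a common estimated residual scale sigma_eps^2). The
fixed-known-variance meta-analytic convention Var(e_i) = s_i^2 (sigma_eps
fixed at 1) is available via ``residual_scale="fixed"``.

beta is profiled out by generalized least squares inside a small variance
optimization; ML is used for likelihood-ratio tests and AICc, REML for
variance reporting. Model fit is summarised by the marginal R² for mixed
models (fixed-effect variance over total variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_BASELINES = {"forest_type": "lowland-hill", "disturbance": "primary"}
YEAR_ORIGIN = 1996  # years counted since the first compiled study


@dataclass
class MetaFit:
    """A fitted weighted mixed meta-regression."""

    beta: pd.Series
    se_beta: pd.Series
    tau2: float
    sigma2_eps: float
    log_lik: float
    method: str  # "ML" | "REML"
    n: int
    k_fixed: int
    k_var: int
    terms: tuple
    residual_scale: str
    boundary_tau: bool
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    s: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    cov_beta: np.ndarray = field(repr=False)

    @property
    def z(self) -> pd.Series:
        """Wald z statistics (large-sample; treat cautiously at small n)."""
        return self.beta / self.se_beta

    @property
    def p_values(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.z)), index=self.beta.index)

    @property
    def k(self) -> int:
        """Parameter count for information criteria: fixed + variance."""
        return self.k_fixed + self.k_var

    def fitted_fixed(self) -> np.ndarray:
        return self.X @ self.beta.to_numpy()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.beta,
            "se": self.se_beta,
            "z": self.z,
            "p": self.p_values,
            "percent": [effect_percent(b) for b in self.beta],
        })


def build_design(records: pd.DataFrame, fixed_terms) -> tuple:
    """Design matrix for the documented covariate encodings.

    ``forest_type`` (baseline lowland-hill) and ``disturbance`` (baseline
    primary) enter as 0/1 indicators; ``year`` is centred at 1996; any
    other numeric column enters as-is.
    """
    cols = {"Intercept": np.ones(len(records))}
    for term in fixed_terms:
        if term == "forest_type":
            cols["forest_type[peat-montane]"] = (
                records["forest_type"].to_numpy() == "peat-montane"
            ).astype(float)
        elif term == "disturbance":
            cols["disturbance[logged]"] = (
                records["disturbance"].to_numpy() == "logged"
            ).astype(float)
        elif term == "year":
            cols["year_since_1996"] = records["year"].to_numpy(float) - YEAR_ORIGIN
        else:
            cols[term] = records[term].to_numpy(float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design over terms {list(fixed_terms)}")
    return X, names


def _records_arrays(records: pd.DataFrame):
    if "y" in records and "s" in records:
        y = records["y"].to_numpy(float)
        s = records["s"].to_numpy(float)
    else:
        y = np.log(records["density"].to_numpy(float))
        s = (records["se_density"] / records["density"]).to_numpy(float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite log densities")
    if (s <= 0).any():
        raise ValueError("relative SEs must be positive")
    groups = records["landscape"].to_numpy()
    return y, s, groups


class _SortedData:
    """Records sorted by landscape, with reduceat segment starts, so the
    blockwise quantities vectorize."""

    def __init__(self, X, y, s, groups):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order]
        self.s2 = s[order] ** 2
        g = np.asarray(groups)[order]
        self.starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self.n, self.k = X.shape


def _nll_profiled(theta, data: _SortedData, method, residual_scale, fix_tau2=None):
    """-2x profile log-likelihood in the variance parameters; beta by GLS.

    Returns (deviance, beta, cov_beta). V is block diagonal by landscape,
    V_g = sigma_eps^2 diag(s_g^2) + tau^2 11'; its inverse and determinant
    use the rank-one (Sherman-Morrison) forms, so the whole evaluation is a
    handful of segmented reductions.
    """
    if fix_tau2 is not None:
        tau2 = float(fix_tau2)
        sigma2 = 1.0 if residual_scale == "fixed" else np.exp(theta[0])
    elif residual_scale == "fixed":
        sigma2 = 1.0
        tau2 = np.exp(theta[0])
    else:
        sigma2, tau2 = np.exp(theta)
    if not np.isfinite(sigma2) or not np.isfinite(tau2):
        return np.inf, None, None
    X, y, s2, starts = data.X, data.y, data.s2, data.starts
    n, k = data.n, data.k
    inv_a = 1.0 / (sigma2 * s2)
    ginv = np.add.reduceat(inv_a, starts)  # sum 1/a per group
    denom = 1.0 + tau2 * ginv
    c = tau2 / denom  # Sherman-Morrison factor per group
    Xw = X * inv_a[:, None]
    t = np.add.reduceat(Xw, starts, axis=0)  # (G, k): X_g' a_g^-1 1
    u = np.add.reduceat(y * inv_a, starts)  # (G,)
    xtvx = X.T @ Xw - (t * c[:, None]).T @ t
    xtvy = Xw.T @ y - t.T @ (c * u)
    ytvy = float(y @ (y * inv_a) - c @ u**2)
    try:
        cov = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    beta = cov @ xtvy
    rss = ytvy - 2 * beta @ xtvy + beta @ xtvx @ beta
    logdet = float(np.log(sigma2 * s2).sum() + np.log(denom).sum())
    dev = logdet + rss + n * np.log(2 * np.pi)
    if method == "REML":
        sign, ld2 = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return np.inf, None, None
        dev += ld2 - k * np.log(2 * np.pi)
    return dev, beta, cov


def fit_meta_lmm(
    records: pd.DataFrame,
    fixed_terms=(),
    method: str = "ML",
    residual_scale: str = "estimated",
    fix_tau2: float | None = None,
) -> MetaFit:
    """Fit the weighted landscape-random-intercept meta-regression.

    ``records`` needs ``density``/``se_density`` (or precomputed ``y``/``s``)
    plus ``landscape`` and the covariate columns named in ``fixed_terms``.
    ``fix_tau2`` pins the random-intercept variance (0 drops the random
    effect, giving pure weighted least squares).
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if residual_scale not in ("estimated", "fixed"):
        raise ValueError("residual_scale must be 'estimated' or 'fixed'")
    y, s, groups = _records_arrays(records)
    X, names = build_design(records, fixed_terms)
    n, k = X.shape
    if n <= k:
        raise ValueError("more fixed-effect parameters than records")

    data = _SortedData(X, y, s, groups)

    def obj(th):
        return _nll_profiled(th, data, method, residual_scale, fix_tau2)[0]

    # variance scale of the weighted residuals seeds the search
    w_var = float(np.var(y / s)) if n > 1 else 1.0
    v0 = np.log(max(np.var(y), 1e-3))
    n_free = (0 if residual_scale == "fixed" else 1) + (0 if fix_tau2 is not None else 1)
    if n_free == 0:
        best_x = np.empty(0)
    else:
        if n_free == 1 and fix_tau2 is not None:
            starts = [np.array([v]) for v in (np.log(max(w_var, 1e-3)), 0.0, v0)]
        elif n_free == 1:
            starts = [np.array([v]) for v in (v0, v0 - 3, v0 + 2, -8.0)]
        else:
            starts = [
                np.array([np.log(max(w_var, 1e-3)), v0 - 1]),
                np.array([0.0, -2.0]),
                np.array([v0, -8.0]),
            ]
        best = None
        for th0 in starts:
            res = optimize.minimize(obj, th0, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        best_x = best.x
    dev, beta, cov = _nll_profiled(best_x, data, method, residual_scale, fix_tau2)
    if fix_tau2 is not None:
        tau2 = float(fix_tau2)
        sigma2 = 1.0 if residual_scale == "fixed" else float(np.exp(best_x[0]))
    elif residual_scale == "fixed":
        sigma2, tau2 = 1.0, float(np.exp(best_x[0]))
    else:
        sigma2, tau2 = (float(np.exp(v)) for v in best_x)
    k_var = n_free
    boundary = fix_tau2 is None and tau2 < 1e-6 * max(sigma2, 1.0)
    if boundary:
        tau2 = 0.0
    return MetaFit(
        beta=pd.Series(beta, index=names),
        se_beta=pd.Series(np.sqrt(np.diag(cov)), index=names),
        tau2=tau2,
        sigma2_eps=sigma2,
        log_lik=float(-0.5 * dev),
        method=method,
        n=n,
        k_fixed=k,
        k_var=k_var,
        terms=tuple(fixed_terms),
        residual_scale=residual_scale,
        boundary_tau=bool(boundary),
        X=X, y=y, s=s, groups=groups, cov_beta=cov,
    )


def lrt(fit_null: MetaFit, fit_alt: MetaFit) -> tuple:
    """Likelihood-ratio test of nested ML fits: (chi2, df, p)."""
    if fit_null.method != "ML" or fit_alt.method != "ML":
        raise ValueError("likelihood-ratio tests require ML fits")
    if fit_null.n != fit_alt.n:
        raise ValueError("fits must use the same records")
    df = fit_alt.k - fit_null.k
    if df < 0:
        raise ValueError("null model must be nested in the alternative")
    chi2 = max(2.0 * (fit_alt.log_lik - fit_null.log_lik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0 and chi2 == 0:
        p = 1.0
    return float(chi2), int(df), p


def aicc(fit: MetaFit) -> float:
    """Small-sample AIC: -2 log L + 2k + 2k(k+1)/(n-k-1).

    k counts fixed effects plus variance parameters, so deltas between
    candidate models are interpretable within this package's convention.
    """
    if fit.method != "ML":
        raise ValueError("AICc is computed from ML fits")
    n, k = fit.n, fit.k
    if n <= k + 1:
        raise ValueError("AICc undefined: n must exceed k + 1")
    return float(-2 * fit.log_lik + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def marginal_r2(fit: MetaFit) -> float:
    """Marginal R² for mixed models: fixed-effect variance over total.

    Total = Var(X beta) + tau^2 + mean residual variance
    (sigma_eps^2 * mean(s^2)).
    """
    vf = float(np.var(fit.fitted_fixed()))
    tot = vf + fit.tau2 + fit.sigma2_eps * float(np.mean(fit.s**2))
    return vf / tot if tot > 0 else 0.0


def effect_percent(beta_log: float) -> float:
    """Multiplicative effect as a percent: (exp(beta) - 1) * 100."""
    return float((np.exp(beta_log) - 1.0) * 100.0)


def effect_percent_rebased(beta_log: float) -> float:
    """The same effect re-based to the other level: (exp(-beta) - 1) * 100.

    A -31.9% logging effect re-bases to +46.8% 'higher in primary'.
    """
    return float((np.exp(-beta_log) - 1.0) * 100.0)


def model_comparison(records: pd.DataFrame, candidate_terms, **kwargs) -> pd.DataFrame:
    """ML fits, AICc and marginal R² across candidate fixed-term sets."""
    rows = []
    for terms in candidate_terms:
        fit = fit_meta_lmm(records, terms, method="ML", **kwargs)
        rows.append(dict(
            terms="+".join(terms) if terms else "(intercept)",
            k=fit.k, log_lik=fit.log_lik, aicc=aicc(fit),
            marginal_r2=marginal_r2(fit), tau2=fit.tau2,
        ))
    out = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    return out
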