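"""Statistical layer: mixed ANOVA, marginal-mean contrasts, t tests,
BIC-approximate Bayes factors, and random-intercept mixed regression.

Conventions: all tests are two-tailed at alpha = 0.05; confidence intervals
are 95%; effect sizes for ANOVA effects are partial eta squared
(``eta_p2 = F * df1 / (F * df1 + df2)``). Bayes factors are *approximate*,
derived from the BIC difference between the effect and no-effect models
(``BF10 = exp((BIC0 - BIC1) / 2)``) — a transparent default-prior-free
surrogate for package-specific default-Bayes-factor conventions.

Mixed regressions use a participant random intercept fitted by REML
(statsmodels), with Satterthwaite degrees of freedom computed from the
curvature of the REML log-likelihood in the variance parameters; a
residual-df fixed-effects fallback (flagged) covers singular fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "ContrastResult",
    "MixedLMResult",
    "mixed_anova",
    "emm_contrast",
    "t_tests",
    "mixed_lm",
    "bf10_approx",
    "bf10_from_sse",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p2: float
    bf10_approx: float


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    bf10_approx: float
    degenerate: bool = False


@dataclass(frozen=True)
class MixedLMResult:
    term: str
    beta: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    satterthwaite: bool


# ---------------------------------------------------------------------------
# Bayes factor approximations


def bf10_approx(loglik_0: float, loglik_1: float, n: int, k0: int, k1: int) -> float:
    """BIC-approximate Bayes factor for model 1 over model 0.

    ``BIC_i = k_i * ln(n) - 2 * loglik_i``; identical models give 1.0.
    """
    if n <= max(k0, k1):
        raise ValueError("n must exceed the number of parameters")
    bic0 = k0 * np.log(n) - 2.0 * loglik_0
    bic1 = k1 * np.log(n) - 2.0 * loglik_1
    return float(np.exp((bic0 - bic1) / 2.0))


def _gauss_loglik(sse: float, n: int) -> float:
    sse = max(float(sse), 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sse / n) + 1.0)


def bf10_from_sse(sse0: float, sse1: float, n: int, k0: int, k1: int) -> float:
    """BIC-approximate BF from residual sums of squares of nested Gaussian
    models (parameter counts include the residual variance)."""
    return bf10_approx(_gauss_loglik(sse0, n), _gauss_loglik(sse1, n), n, k0, k1)


def _bf_from_f(F: float, df1: int, df2: int) -> float:
    # SSE_reduced / SSE_full = 1 + df1 * F / df2 within the effect's stratum
    n_eff = df1 + df2 + 1
    with np.errstate(over="ignore"):
        log_bf = 0.5 * (n_eff * np.log1p(df1 * F / df2) - df1 * np.log(n_eff))
    return float(np.exp(np.clip(log_bf, -700, 700)))


# ---------------------------------------------------------------------------
# Mixed-design ANOVA


def _check_design(data, dv, within, between, subject):
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="count")
    if pivot.isna().any().any() or (pivot != 1).any().any():
        raise ValueError("each participant must have each within-level exactly once")
    groups = data.groupby(subject)[between].nunique()
    if (groups != 1).any():
        raise ValueError("each participant must belong to exactly one group")
    if data[between].nunique() != 2:
        raise ValueError("exactly two between-participant groups are required")
    per_group = data.groupby(between)[subject].nunique()
    if (per_group < 2).any():
        raise ValueError("each group needs at least two participants")


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "period",
    between: str = "group",
    subject: str = "participant_id",
) -> list:
    """Two-factor mixed ANOVA (one between-, one within-participant factor).

    Returns ``AnovaResult`` rows for the between effect, the within effect
    and their interaction. With a single within level the design degenerates
    to a one-way between-groups ANOVA (whose F equals the squared pooled t).
    """
    data = data.dropna(subset=[dv])
    n_within = data[within].nunique()
    if n_within == 1:
        _check_design(data, dv, within, between, subject)
        g0, g1 = [g[dv].to_numpy() for _, g in data.groupby(between)]
        F, p = sps.f_oneway(g0, g1)
        df1, df2 = 1, len(g0) + len(g1) - 2
        return [
            AnovaResult(between, float(F), df1, df2, float(p),
                        float(F * df1 / (F * df1 + df2)), _bf_from_f(F, df1, df2))
        ]
    _check_design(data, dv, within, between, subject)
    table = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    results = []
    for _, row in table.iterrows():
        F = float(row.get("F", np.nan))
        df1, df2 = int(row["DF1"]), int(row["DF2"])
        label = {between: between, "Interaction": f"{between} x {within}"}.get(
            row["Source"], within
        )
        p = float(row.get("p_unc", row.get("p-unc", np.nan)))
        if not np.isfinite(F) and float(row.get("SS", np.nan)) == 0.0:
            # a zero effect sum of squares is no effect, even when the
            # error stratum is also degenerate (0/0)
            F, p = 0.0, 1.0
        if np.isinf(F):
            eta, p = 1.0, 0.0
        else:
            eta = F * df1 / (F * df1 + df2) if F > 0 else 0.0
        results.append(
            AnovaResult(label, F, df1, df2, p, float(eta), _bf_from_f(F, df1, df2))
        )
    return results


def emm_contrast(
    data: pd.DataFrame,
    at,
    dv: str = "value",
    within: str = "period",
    between: str = "group",
    subject: str = "participant_id",
) -> ContrastResult:
    """Between-group difference of marginal means at one within-level.

    A pooled-variance two-sample t test (two-tailed, df = n1 + n2 - 2) on
    the per-participant values at that level; the estimate is first group
    minus second group in sorted label order.
    """
    if at not in set(data[within]):
        raise ValueError(f"unknown within-level {at!r}")
    sub = data[data[within] == at].dropna(subset=[dv])
    labels = sorted(sub[between].unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    a = sub.loc[sub[between] == labels[0], dv].to_numpy()
    b = sub.loc[sub[between] == labels[1], dv].to_numpy()
    return _two_sample_t(a, b, pooled=True)


# ---------------------------------------------------------------------------
# t tests


def _two_sample_t(a, b, pooled: bool) -> ContrastResult:
    n1, n2 = len(a), len(b)
    estimate = float(np.mean(a) - np.mean(b))
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        t = 0.0 if estimate == 0 else np.inf * np.sign(estimate)
        p = 1.0 if estimate == 0 else 0.0
        return ContrastResult(estimate, estimate, estimate, float(t),
                              n1 + n2 - 2, p, np.nan, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=pooled)
    ci = res.confidence_interval(0.95)
    sse1 = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    grand = np.concatenate([a, b])
    sse0 = np.sum((grand - grand.mean()) ** 2)
    bf = bf10_from_sse(sse0, sse1, n1 + n2, 2, 3)
    return ContrastResult(
        estimate, float(ci.low), float(ci.high), float(res.statistic),
        float(res.df), float(res.pvalue), bf,
    )


def t_tests(a, b, paired: bool = False) -> ContrastResult:
    """Paired or Welch independent t test with 95% CI and approximate BF.

    Paired comparisons with zero-variance differences are flagged
    degenerate (t guarded to 0 with p = 1 when the estimate is also 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        if len(a) < 2:
            raise ValueError("need at least two pairs")
        d = a - b
        estimate = float(d.mean())
        sd = d.std(ddof=1)
        n = len(d)
        if sd == 0:
            t = 0.0 if estimate == 0 else np.inf * np.sign(estimate)
            p = 1.0 if estimate == 0 else 0.0
            return ContrastResult(estimate, estimate, estimate, float(t), n - 1, p,
                                  np.nan, degenerate=True)
        res = sps.ttest_1samp(d, 0.0)
        ci = res.confidence_interval(0.95)
        sse1 = np.sum((d - d.mean()) ** 2)
        sse0 = np.sum(d**2)
        bf = bf10_from_sse(sse0, sse1, n, 1, 2)
        return ContrastResult(estimate, float(ci.low), float(ci.high),
                              float(res.statistic), n - 1, float(res.pvalue), bf)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    return _two_sample_t(a, b, pooled=False)


# ---------------------------------------------------------------------------
# Random-intercept mixed regression with Satterthwaite df


def _reml_pieces(theta, groups, X_list, y_list):
    """REML log-likelihood, beta covariance and beta for a random-intercept
    model; theta = (sigma_u^2, sigma_e^2)."""
    su2, se2 = theta
    xtvx = 0.0
    xtvy = 0.0
    logdet = 0.0
    for X, y in zip(X_list, y_list):
        n_i = len(y)
        shrink = su2 / (se2 + n_i * su2)
        Xs = X.sum(axis=0)
        ys = y.sum()
        xtvx = xtvx + (X.T @ X - shrink * np.outer(Xs, Xs)) / se2
        xtvy = xtvy + (X.T @ y - shrink * Xs * ys) / se2
        logdet += (n_i - 1) * np.log(se2) + np.log(se2 + n_i * su2)
    cov_beta = np.linalg.inv(xtvx)
    beta = cov_beta @ xtvy
    quad = 0.0
    for X, y in zip(X_list, y_list):
        n_i = len(y)
        r = y - X @ beta
        shrink = su2 / (se2 + n_i * su2)
        quad += (r @ r - shrink * r.sum() ** 2) / se2
    sign, logdet_x = np.linalg.slogdet(xtvx)
    ll = -0.5 * (logdet + quad + logdet_x)
    return ll, cov_beta, beta


def _satterthwaite_df(theta, contrast, groups, X_list, y_list):
    """df = 2 f^2 / (g' A g) with f = c' Cov(beta) c, g its gradient in the
    variance parameters and A the inverse REML information."""
    theta = np.asarray(theta, dtype=float)
    eps = np.maximum(1e-6, 1e-4 * theta)

    def f(th):
        return contrast @ _reml_pieces(th, groups, X_list, y_list)[1] @ contrast

    def ll(th):
        return _reml_pieces(th, groups, X_list, y_list)[0]

    grad = np.zeros(2)
    hess = np.zeros((2, 2))
    for i in range(2):
        ei = np.zeros(2)
        ei[i] = eps[i]
        grad[i] = (f(theta + ei) - f(np.maximum(theta - ei, 1e-12))) / (
            theta[i] + ei[i] - max(theta[i] - eps[i], 1e-12)
        )
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = eps[i]
            ej[j] = eps[j]
            hess[i, j] = hess[j, i] = (
                ll(theta + ei + ej) - ll(theta + ei - ej) - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4.0 * eps[i] * eps[j])
    info = -hess
    try:
        cov_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.nan
    denom = grad @ cov_theta @ grad
    if denom <= 0:
        return np.nan
    return float(2.0 * f(theta) ** 2 / denom)


def _ols_fallback(data, x, y, intercept_ref):
    import statsmodels.api as sm

    X = sm.add_constant(data[x].to_numpy())
    fit = sm.OLS(data[y].to_numpy(), X).fit()
    out = []
    n, p = X.shape
    df = n - p
    for k, term in enumerate(["intercept", x]):
        beta = float(fit.params[k])
        ref = intercept_ref if term == "intercept" else 0.0
        se = float(fit.bse[k])
        if se == 0:
            t = 0.0 if beta == ref else np.inf * np.sign(beta - ref)
            pval = 1.0 if beta == ref else 0.0
            out.append(MixedLMResult(term, beta, beta, beta, float(t), df, pval, False))
            continue
        t = (beta - ref) / se
        crit = sps.t.ppf(0.975, df)
        out.append(
            MixedLMResult(term, beta, beta - crit * se, beta + crit * se,
                          float(t), float(df), float(2 * sps.t.sf(abs(t), df)), False)
        )
    return out


def mixed_lm(
    data: pd.DataFrame,
    subject: str = "participant_id",
    x: str = "cycle",
    y: str = "value",
    intercept_ref: float = 0.0,
) -> list:
    """Random-intercept regression of ``y`` on ``x`` across participants.

    REML fit with Satterthwaite degrees of freedom; the intercept's t test
    is optionally offset against ``intercept_ref`` (e.g. an asymptotic
    learning level). Returns ``MixedLMResult`` rows for the intercept and
    slope. Singular random-effects fits fall back to a fixed-effects
    regression with residual df, flagged via ``satterthwaite=False``.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    if data[subject].nunique() < 2 or data[x].nunique() < 2:
        return _ols_fallback(data, x, y, intercept_ref)

    endog = data[y].to_numpy(dtype=float)
    exog = sm.add_constant(data[x].to_numpy(dtype=float))
    groups = data[subject].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = MixedLM(endog, exog, groups=groups).fit(reml=True)
        su2 = float(np.asarray(fit.cov_re)[0, 0])
        se2 = float(fit.scale)
        ok = np.isfinite(su2) and np.isfinite(se2) and su2 > 1e-8 * se2 and se2 > 0
    except Exception:
        ok = False
    if not ok:
        warnings.warn("singular random-effects fit; falling back to fixed effects")
        return _ols_fallback(data, x, y, intercept_ref)

    X_list = [exog[groups == g] for g in pd.unique(groups)]
    y_list = [endog[groups == g] for g in pd.unique(groups)]
    theta = np.array([su2, se2])
    _, cov_beta, beta = _reml_pieces(theta, None, X_list, y_list)
    out = []
    for k, term in enumerate(["intercept", x]):
        contrast = np.zeros(2)
        contrast[k] = 1.0
        se = float(np.sqrt(cov_beta[k, k]))
        df = _satterthwaite_df(theta, contrast, None, X_list, y_list)
        satt = np.isfinite(df) and df > 0
        if not satt:
            df = len(endog) - 2.0
        ref = intercept_ref if term == "intercept" else 0.0
        t = (float(beta[k]) - ref) / se
        crit = sps.t.ppf(0.975, df)
        out.append(
            MixedLMResult(
                term, float(beta[k]), float(beta[k] - crit * se), float(beta[k] + crit * se),
                float(t), float(df), float(2 * sps.t.sf(abs(t), df)), bool(satt),
            )
        )
    return out
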