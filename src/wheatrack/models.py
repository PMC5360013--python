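"""Mixed-effects reaction-norm models with flat-prior posterior simulation.

The departure-probability model is a mixed-effects logistic regression
(MELR) with a single random intercept (deployment year), fitted by
maximum likelihood with adaptive Gauss-Hermite quadrature.  Travel-speed
and total-speed models are linear mixed models fitted by REML with
optional observation weights (inverse latitude-SD), one random intercept
and a profiled variance ratio, so the optimisation is one-dimensional.

Uncertainty follows the flat-prior simulation convention: 2,000 draws
from the large-sample joint posterior (scaled inverse-chi-square for the
residual variance, multivariate normal for the coefficients), with the
2.5/50/97.5% quantiles as the 95% credible interval and the median as
the point estimate.  An effect is "significant" when its 95% CrI
excludes zero.  R-squared is the variance-partition (marginal /
conditional) form with the pi^2/3 residual variance for the logit link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "z_transform",
    "vif",
    "vif_screen",
    "build_design",
    "fit_melr",
    "fit_lmm",
    "posterior_sim",
    "effect_predictions",
    "r_squared",
]

_GH_NODES = 15


@dataclass
class ModelSpec:
    """Formula-like description of one mixed model."""

    response: str
    fixed: list                      # term names; 'a:b' denotes an interaction
    group: str = "year"
    family: str = "binomial"         # 'binomial' (logit) or 'gaussian'
    transform: str = "identity"      # response transform: 'identity' | 'log10'
    weights: Optional[str] = None    # column of observation weights

    def __post_init__(self):
        if self.family not in ("binomial", "gaussian"):
            raise ValueError("family must be 'binomial' or 'gaussian'")
        for t in self.fixed:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed or b not in self.fixed:
                    raise ValueError(f"interaction {t} lacks a main effect")


@dataclass
class FitResult:
    spec: ModelSpec
    terms: list
    coef: np.ndarray                 # ML/REML point estimates (incl. intercept)
    cov: np.ndarray                  # asymptotic covariance of coef
    random_sd: float
    resid_sd: Optional[float]        # gaussian only
    scale: Optional[float]           # binomial Pearson dispersion
    n: int
    n_dropped: int
    loglik: float
    marginal_r2: float
    conditional_r2: float
    singular_random: bool = False
    draws: Optional[np.ndarray] = None
    summary_: Optional[pd.DataFrame] = None
    scaling: Optional[dict] = None   # column -> (mean, sd) used on the covariates

    def summary(self) -> pd.DataFrame:
        if self.summary_ is None:
            raise RuntimeError("run posterior_sim first")
        return self.summary_


# ---------------------------------------------------------------------------
# standardisation and collinearity


def z_transform(table: pd.DataFrame, columns: list) -> tuple[pd.DataFrame, dict]:
    """Centre and scale `columns` to unit SD; returns (table, scaling).

    scaling maps column -> (mean, sd) for back-transformation.
    """
    out = table.copy()
    scaling = {}
    for c in columns:
        x = out[c].to_numpy(dtype=float)
        m, s = float(np.nanmean(x)), float(np.nanstd(x, ddof=0))
        if s <= 0 or not np.isfinite(s):
            raise ValueError(f"zero-variance column: {c!r}")
        out[c] = (x - m) / s
        scaling[c] = (m, s)
    return out, scaling


def vif(table: pd.DataFrame, predictors: list) -> pd.Series:
    """Variance inflation factors 1/(1-R_i^2) for each predictor."""
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    X = table[predictors].to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    out = {}
    for i, name in enumerate(predictors):
        y = X[:, i]
        others = np.delete(X, i, axis=1)
        A = np.column_stack([np.ones(len(others)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 1.0
        out[name] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out)


def vif_screen(
    table: pd.DataFrame, predictors: list, threshold: float = 2.0
) -> tuple[list, pd.DataFrame]:
    """Iteratively drop the largest-VIF predictor until all fall below
    `threshold`.  Returns (retained predictors, drop report)."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    kept = list(predictors)
    report = []
    while len(kept) >= 2:
        v = vif(table, kept)
        worst = v.idxmax()
        if v[worst] < threshold:
            break
        # perfect ties: drop the later-listed predictor
        ties = v.index[np.isclose(v, v[worst], rtol=1e-9)]
        worst = ties[-1]
        report.append({"dropped": worst, "vif": float(v[worst])})
        kept.remove(worst)
    return kept, pd.DataFrame(report, columns=["dropped", "vif"])


# ---------------------------------------------------------------------------
# design matrices


def build_design(table: pd.DataFrame, spec: ModelSpec):
    """Design matrix, response, group codes and weights for a ModelSpec.

    Rows with a missing response, covariate or weight are dropped
    listwise; the count is reported.
    """
    cols = sorted({c for t in spec.fixed for c in t.split(":")})
    need = cols + [spec.response, spec.group] + ([spec.weights] if spec.weights else [])
    sub = table[need].copy()
    n0 = len(sub)
    sub = sub.dropna()
    n_dropped = n0 - len(sub)

    terms = ["intercept"] + list(spec.fixed)
    X = np.column_stack(
        [np.ones(len(sub))]
        + [
            np.prod([sub[c].to_numpy(dtype=float) for c in t.split(":")], axis=0)
            for t in spec.fixed
        ]
    )
    y = sub[spec.response].to_numpy(dtype=float)
    if spec.transform == "log10":
        if (y <= 0).any():
            raise ValueError("log10 transform needs a positive response")
        y = np.log10(y)
    codes, _ = pd.factorize(sub[spec.group])
    w = (
        sub[spec.weights].to_numpy(dtype=float)
        if spec.weights
        else np.ones(len(sub))
    )
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return X, y, codes, w, terms, n_dropped


# ---------------------------------------------------------------------------
# MELR: logistic regression with one random intercept (adaptive GHQ)


def _melr_loglik(beta, log_sigma, X, y, codes, n_groups, nodes, weights):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    # group-mode Newton iterations (vectorised over groups)
    u = np.zeros(n_groups)
    for _ in range(30):
        eta = eta0 + u[codes]
        p = 1.0 / (1.0 + np.exp(-eta))
        g = np.bincount(codes, weights=y - p, minlength=n_groups) - u / sigma**2
        h = -np.bincount(codes, weights=p * (1 - p), minlength=n_groups) - 1.0 / sigma**2
        step = g / h
        u_new = u - step
        if np.max(np.abs(step)) < 1e-10:
            u = u_new
            break
        u = u_new
    s_hat = 1.0 / np.sqrt(-h)  # curvature scale at the mode

    logint = np.full((n_groups, len(nodes[0])), -np.inf)
    for k, (xk, lwk) in enumerate(zip(*nodes)):
        uk = u + np.sqrt(2.0) * s_hat * xk
        eta = eta0 + uk[codes]
        # Bernoulli log-likelihood, numerically safe
        llik = -np.logaddexp(0.0, -eta) * y - np.logaddexp(0.0, eta) * (1 - y)
        gsum = np.bincount(codes, weights=llik, minlength=n_groups)
        log_prior = stats.norm.logpdf(uk, 0.0, sigma)
        # AGQ weight: w_k e^{x_k^2} sqrt(2) s_hat
        logint[:, k] = gsum + log_prior + lwk + xk**2 + 0.5 * np.log(2.0) + np.log(s_hat)
    m = logint.max(axis=1)
    ll = float(np.sum(m + np.log(np.sum(np.exp(logint - m[:, None]), axis=1))))
    return ll, u


def fit_melr(table: pd.DataFrame, spec: ModelSpec, n_quad: int = _GH_NODES) -> FitResult:
    """Fit a mixed-effects logistic regression by adaptive Gauss-Hermite ML.

    With fewer than 2 groups the model falls back to a fixed-intercept
    logistic fit (random SD 0) with a warning.
    """
    if spec.family != "binomial":
        raise ValueError("fit_melr needs a binomial spec")
    X, y, codes, _, terms, n_dropped = build_design(table, spec)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary response required")
    n_groups = int(codes.max()) + 1
    p = X.shape[1]
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    nodes = (gh_x, np.log(gh_w))

    fallback = n_groups < 2
    if fallback:
        import warnings

        warnings.warn("fewer than 2 groups: fixed-intercept logistic fallback")

    def nll(params):
        beta, ls = params[:p], params[p]
        if fallback:
            eta = X @ beta
            return float(
                np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y))
            )
        ll, _ = _melr_loglik(beta, ls, X, y, codes, n_groups, nodes, None)
        return -ll

    x0 = np.zeros(p + 1)
    x0[p] = np.log(0.3)
    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    if not np.isfinite(res.fun):
        raise RuntimeError("MELR optimisation failed (non-finite likelihood)")
    beta_hat = res.x[:p]
    sigma_u = 0.0 if fallback else float(np.exp(res.x[p]))

    # separation check: runaway coefficients (z-scale effects this large
    # do not occur in identified fits)
    if np.max(np.abs(beta_hat)) > 8.0:
        worst = terms[int(np.argmax(np.abs(beta_hat)))]
        raise RuntimeError(f"complete separation suspected on term {worst!r}")

    if fallback or sigma_u < 0.01:
        # variance at/near the boundary: the log-sigma direction is flat,
        # so profile it out instead of inverting a near-singular Hessian
        ls_fix = res.x[p]
        cov = _numeric_hessian_inv(lambda b: nll(np.append(b, ls_fix)), res.x[:p])
    else:
        cov = _numeric_hessian_inv(nll, res.x)[:p, :p]

    # conditional fitted values at the posterior-mode random effects
    if fallback:
        u = np.zeros(1)
        ll = -res.fun
    else:
        ll, u = _melr_loglik(beta_hat, res.x[p], X, y, codes, n_groups, nodes, None)
    eta = X @ beta_hat + u[codes]
    phat = 1.0 / (1.0 + np.exp(-eta))
    pearson = (y - phat) / np.sqrt(phat * (1 - phat))
    scale = float(np.sum(pearson**2) / (len(y) - p))

    var_f = float(np.var(X @ beta_hat))
    var_u = sigma_u**2
    var_e = np.pi**2 / 3.0
    marg = var_f / (var_f + var_u + var_e)
    cond = (var_f + var_u) / (var_f + var_u + var_e)

    return FitResult(
        spec=spec,
        terms=terms,
        coef=beta_hat,
        cov=cov,
        random_sd=sigma_u,
        resid_sd=None,
        scale=scale,
        n=len(y),
        n_dropped=n_dropped,
        loglik=float(ll),
        marginal_r2=marg,
        conditional_r2=cond,
        singular_random=sigma_u < 0.01,
    )


def _numeric_hessian_inv(f, x, eps=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xi = x.copy(); xi[i] += eps; xi[j] += eps
            xj = x.copy(); xj[i] += eps; xj[j] -= eps
            xk_ = x.copy(); xk_[i] -= eps; xk_[j] += eps
            xl = x.copy(); xl[i] -= eps; xl[j] -= eps
            H[i, j] = H[j, i] = (f(xi) - f(xj) - f(xk_) + f(xl)) / (4 * eps**2)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# weighted LMM with one random intercept (profiled REML)


def _lmm_profile(lam, X, y, codes, w, n_groups):
    """Profiled REML pieces for variance ratio lam = tau^2/sigma^2.

    Uses the Woodbury identity per group: (W^-1 + lam 11')^-1 =
    W - lam (W 1)(1' W)/(1 + lam s), s = sum of weights.
    """
    p = X.shape[1]
    XtAX = np.zeros((p, p))
    XtAy = np.zeros(p)
    ytAy = 0.0
    logdet_V = 0.0
    for g in range(n_groups):
        m = codes == g
        Xg, yg, wg = X[m], y[m], w[m]
        s = wg.sum()
        c = lam / (1.0 + lam * s)
        WX = Xg * wg[:, None]
        Wy = yg * wg
        XtAX += Xg.T @ WX - c * np.outer(WX.sum(axis=0), WX.sum(axis=0))
        XtAy += Xg.T @ Wy - c * WX.sum(axis=0) * Wy.sum()
        ytAy += yg @ Wy - c * Wy.sum() ** 2
        # log|V_g/sigma^2| = log(1 + lam s) - sum log w
        logdet_V += np.log1p(lam * s) - np.log(wg).sum()
    beta = np.linalg.solve(XtAX, XtAy)
    rss = max(ytAy - XtAy @ beta, 0.0)
    return beta, rss, XtAX, logdet_V


def _lmm_reml_nll(lam, X, y, codes, w, n_groups):
    n, p = X.shape
    _, rss, XtAX, logdet_V = _lmm_profile(lam, X, y, codes, w, n_groups)
    sigma2 = max(rss / (n - p), 1e-300)  # exact fits: avoid log(0)
    sign, logdet_XtAX = np.linalg.slogdet(XtAX)
    return 0.5 * ((n - p) * np.log(sigma2) + logdet_V + logdet_XtAX + (n - p))


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """REML fit of a weighted linear mixed model with one random intercept.

    A singular random effect (variance driven to the boundary) keeps the
    fit and reports random SD ~ 0 with ``singular_random=True``.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm needs a gaussian spec")
    X, y, codes, w, terms, n_dropped = build_design(table, spec)
    n_groups = int(codes.max()) + 1
    n, p = X.shape

    obj = lambda loglam: _lmm_reml_nll(np.exp(loglam), X, y, codes, w, n_groups)
    res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    if obj(-12.0) <= res.fun + 1e-10:
        lam = np.exp(-12.0)  # boundary: effectively no group variance
    beta, rss, XtAX, logdet_V = _lmm_profile(lam, X, y, codes, w, n_groups)
    sigma2 = rss / (n - p)
    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(XtAX)
    singular = lam <= np.exp(-11.5)

    var_f = float(np.var(X @ beta))
    marg = var_f / (var_f + tau2 + sigma2)
    cond = (var_f + tau2) / (var_f + tau2 + sigma2)

    return FitResult(
        spec=spec,
        terms=terms,
        coef=beta,
        cov=cov,
        random_sd=float(np.sqrt(tau2)),
        resid_sd=float(np.sqrt(sigma2)),
        scale=None,
        n=n,
        n_dropped=n_dropped,
        loglik=float(-_lmm_reml_nll(lam, X, y, codes, w, n_groups)),
        marginal_r2=marg,
        conditional_r2=cond,
        singular_random=singular,
    )


# ---------------------------------------------------------------------------
# posterior simulation, predictions, R^2


def posterior_sim(fit: FitResult, n_draws: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Simulate the joint posterior under flat priors and attach a summary.

    Gaussian fits draw sigma^2 from its scaled inverse-chi-square and the
    coefficients from a multivariate normal scaled accordingly; binomial
    fits draw from the asymptotic normal on the link scale.  The returned
    summary has the median and 2.5/97.5% quantiles per term and a
    significance flag (95% CrI excludes zero).
    """
    if n_draws < 1000:
        raise ValueError("use at least 1000 draws")
    rng = np.random.default_rng(seed)
    p = len(fit.coef)
    # guard: covariance must be positive definite
    try:
        L = np.linalg.cholesky(fit.cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("non-positive-definite coefficient covariance") from exc

    if fit.spec.family == "gaussian":
        df = max(fit.n - p, 1)
        sigma2_hat = fit.resid_sd**2
        sigma2 = sigma2_hat * df / rng.chisquare(df, n_draws)
        z = rng.standard_normal((n_draws, p))
        scalefac = np.sqrt(sigma2 / sigma2_hat)[:, None]
        draws = fit.coef + (z @ L.T) * scalefac
    else:
        z = rng.standard_normal((n_draws, p))
        draws = fit.coef + z @ L.T

    lo, med, hi = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    fit.draws = draws
    fit.summary_ = pd.DataFrame(
        {
            "term": fit.terms,
            "estimate": med,
            "cri_lo": lo,
            "cri_hi": hi,
            "significant": (lo > 0) | (hi < 0),
        }
    )
    return fit.summary_


def effect_predictions(
    fit: FitResult,
    table: pd.DataFrame,
    interaction: str,
    n_cat: int = 5,
) -> pd.DataFrame:
    """Predicted response over a 5x5 grid of an interaction's two variables.

    Both variables are summarised into `n_cat` equal-count categories
    (category value = within-bin mean); all other covariates sit at their
    means (zero on the z-scale).  Cells without observed support (no data
    jointly in both bins) are flagged unsupported and their predictions
    suppressed.  Intervals come from the posterior draws.
    """
    if interaction not in fit.terms:
        raise ValueError(f"interaction {interaction!r} not in the fit")
    if fit.draws is None:
        posterior_sim(fit)
    a, b = interaction.split(":")
    xa = table[a].dropna().to_numpy(dtype=float)
    xb = table[b].dropna().to_numpy(dtype=float)
    qa = np.quantile(xa, np.linspace(0, 1, n_cat + 1))
    qb = np.quantile(xb, np.linspace(0, 1, n_cat + 1))
    ca = [xa[(xa >= qa[i]) & (xa <= qa[i + 1])].mean() for i in range(n_cat)]
    cb = [xb[(xb >= qb[i]) & (xb <= qb[i + 1])].mean() for i in range(n_cat)]

    sub = table[[a, b]].dropna()
    rows = []
    for i, va in enumerate(ca):
        for j, vb in enumerate(cb):
            supported = bool(
                (
                    (sub[a] >= qa[i]) & (sub[a] <= qa[i + 1])
                    & (sub[b] >= qb[j]) & (sub[b] <= qb[j + 1])
                ).any()
            )
            x = np.zeros(len(fit.terms))
            for k, t in enumerate(fit.terms):
                if t == "intercept":
                    x[k] = 1.0
                elif t == a:
                    x[k] = va
                elif t == b:
                    x[k] = vb
                elif t == interaction:
                    x[k] = va * vb
                elif set(t.split(":")) == {a, b}:
                    x[k] = va * vb
            eta = fit.draws @ x
            if fit.spec.family == "binomial":
                pred = 1.0 / (1.0 + np.exp(-eta))
            else:
                pred = eta
            lo, med, hi = np.percentile(pred, [2.5, 50.0, 97.5])
            rows.append(
                {
                    a: va,
                    b: vb,
                    "category_" + a: i,
                    "category_" + b: j,
                    "predicted": med if supported else np.nan,
                    "lo": lo if supported else np.nan,
                    "hi": hi if supported else np.nan,
                    "supported": supported,
                }
            )
    return pd.DataFrame(rows)


def r_squared(fit: FitResult) -> dict:
    """Marginal and conditional variance-partition R^2."""
    return {"marginal": fit.marginal_r2, "conditional": fit.conditional_r2}
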