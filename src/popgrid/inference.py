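"""Count regression of follow-up cluster population on cluster features.

The core model is a generalized linear model with log link and the log
baseline population as an offset (coefficient fixed at 1), so the regression
describes *relative* five-year growth:

    log mu_c = log n_c(baseline) + beta_0 + beta_1 log(Area_c)
               + beta_2 log(Density_c) + sum_i beta_i X_ic

The Poisson variant assumes Var = mu; the overdispersion score test
(Dean–Lawless form, N(0,1) under the Poisson null, one-sided upper tail)
decides whether to move to the negative binomial (NB2) model with
Var = mu + mu^2/theta.  theta is estimated by profile maximum likelihood,
alternating a fixed-theta GLM fit for beta with a one-dimensional
log-likelihood maximization over theta until the log-likelihood stabilizes —
the same scheme as the classic glm.nb workflow.  Reported standard errors
for beta are conditional on the estimated theta (as in that workflow);
95% confidence intervals are Wald, estimate +/- 1.96 SE.

Model selection: backward elimination over the nine main effects plus all
36 pairwise interactions of the mean-centered covariates, dropping at each
step the single term whose removal most decreases the AIC, honouring
marginality (a main effect is not removable while one of its interactions
remains), and stopping when no removal decreases the AIC.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Covariates of the multivariate model, in canonical order.
COVARIATES = (
    "log_area", "log_density", "roundness", "irregularity", "cl",
    "heterogeneity", "gender", "age", "tertiary",
)

_Z95 = 1.96  # Wald interval multiplier


# ---------------------------------------------------------------------------
# model matrix

@dataclasses.dataclass
class ModelMatrix:
    """Response, offset and covariate columns for the offset regressions."""

    response: np.ndarray          # n_followup per cluster (non-negative ints)
    offset: np.ndarray            # log n_baseline
    covariates: pd.DataFrame      # columns COVARIATES
    centered: bool
    means: pd.Series | None
    cluster_id: np.ndarray


def build_model_matrix(features: pd.DataFrame, center: bool = False) -> ModelMatrix:
    """Assemble response, offset and covariates from a feature table.

    Applies the natural log to Area and Density only.  With ``center=True``
    every covariate column is shifted to zero mean (used before forming
    interaction terms, to keep their VIFs small).
    """
    f = features
    if (f["density"] <= 0).any():
        bad = f.loc[f["density"] <= 0, "cluster_id"].iloc[0]
        raise ValueError(f"non-positive density for cluster {bad}")
    if (f["n_baseline"] < 1).any():
        bad = f.loc[f["n_baseline"] < 1, "cluster_id"].iloc[0]
        raise ValueError(f"n_baseline < 1 for cluster {bad}")
    X = pd.DataFrame({
        "log_area": np.log(f["S"].to_numpy(dtype=float)),
        "log_density": np.log(f["density"].to_numpy(dtype=float)),
        "roundness": f["roundness"].to_numpy(dtype=float),
        "irregularity": f["irregularity"].to_numpy(dtype=float),
        "cl": f["cl"].to_numpy(dtype=float),
        "heterogeneity": f["heterogeneity"].to_numpy(dtype=float),
        "gender": f["gender"].to_numpy(dtype=float),
        "age": f["age"].to_numpy(dtype=float),
        "tertiary": f["tertiary"].to_numpy(dtype=float),
    })
    if X.isna().any().any():
        raise ValueError("covariate columns contain missing values")
    means = None
    if center:
        means = X.mean()
        X = X - means
    return ModelMatrix(
        response=f["n_followup"].to_numpy(dtype=np.int64),
        offset=np.log(f["n_baseline"].to_numpy(dtype=float)),
        covariates=X,
        centered=center,
        means=means,
        cluster_id=f["cluster_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# fit results

@dataclasses.dataclass
class FitResult:
    """A fitted offset count regression."""

    family: str                   # "poisson" or "negbin"
    terms: tuple
    params: pd.Series             # index: ["const", *terms]
    bse: pd.Series
    ci95: pd.DataFrame            # columns: lower, upper
    theta: float | None
    loglik: float
    aic: float
    fitted: np.ndarray            # mu_c
    converged: bool
    theta_capped: bool = False

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "terms": list(self.terms),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "ci95": {k: [float(self.ci95.loc[k, "lower"]), float(self.ci95.loc[k, "upper"])]
                     for k in self.ci95.index},
            "theta": None if self.theta is None else float(self.theta),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "theta_capped": bool(self.theta_capped),
        }


def _design(mm: ModelMatrix, terms, extra: pd.DataFrame | None = None) -> tuple[np.ndarray, list]:
    names = ["const"] + list(terms)
    cols = [np.ones(len(mm.response))]
    for t in terms:
        if extra is not None and t in extra.columns:
            cols.append(extra[t].to_numpy(dtype=float))
        else:
            cols.append(mm.covariates[t].to_numpy(dtype=float))
    return np.column_stack(cols), names


def _wrap(family, terms, names, res, theta=None, loglik=None, aic=None,
          theta_capped=False) -> FitResult:
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    ci = pd.DataFrame({"lower": params - _Z95 * bse, "upper": params + _Z95 * bse})
    ll = float(res.llf) if loglik is None else float(loglik)
    k = len(names) + (1 if family == "negbin" else 0)
    return FitResult(
        family=family, terms=tuple(terms), params=params, bse=bse, ci95=ci,
        theta=theta, loglik=ll, aic=(2 * k - 2 * ll) if aic is None else float(aic),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        converged=bool(getattr(res, "converged", True)), theta_capped=theta_capped)


def fit_poisson_offset(mm: ModelMatrix, terms=None) -> FitResult:
    """Maximum-likelihood Poisson regression with log link and unit offset."""
    if terms is None:
        terms = list(COVARIATES)
    X, names = _design(mm, terms)
    model = sm.GLM(mm.response, X, family=sm.families.Poisson(), offset=mm.offset)
    res = model.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError(
            f"Poisson fit did not converge after {res.fit_history['iteration']} "
            "IRLS iterations; check for separation or degenerate covariates")
    return _wrap("poisson", terms, names, res)


# ---------------------------------------------------------------------------
# overdispersion test

@dataclasses.dataclass
class OverdispersionResult:
    statistic: float
    p_value: float
    level: float

    @property
    def overdispersed(self) -> bool:
        return self.p_value < self.level


def dean_lawless_statistic(response, mu) -> float:
    """T = sum[(y - mu)^2 - y] / sqrt(2 sum mu^2), N(0,1) under Poisson."""
    y = np.asarray(response, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.size < 1:
        raise ValueError("need at least one observation")
    return float(((y - mu) ** 2 - y).sum() / np.sqrt(2.0 * (mu ** 2).sum()))


def overdispersion_test(poisson_fit: FitResult, response, level: float = 0.001) -> OverdispersionResult:
    """Score test of Var = mu against Var > mu (one-sided upper tail)."""
    y = np.asarray(response)
    if y.size < 2:
        raise ValueError("overdispersion test needs at least two clusters")
    t = dean_lawless_statistic(y, poisson_fit.fitted)
    return OverdispersionResult(statistic=t, p_value=float(stats.norm.sf(t)), level=level)


# ---------------------------------------------------------------------------
# negative binomial (NB2) with profiled theta

def nb_logpmf(k, mu, theta):
    """NB2 log pmf with mean mu and variance mu + mu^2/theta."""
    mu = np.asarray(mu, dtype=float)
    return stats.nbinom.logpmf(np.asarray(k), theta, theta / (theta + mu))


def _nb_loglik(y, mu, theta) -> float:
    return float(nb_logpmf(y, mu, theta).sum())


def _optimize_theta(y, mu, lo=1e-4, hi=1e8) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -_nb_loglik(y, mu, np.exp(lt)),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-10})
    return float(np.exp(res.x))


def _glm_nb_fixed_theta(y, X, offset, theta, start_params=None):
    """Fit beta for fixed theta; returns the statsmodels results object."""
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta),
                   offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(start_params=start_params, maxiter=200)


def fit_negbin_offset(mm: ModelMatrix, terms=None, tol: float = 1e-8,
                      max_outer: int = 50, theta_cap: float = 1e6) -> FitResult:
    """Joint ML fit of the NB2 offset model over beta and theta.

    Alternates a fixed-theta GLM fit for beta with a bounded scalar
    maximization of the exact NB log-likelihood over theta, until the
    log-likelihood changes by less than `tol`.  A theta running beyond
    `theta_cap` means the data are Poisson-like; the fit is flagged
    (``theta_capped``) and theta reported at the cap.
    """
    if terms is None:
        terms = list(COVARIATES)
    X, names = _design(mm, terms)
    y = mm.response
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=mm.offset).fit(maxiter=200)
    mu = np.asarray(pois.fittedvalues)
    # moment start for theta: E[(y-mu)^2 - y] ~ mu^2/theta
    excess = ((y - mu) ** 2 - y).sum()
    theta = float(np.clip((mu ** 2).sum() / excess if excess > 0 else theta_cap,
                          1e-3, theta_cap))
    params = np.asarray(pois.params)
    ll_prev = -np.inf
    res = pois
    capped = False
    converged = False
    for _ in range(max_outer):
        theta = _optimize_theta(y, mu, hi=theta_cap * 10)
        if theta >= theta_cap:
            warnings.warn("theta diverged (data look Poisson-like); capping",
                          RuntimeWarning, stacklevel=2)
            theta = theta_cap
            capped = True
        res = _glm_nb_fixed_theta(y, X, mm.offset, theta, start_params=params)
        params = np.asarray(res.params)
        mu = np.asarray(res.fittedvalues)
        ll = _nb_loglik(y, mu, theta)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        if capped:
            converged = True
            break
    ll = _nb_loglik(y, mu, theta)
    fit = _wrap("negbin", terms, names, res, theta=theta, loglik=ll,
                theta_capped=capped)
    fit.converged = converged
    return fit


def fit_univariate_suite(features: pd.DataFrame, **kwargs) -> dict:
    """One NB offset fit per covariate (same offset as the multivariate fit).

    Returns ``{covariate: FitResult or None}``; a covariate whose fit fails
    is reported as None with a logged warning and the others proceed.
    """
    mm = build_model_matrix(features, center=False)
    out: dict = {}
    for cov in COVARIATES:
        try:
            out[cov] = fit_negbin_offset(mm, terms=[cov], **kwargs)
        except Exception as exc:  # noqa: BLE001 - per-covariate isolation
            logger.warning("univariate fit failed for %s: %s", cov, exc)
            out[cov] = None
    return out


# ---------------------------------------------------------------------------
# effect transforms and diagnostics

def effect_transform(beta: float, delta: float = 1.0, kind: str = "multiplicative") -> float:
    """Translate a coefficient into an interpretable effect size.

    ``multiplicative``: exp(beta * delta), the factor by which the expected
    count changes when the covariate increases by delta.
    ``decrease_fraction``: 1 - exp(beta * delta), the fractional decrease.
    ``elasticity``: beta itself (for logged covariates, % change per 1%).
    """
    if kind == "multiplicative":
        return float(np.exp(beta * delta))
    if kind == "decrease_fraction":
        return float(1.0 - np.exp(beta * delta))
    if kind == "elasticity":
        return float(beta)
    raise ValueError(f"unknown effect kind {kind!r}")


def correlation_matrix(features: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlations between the nine covariates.

    ``method`` is pearson, spearman or kendall (tau-b, tie-corrected).
    Entries involving a constant column are NaN.
    """
    if method not in {"pearson", "spearman", "kendall"}:
        raise ValueError(f"unknown correlation method {method!r}")
    X = build_model_matrix(features).covariates
    const = X.columns[X.std(ddof=0) == 0]
    if len(const):
        logger.warning("constant covariate column(s) %s: correlations undefined",
                       list(const))
    return X.corr(method=method)


def vif(features: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) per covariate.

    R^2_j comes from the OLS regression (with intercept) of covariate j on
    the remaining covariates.  Perfect collinearity is reported as inf.
    """
    X = build_model_matrix(features).covariates
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more clusters than covariates for VIF")
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        A = np.column_stack([np.ones(len(X)), others.to_numpy(dtype=float)])
        y = X[col].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        out[col] = np.inf if 1.0 - r2 <= 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# backward AIC selection with pairwise interactions

@dataclasses.dataclass
class SelectionTrace:
    """Ordered record of a backward elimination run."""

    steps: list                    # dicts: removed, terms, aic
    final: FitResult
    terms: tuple

    def to_dict(self) -> dict:
        return {
            "steps": [{"removed": s["removed"], "terms": list(s["terms"]),
                       "aic": float(s["aic"])} for s in self.steps],
            "final_terms": list(self.terms),
            "final": self.final.to_dict(),
        }


def interaction_columns(X: pd.DataFrame) -> pd.DataFrame:
    """All 36 pairwise products of the (centered) covariate columns."""
    return pd.DataFrame({f"{a}:{b}": X[a] * X[b]
                         for a, b in combinations(X.columns, 2)},
                        index=X.index)


def _irls_nb(y, X, offset, theta, start, tol=1e-9, maxiter=30):
    """Lean IRLS for the fixed-theta NB GLM (log link, unit offset).

    Used for candidate scoring inside backward elimination, where thousands
    of warm-started fits are needed; returns (params, mu, loglik).
    """
    beta = np.asarray(start, dtype=float).copy()
    ll_prev = -np.inf
    for _ in range(maxiter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0 + offset.max())
        mu = np.exp(eta)
        w = mu / (1.0 + mu / theta)          # (dmu/deta)^2 / Var
        z = (eta - offset) + (y - mu) / mu   # working response
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if not np.all(np.isfinite(beta_new)):
            raise RuntimeError("IRLS produced non-finite coefficients")
        beta = beta_new
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta + offset, -30.0, 700.0)), theta)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    mu = np.exp(np.clip(X @ beta + offset, -30.0, 700.0))
    return beta, mu, _nb_loglik(y, mu, theta)


def _fit_nb_design(y, X, names, offset, tol=1e-8, max_outer=50,
                   theta_cap=1e6, start_params=None, theta0=None):
    """Profile-theta NB fit for an explicit design matrix."""
    if theta0 is not None:
        res = _glm_nb_fixed_theta(y, X, offset, theta0, start_params=start_params)
    else:
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(
            maxiter=200, start_params=start_params)
    mu = np.asarray(res.fittedvalues)
    params = np.asarray(res.params)
    ll_prev = -np.inf
    theta = theta0 if theta0 is not None else 1.0
    for _ in range(max_outer):
        theta = min(_optimize_theta(y, mu, hi=theta_cap * 10), theta_cap)
        res = _glm_nb_fixed_theta(y, X, offset, theta, start_params=params)
        params = np.asarray(res.params)
        mu = np.asarray(res.fittedvalues)
        ll = _nb_loglik(y, mu, theta)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    fit = _wrap("negbin", names[1:], names, res, theta=theta,
                loglik=_nb_loglik(y, mu, theta))
    return fit


def backward_aic_selection(features: pd.DataFrame, theta_cap: float = 1e6) -> SelectionTrace:
    """Backward AIC elimination over main effects and pairwise interactions.

    Starts from all nine main effects plus all 36 pairwise interactions of
    the mean-centered covariates.  Candidate removals are scored with theta
    held at the current model's estimate (one GLM fit each); after a removal
    is accepted, theta is re-profiled and the profiled AIC recorded, so the
    trace AIC is non-increasing by construction.  Marginality is enforced: a
    main effect stays while any interaction involving it remains.
    """
    mm = build_model_matrix(features, center=True)
    pool = pd.concat([mm.covariates, interaction_columns(mm.covariates)], axis=1)
    y, offset = mm.response, mm.offset

    def design(terms):
        names = ["const"] + list(terms)
        cols = [np.ones(len(y))] + [pool[t].to_numpy(dtype=float) for t in terms]
        return np.column_stack(cols), names

    terms = list(pool.columns)
    X, names = design(terms)
    current = _fit_nb_design(y, X, names, offset, theta_cap=theta_cap)
    steps = [{"removed": None, "terms": tuple(terms), "aic": current.aic}]
    while terms:
        in_interactions = set()
        for t in terms:
            if ":" in t:
                in_interactions.update(t.split(":"))
        removable = [t for t in terms if ":" in t or t not in in_interactions]
        best = None
        cur_params = current.params
        for t in removable:
            cand = [u for u in terms if u != t]
            Xc, nc = design(cand)
            start = cur_params.drop(index=t).to_numpy()
            try:
                _, _, ll = _irls_nb(y, Xc, offset, current.theta, start)
            except Exception as exc:  # noqa: BLE001 - skip bad candidate
                logger.warning("candidate removal of %s failed to fit: %s", t, exc)
                continue
            aic = 2 * (len(nc) + 1) - 2 * ll
            if best is None or aic < best[1]:
                best = (t, aic, cand)
        if best is None or best[1] >= steps[-1]["aic"] - 1e-10:
            break
        terms = best[2]
        X, names = design(terms)
        current = _fit_nb_design(
            y, X, names, offset, theta_cap=theta_cap, theta0=current.theta,
            start_params=cur_params.drop(index=best[0]).to_numpy())
        steps.append({"removed": best[0], "terms": tuple(terms), "aic": current.aic})
    return SelectionTrace(steps=steps, final=current, terms=tuple(terms))


# ---------------------------------------------------------------------------
# auxiliary regressions and descriptives

def size_growth_regression(growth: pd.DataFrame) -> dict:
    """OLS of log growth ratio on log baseline size, through the origin:

        log(n_followup / n_baseline) = beta * log(n_baseline)

    Clusters with zero follow-up population are excluded (count reported).
    """
    ok = growth["n_followup"] >= 1
    excluded = int((~ok).sum())
    if excluded:
        logger.info("size_growth_regression: excluded %d clusters with zero "
                    "follow-up population", excluded)
    sub = growth[ok]
    x = np.log(sub["n_baseline"].to_numpy(dtype=float))
    y = np.log(sub["n_followup"].to_numpy(dtype=float)) - x
    res = sm.OLS(y, x[:, None]).fit()
    return {
        "slope": float(res.params[0]),
        "se": float(res.bse[0]),
        "p_value": float(res.pvalues[0]),
        "n_used": int(ok.sum()),
        "n_excluded": excluded,
    }


def summarize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: min/max/median/mean/SD/CV/skewness per variable.

    SD uses divisor n-1, CV = SD/mean, skewness is the adjusted
    Fisher–Pearson coefficient.  Constant columns report SD = CV =
    skewness = 0.
    """
    if len(features) == 0:
        raise ValueError("empty feature table")
    f = features
    table = pd.DataFrame({
        "n_followup": f["n_followup"].astype(float),
        "n_baseline": f["n_baseline"].astype(float),
        "log_area": np.log(f["S"].astype(float)),
        "log_density": np.log(f["density"].astype(float)),
        "roundness": f["roundness"],
        "irregularity": f["irregularity"],
        "cl": f["cl"],
        "heterogeneity": f["heterogeneity"],
        "gender": f["gender"],
        "age": f["age"],
        "tertiary": f["tertiary"],
        "S": f["S"].astype(float),
        "density": f["density"].astype(float),
    })
    rows = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        mean = float(np.mean(v))
        if sd == 0.0:
            cv = skew = 0.0
        else:
            cv = sd / mean
            skew = float(stats.skew(v, bias=False))
        rows[col] = {
            "min": float(np.min(v)), "max": float(np.max(v)),
            "median": float(np.median(v)), "mean": mean,
            "sd": sd, "cv": cv, "skewness": skew,
        }
    return pd.DataFrame(rows).T[["min", "max", "median", "mean", "sd", "cv", "skewness"]]


def significance_stars(p: float) -> str:
    """Report-style significance marks at the 0.1/0.05/0.01/0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "†"
    return ""
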