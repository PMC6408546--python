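"""Seasonal driver analysis: simple regressions, AR(1)-GLS with AICc selection,
collinearity screening, and cross-location correlations.

The seasonal question is which combination of temperature, soil water content
(SWC) and midday sap flux (SF) — including their first-order interactions —
best explains daily-mean fluxes. Candidate linear models are fit by exact
maximum likelihood with AR(1) residual correlation (daily flux series are
autocorrelated), ranked by the small-sample Akaike criterion AICc, and, among
models within two AICc units of the best, the most complex one is kept: the
aim is understanding driver relations, not parsimony-optimal prediction.
CO2 responses are log-transformed to linearize the temperature relation; all
variables are z-scored so coefficients are comparable effect sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MAIN_TERMS = ("Temperature", "SWC", "SF")
INTERACTIONS = {
    "Temp*SWC": ("Temperature", "SWC"),
    "Temp*SF": ("Temperature", "SF"),
    "SWC*SF": ("SWC", "SF"),
}
VIF_THRESHOLD = 2.0


# ---------------------------------------------------------------------------
# scaling and collinearity

def scale_predictors(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every column over complete cases.

    Returns the scaled table and a constants frame (mean, sd per column) for
    back-transformation. A zero-variance column is an error naming it.
    """
    complete = table.dropna()
    constants = {}
    scaled = table.copy()
    for col in table.columns:
        mu = float(complete[col].mean())
        sd = float(complete[col].std(ddof=1))
        if sd == 0 or not math.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot scale")
        scaled[col] = (table[col] - mu) / sd
        constants[col] = {"mean": mu, "sd": sd}
    return scaled, pd.DataFrame(constants).T


def unscale(scaled: pd.Series | np.ndarray, constants: pd.DataFrame, col: str):
    """Inverse of :func:`scale_predictors` for one column."""
    return scaled * constants.loc[col, "sd"] + constants.loc[col, "mean"]


def vif(predictors: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per predictor: VIF_j = 1 / (1 - R2_j).

    R2_j comes from regressing predictor j on the others (with intercept).
    Perfect collinearity reports +inf. ``below_threshold`` flags VIF < 2,
    the conventional no-collinearity bar.
    """
    X = predictors.dropna()
    if X.shape[1] < 2:
        raise ValueError("need >= 2 predictors for VIF")
    vifs = []
    for col in X.columns:
        others = X.drop(columns=col).to_numpy()
        design = np.column_stack([np.ones(len(X)), others])
        y = X[col].to_numpy()
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        vifs.append(math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    return pd.DataFrame(
        {"vif": np.asarray(vifs, dtype=float),
         "below_threshold": np.asarray(vifs) < VIF_THRESHOLD},
        index=X.columns,
    )


# ---------------------------------------------------------------------------
# AR(1) generalized least squares by exact maximum likelihood

@dataclass(frozen=True)
class ModelSpec:
    response: str
    terms: tuple[str, ...] = ()
    log_transform: bool = False
    correlation: str = "AR1"  # "AR1" | "none"

    def __post_init__(self) -> None:
        for t in self.terms:
            if t in INTERACTIONS:
                a, b = INTERACTIONS[t]
                if a not in self.terms or b not in self.terms:
                    raise ValueError(f"interaction {t} without both main effects (hierarchy)")
            elif t not in MAIN_TERMS:
                raise ValueError(f"unknown term {t!r}")


@dataclass
class GLSResult:
    spec: ModelSpec
    coefficients: pd.DataFrame  # index term; columns estimate, se, t, p
    phi: float
    sigma2: float
    log_likelihood: float
    aicc: float
    adj_r2: float
    n: int
    converged: bool
    k: int = 0
    fitted: np.ndarray = field(default=None, repr=False)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n-k-1)."""
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for t in terms:
        if t in INTERACTIONS:
            a, b = INTERACTIONS[t]
            cols.append((data[a] * data[b]).to_numpy())
        else:
            cols.append(data[t].to_numpy())
        names.append(t)
    return np.column_stack(cols), names


def _ar1_profile(phi: float, X: np.ndarray, y: np.ndarray):
    """Prais-Winsten transform and profile log-likelihood pieces at fixed phi."""
    n = y.size
    c = math.sqrt(1.0 - phi**2)
    ys = np.empty(n)
    Xs = np.empty_like(X)
    ys[0] = c * y[0]
    Xs[0] = c * X[0]
    ys[1:] = y[1:] - phi * y[:-1]
    Xs[1:] = X[1:] - phi * X[:-1]
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    rss = float(np.sum((ys - Xs @ beta) ** 2))
    sigma2 = rss / n
    loglik = (
        -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        + 0.5 * math.log(1.0 - phi**2)
    )
    return loglik, beta, sigma2, Xs, ys


def fit_gls(spec: ModelSpec, data: pd.DataFrame) -> GLSResult:
    """Exact ML fit of a linear model with AR(1) residual correlation.

    The AR(1) parameter phi is profiled out numerically (Prais-Winsten
    transform gives the conditional GLS solution in closed form). ML rather
    than REML so log-likelihoods — and hence AICc — are comparable across
    fixed-effect sets. Consecutive rows of ``data`` are treated as
    consecutive AR steps regardless of calendar gaps.

    AICc = AIC + 2k(k+1)/(n - k - 1) with k counting the mean parameters plus
    the residual variance plus phi (when estimated). Adjusted R2 uses the
    squared correlation of fitted vs observed, the only form that remains
    well defined under a non-spherical error covariance.
    """
    y = data[spec.response].to_numpy(dtype=float)
    X, names = _design_matrix(data, spec.terms)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few complete cases for the requested model")

    if spec.correlation == "AR1":
        obj = lambda phi: -_ar1_profile(phi, X, y)[0]
        res = optimize.minimize_scalar(obj, bounds=(-0.98, 0.98), method="bounded",
                                       options={"xatol": 1e-8})
        phi = float(res.x)
        converged = bool(res.success)
    else:
        phi = 0.0
        converged = True
    loglik, beta, sigma2, Xs, ys = _ar1_profile(phi, X, y)

    dof = n - p
    s2_unbiased = float(np.sum((ys - Xs @ beta) ** 2)) / dof
    XtX_inv = np.linalg.pinv(Xs.T @ Xs)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2_unbiased, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    coef = pd.DataFrame({"estimate": beta, "se": se, "t": tvals, "p": pvals}, index=names)

    k = p + 1 + (1 if spec.correlation == "AR1" else 0)
    model_aicc = aicc(loglik, k, n)

    fitted = X @ beta
    if np.std(fitted) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1]) ** 2
    else:
        r2 = 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")

    return GLSResult(spec=spec, coefficients=coef, phi=phi, sigma2=sigma2,
                     log_likelihood=loglik, aicc=model_aicc, adj_r2=adj_r2, n=n,
                     converged=converged, k=k, fitted=fitted)


# ---------------------------------------------------------------------------
# model enumeration and selection

def enumerate_model_terms() -> list[tuple[str, ...]]:
    """All hierarchy-respecting subsets of 3 mains + 3 two-way interactions.

    Every interaction requires both of its main effects; brute-force
    enumeration gives 18 candidates including the intercept-only model.
    """
    models = []
    for r in range(4):
        for mains in itertools.combinations(MAIN_TERMS, r):
            allowed = [i for i, (a, b) in INTERACTIONS.items() if a in mains and b in mains]
            for ri in range(len(allowed) + 1):
                for ints in itertools.combinations(allowed, ri):
                    models.append(tuple(mains) + tuple(ints))
    return models


def _complexity_key(result: GLSResult) -> tuple:
    terms = result.spec.terms
    n_int = sum(1 for t in terms if t in INTERACTIONS)
    # most terms, then most interactions, then lower AICc
    return (len(terms), n_int, -result.aicc)


def lrt(full: GLSResult, reduced: GLSResult) -> tuple[float, float]:
    """Likelihood-ratio test of nested ML fits: (statistic, p-value)."""
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    df = full.k - reduced.k
    if df <= 0:
        return float("nan"), float("nan")
    return stat, float(stats.chi2.sf(max(stat, 0.0), df))


@dataclass
class SelectionResult:
    selected: GLSResult
    candidates: pd.DataFrame  # one row per candidate model
    overall_p: float
    significant: bool  # False -> "n.s."


def enumerate_and_select(
    response: str,
    data: pd.DataFrame,
    log_transform: bool = False,
    correlation: str = "AR1",
    delta_aicc: float = 2.0,
) -> SelectionResult:
    """Fit all 18 candidate models and select per the AICc-window rule.

    Models are ranked by AICc; among those within ``delta_aicc`` of the
    minimum (statistically indistinguishable by likelihood-ratio test at
    that spacing) the most complex is kept — most terms, then most
    interactions, then lower AICc. The overall model p-value is the LRT of
    the selected model against intercept-only; p > 0.05 is reported as not
    significant.
    """
    fits: list[GLSResult] = []
    for terms in enumerate_model_terms():
        spec = ModelSpec(response=response, terms=terms,
                         log_transform=log_transform, correlation=correlation)
        try:
            fit = fit_gls(spec, data)
        except Exception:
            continue
        if fit.converged and math.isfinite(fit.aicc):
            fits.append(fit)
    if not fits:
        raise RuntimeError("no candidate model converged")

    best_aicc = min(f.aicc for f in fits)
    window = [f for f in fits if f.aicc - best_aicc <= delta_aicc]
    selected = max(window, key=_complexity_key)

    null = next((f for f in fits if len(f.spec.terms) == 0), None)
    if null is None:
        null = fit_gls(ModelSpec(response=response, terms=(), correlation=correlation), data)
    if selected.spec.terms:
        _, overall_p = lrt(selected, null)
    else:
        overall_p = 1.0

    rows = []
    for f in sorted(fits, key=lambda f: f.aicc):
        rows.append({
            "terms": "+".join(f.spec.terms) if f.spec.terms else "(Intercept)",
            "n_terms": len(f.spec.terms),
            "aicc": f.aicc,
            "delta_aicc": f.aicc - best_aicc,
            "log_likelihood": f.log_likelihood,
            "phi": f.phi,
            "adj_r2": f.adj_r2,
            "in_window": f.aicc - best_aicc <= delta_aicc,
            "selected": f is selected,
        })
    return SelectionResult(selected=selected, candidates=pd.DataFrame(rows),
                           overall_p=float(overall_p),
                           significant=bool(overall_p <= 0.05))


# ---------------------------------------------------------------------------
# simple per-pair regressions (seasonal scatter fits)

def _cooks_screen(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Keep-mask removing points with linear-fit Cook's distance > 4/n."""
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    p = 2
    mse = float(np.sum(resid**2)) / (n - p)
    if mse == 0:
        return np.ones(n, dtype=bool)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    lev = np.diag(H)
    cooks = resid**2 / (p * mse) * lev / (1.0 - lev) ** 2
    return cooks <= 4.0 / n


@dataclass
class SimpleFit:
    form: str
    params: tuple
    r_squared: float
    p_value: float
    n: int
    converged: bool


def fit_simple_regression(x, y, form: str = "linear") -> SimpleFit:
    """Two-variable seasonal regression with influence screening.

    Points with Cook's distance above 4/n (from the linear fit) are dropped
    first. Forms: ``linear`` (OLS, slope t-test p), ``exponential``
    (y = a exp(b x)) and ``sigmoidal`` (4-parameter logistic
    y = d + (a - d) / (1 + exp(-b (x - c)))), both tested against the
    constant model by F-test. Non-convergence is a reported state.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError("need >= 5 complete pairs")
    keep = _cooks_screen(x, y)
    x, y = x[keep], y[keep]
    n = x.size

    sst = float(np.sum((y - y.mean()) ** 2))

    if form == "linear":
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ssr = float(np.sum(resid**2))
        se = math.sqrt(ssr / (n - 2) / float(np.sum((x - x.mean()) ** 2)))
        tval = beta[1] / se if se > 0 else math.inf
        p = 2.0 * stats.t.sf(abs(tval), n - 2)
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        return SimpleFit("linear", (float(beta[0]), float(beta[1])), r2, float(p), n, True)

    if form == "exponential":
        func = lambda t, a, b: a * np.exp(b * t)
        b0 = np.polyfit(x, np.log(np.abs(y) + 1e-9), 1)[0]
        p0 = [y[np.argmin(x)] if y.mean() >= 0 else y.mean(), b0]
        n_par = 2
    elif form == "sigmoidal":
        func = lambda t, a, b, c, d: d + (a - d) / (1.0 + np.exp(-b * (t - c)))
        p0 = [y.max(), 1.0, float(np.median(x)), y.min()]
        n_par = 4
    else:
        raise ValueError(f"unknown regression form {form!r}")

    try:
        popt, _ = optimize.curve_fit(func, x, y, p0=p0, maxfev=20_000)
        fitted = func(x, *popt)
        if not np.all(np.isfinite(fitted)):
            raise RuntimeError
    except Exception:
        return SimpleFit(form, (), float("nan"), float("nan"), n, False)
    ssr = float(np.sum((y - fitted) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    if ssr == 0:
        p = 0.0
    else:
        f_stat = ((sst - ssr) / (n_par - 1)) / (ssr / (n - n_par))
        p = float(stats.f.sf(f_stat, n_par - 1, n - n_par))
    return SimpleFit(form, tuple(float(v) for v in popt), r2, p, n, True)


def cross_location_correlation(daily_wide: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between locations for one gas.

    ``daily_wide`` has one column per location. Returns long-form rows with
    r, two-sided p (t-test) and the figure star code (** p<0.001, * p<0.05).
    """
    rows = []
    cols = list(daily_wide.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            pair = daily_wide[[a, b]].dropna()
            if len(pair) < 3:
                rows.append({"a": a, "b": b, "r": float("nan"),
                             "p": float("nan"), "stars": "", "n": len(pair)})
                continue
            r, p = stats.pearsonr(pair[a], pair[b])
            stars = "**" if p < 0.001 else ("*" if p < 0.05 else "")
            rows.append({"a": a, "b": b, "r": float(r), "p": float(p),
                         "stars": stars, "n": len(pair)})
    return pd.DataFrame(rows)
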