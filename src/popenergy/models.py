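"""Temporal-trend and environment-energy models.

Covers the statistical layer of the analysis: collinearity screening of
environmental covariates (|r| > 0.6 excluded from the same model),
multiple linear regression of population energy on covariates, linear
vs. penalized-spline trend comparison by AIC (ΔAIC < 2, tie to the
simpler model), linear mixed-effects models with a random intercept per
bear for class-level analyses, Kruskal-Wallis/Dunn nonparametric class
comparisons, and scenario prediction from fitted (or published)
coefficient sets.

AIC convention used throughout: -2·loglik + 2·k with k counting the
intercept, slope/effective parameters and the residual variance, so the
linear and smooth candidates are compared on the same footing.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "TrendComparison",
    "MissingCovariate",
    "collinearity_screen",
    "default_model_menu",
    "screen_menu",
    "fit_linear",
    "fit_smooth_trend",
    "fit_trend_menu",
    "fit_env_models",
    "fit_class_env_models",
    "class_differences",
    "dunn_test",
    "predict_scenario",
    "reference_env_fits",
    "REFERENCE_MINIMUM_ENERGY_DENSITY",
    "REFERENCE_MINIMUM_STORAGE_ENERGY",
]

COLLINEARITY_THRESHOLD = 0.6
ALPHA = 0.05


class MissingCovariate(KeyError):
    """A prediction was requested without a value for a model covariate."""


@dataclass
class RegressionFit:
    """A fitted (or published) linear model with a prediction interface."""

    response: str
    covariates: list[str]
    intercept: float
    coef: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    r2: float = float("nan")
    fvalue: float = float("nan")
    aic: float = float("nan")
    n: int = 0
    kind: str = "ols"
    edf: float = float("nan")
    random_intercept_var: float = float("nan")

    def predict(self, values: dict[str, float] | pd.DataFrame) -> float | np.ndarray:
        """Linear predictor: intercept + sum(beta_i * x_i)."""
        if isinstance(values, pd.DataFrame):
            missing = [c for c in self.covariates if c not in values.columns]
            if missing:
                raise MissingCovariate(f"missing covariate(s) {missing}")
            out = np.full(len(values), self.intercept, dtype=float)
            for c in self.covariates:
                out += self.coef[c] * values[c].to_numpy(dtype=float)
            return out
        missing = [c for c in self.covariates if c not in values]
        if missing:
            raise MissingCovariate(f"missing covariate(s) {missing}")
        return self.intercept + sum(self.coef[c] * values[c]
                                    for c in self.covariates)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionFit":
        return cls(**d)


def _own_aic(llf: float, k: float) -> float:
    return -2.0 * llf + 2.0 * k


def collinearity_screen(covariates: pd.DataFrame,
                        threshold: float = COLLINEARITY_THRESHOLD
                        ) -> pd.DataFrame:
    """Pairwise Pearson r between covariates with admissibility flags.

    Pairs with |r| > threshold are inadmissible in the same model.
    Pairs involving a constant column have undefined r and are flagged
    inadmissible with a warning.  Requires >= 3 complete rows.
    """
    cols = list(covariates.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        sub = covariates[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete rows for pair ({a}, {b})")
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("collinearity_screen: constant column in pair "
                           "(%s, %s); r undefined, flagged inadmissible", a, b)
            r = np.nan
            admissible = False
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            admissible = abs(r) <= threshold
        rows.append({"var1": a, "var2": b, "r": r, "admissible": admissible})
    return pd.DataFrame(rows)


def default_model_menu(covariates: list[str]) -> list[list[str]]:
    """The a-priori candidate menu: every singleton plus every pair.

    Pairs violating the collinearity screen are removed later by
    :func:`screen_menu`.
    """
    menu: list[list[str]] = [[c] for c in covariates]
    menu += [list(p) for p in itertools.combinations(covariates, 2)]
    return menu


def screen_menu(menu: list[list[str]], data: pd.DataFrame,
                threshold: float = COLLINEARITY_THRESHOLD) -> list[list[str]]:
    """Drop candidates containing an inadmissible covariate pair."""
    all_vars = sorted({v for m in menu for v in m})
    pairs = collinearity_screen(data[all_vars], threshold)
    bad = {frozenset((r.var1, r.var2)) for r in pairs.itertuples()
           if not r.admissible}
    return [m for m in menu
            if not any(frozenset(p) in bad
                       for p in itertools.combinations(m, 2))]


def fit_linear(data: pd.DataFrame, response: str,
               covariates: list[str]) -> RegressionFit:
    """OLS fit of response ~ covariates with Gaussian AIC."""
    sub = data[[response] + covariates].dropna()
    n, p = len(sub), len(covariates)
    if n <= p + 1:
        raise ValueError(f"need n > p+1 ({n} rows, {p} covariates)")
    y = sub[response].to_numpy(float)
    X = sm.add_constant(sub[covariates].to_numpy(float)) if p else \
        np.ones((n, 1))
    res = sm.OLS(y, X).fit()
    k = p + 2  # intercept + slopes + residual variance
    names = ["const"] + covariates
    return RegressionFit(
        response=response,
        covariates=list(covariates),
        intercept=float(res.params[0]),
        coef={c: float(res.params[i + 1]) for i, c in enumerate(covariates)},
        se={c: float(res.bse[i + 1]) for i, c in enumerate(covariates)},
        pvalues={c: float(res.pvalues[i + 1]) for i, c in enumerate(covariates)},
        r2=float(res.rsquared) if p else 0.0,
        fvalue=float(res.fvalue) if p else float("nan"),
        aic=_own_aic(float(res.llf), k),
        n=n,
        kind="ols",
    )


@dataclass
class SmoothFit:
    """A penalized B-spline trend fit (thin wrapper over GLMGam)."""

    x: np.ndarray
    fitted: np.ndarray
    edf: float          # effective dof of the smooth term (1 ~ linear)
    alpha: float        # selected penalty weight
    llf: float
    aic: float
    n: int

    def predict_at_knots(self) -> np.ndarray:
        return self.fitted


def fit_smooth_trend(data: pd.DataFrame, response: str, x: str,
                     basis_df: int = 10,
                     alpha_grid: np.ndarray | None = None) -> SmoothFit:
    """Penalized-spline smooth of response over x, penalty picked by GCV.

    Delegates estimation to statsmodels' GLMGam (Gaussian, identity
    link); the effective degrees of freedom of the smooth term are the
    trace-based edf minus the intercept.  At very large penalties the
    fit collapses to a straight line (edf -> 1).
    """
    sub = data[[response, x]].dropna().sort_values(x)
    n = len(sub)
    if n < 8:
        raise ValueError(f"need >= 8 points for a smooth fit, got {n}")
    y = sub[response].to_numpy(float)
    xv = sub[x].to_numpy(float)
    basis_df = min(basis_df, n - 2)
    bs = BSplines(xv[:, None], df=[basis_df], degree=[3])
    if alpha_grid is None:
        alpha_grid = np.logspace(-4, 8, 25)
    best = None
    for alpha in alpha_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = GLMGam(y, exog=np.ones((n, 1)), smoother=bs,
                             alpha=[float(alpha)]).fit()
        except Exception:
            continue
        edf_total = float(np.sum(res.edf))
        rss = float(np.sum((y - res.fittedvalues) ** 2))
        if n - edf_total <= 0:
            continue
        gcv = n * rss / (n - edf_total) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, alpha, res, edf_total)
    if best is None:
        raise RuntimeError("smooth fit failed for every penalty weight")
    _, alpha, res, edf_total = best
    # concentrated Gaussian log-likelihood from the RSS, same convention
    # as the OLS fits so the AICs are directly comparable
    rss = float(np.sum((y - res.fittedvalues) ** 2))
    llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    k = edf_total + 1  # effective params + residual variance
    return SmoothFit(
        x=xv, fitted=np.asarray(res.fittedvalues), edf=edf_total - 1.0,
        alpha=float(alpha), llf=llf, aic=_own_aic(llf, k), n=n,
    )


@dataclass
class TrendComparison:
    """Linear vs. smooth temporal-trend comparison for one series."""

    linear: RegressionFit
    smooth: SmoothFit | None
    winner: str          # "linear" or "smooth"
    delta_aic: float     # AIC(linear) - AIC(smooth); NaN if no smooth fit


def fit_trend_menu(data: pd.DataFrame, response: str,
                   time_col: str = "year") -> TrendComparison:
    """Compare a linear and a penalized-spline trend by AIC.

    The smooth candidate wins only if its AIC is more than 2 below the
    linear AIC (ΔAIC < 2 means the models are indistinguishable and the
    simpler linear form is kept).  Smooth non-convergence falls back to
    the linear winner with a warning.
    """
    lin = fit_linear(data, response, [time_col])
    try:
        smooth = fit_smooth_trend(data, response, time_col)
    except Exception as exc:
        logger.warning("smooth trend fit failed (%s); linear selected", exc)
        return TrendComparison(lin, None, "linear", float("nan"))
    delta = lin.aic - smooth.aic
    winner = "smooth" if delta > 2.0 else "linear"
    return TrendComparison(lin, smooth, winner, delta)


def fit_env_models(data: pd.DataFrame, response: str,
                   menu: list[list[str]] | None = None,
                   threshold: float = COLLINEARITY_THRESHOLD
                   ) -> list[RegressionFit]:
    """Fit the (screened) candidate menu by OLS, ranked by AIC."""
    if menu is None:
        covs = [c for c in data.columns if c != response]
        menu = default_model_menu(covs)
    menu = screen_menu(menu, data, threshold)
    fits = []
    for m in menu:
        try:
            fits.append(fit_linear(data, response, m))
        except Exception as exc:
            logger.warning("model %s failed: %s", m, exc)
    return sorted(fits, key=lambda f: f.aic)


def fit_mixed(data: pd.DataFrame, response: str, covariates: list[str],
              group_col: str = "bear_id") -> RegressionFit:
    """Linear mixed model with a random intercept per individual.

    Falls back to OLS (with a warning) when no individual repeats, so
    the random intercept is not estimable.  Fitted by ML so AICs are
    comparable across fixed-effect structures.
    """
    sub = data[[response, group_col] + covariates].dropna()
    repeats = sub[group_col].duplicated().any()
    if not repeats:
        logger.warning("no repeated individuals; degrading to OLS")
        return fit_linear(sub, response, covariates)
    X = sm.add_constant(sub[covariates].to_numpy(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(sub[response].to_numpy(float), X,
                             groups=sub[group_col]).fit(reml=False)
        if not res.converged:
            raise RuntimeError("mixed model did not converge")
    except Exception as exc:
        logger.warning("mixed model failed (%s); degrading to OLS", exc)
        return fit_linear(sub, response, covariates)
    p = len(covariates)
    k = p + 3  # intercept + slopes + random-intercept var + residual var
    return RegressionFit(
        response=response,
        covariates=list(covariates),
        intercept=float(res.params[0]),
        coef={c: float(res.params[i + 1]) for i, c in enumerate(covariates)},
        se={c: float(res.bse[i + 1]) for i, c in enumerate(covariates)},
        pvalues={c: float(res.pvalues[i + 1]) for i, c in enumerate(covariates)},
        aic=_own_aic(float(res.llf), k),
        n=len(sub),
        kind="mixed",
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
    )


def fit_class_env_models(data: pd.DataFrame, response: str,
                         menu: list[list[str]],
                         group_col: str = "bear_id",
                         threshold: float = COLLINEARITY_THRESHOLD
                         ) -> list[RegressionFit]:
    """Class-level environment models with bear-ID random intercepts.

    `data` holds one row per capture of the class with the response and
    covariate columns merged in.  The menu is screened for collinearity
    on the supplied data, each candidate is fitted (mixed, degrading to
    OLS where the random intercept is inestimable or the fit fails) and
    the fits are returned ranked by AIC.
    """
    menu = screen_menu(menu, data, threshold)
    fits = []
    for m in menu:
        try:
            fits.append(fit_mixed(data, response, m, group_col))
        except Exception as exc:
            logger.warning("class model %s failed: %s", m, exc)
    return sorted(fits, key=lambda f: f.aic)


@dataclass
class ClassDifferenceResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise results."""

    statistic: float
    df: int
    pvalue: float
    dunn: pd.DataFrame  # group1, group2, z, p, p_adj


def dunn_test(groups: dict[str, np.ndarray],
              adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank-sum z tests with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups.  Two-sided
    p-values, Holm-adjusted by default.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    N = len(values)
    ranks = st.rankdata(values)
    mean_ranks = {}
    i = 0
    for g in names:
        mean_ranks[g] = ranks[i:i + sizes[g]].mean()
        i += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    ties = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - ties
    rows = []
    for a, b in itertools.combinations(names, 2):
        denom = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / denom if denom > 0 else 0.0
        p = 2.0 * st.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(df["p"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    else:
        df["p_adj"] = df["p"]
    return df


def class_differences(profiles: pd.DataFrame, value_col: str,
                      class_col: str = "class") -> ClassDifferenceResult:
    """Kruskal-Wallis ANOVA across classes plus Dunn post-hoc tests.

    Requires >= 2 classes with >= 2 observations each.  With every value
    identical the tie-corrected statistic is 0 and p is 1.
    """
    groups = {str(g): grp[value_col].dropna().to_numpy(float)
              for g, grp in profiles.groupby(class_col)}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with >= 2 observations")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        stat, p = 0.0, 1.0  # every value tied: statistic 0 after correction
    else:
        stat, p = st.kruskal(*arrays)
    return ClassDifferenceResult(
        statistic=float(stat), df=len(groups) - 1, pvalue=float(p),
        dunn=dunn_test(groups))


def predict_scenario(fit: RegressionFit,
                     values: dict[str, float]) -> float:
    """Point prediction of a fitted model at given covariate values."""
    return float(fit.predict(values))


# ---------------------------------------------------------------------------
# Published reference estimates for the Western Hudson Bay population
# (1985-2018 monitoring program): the best environment models for total
# population energy density and storage energy, with breakup date and
# the one-year-lagged open-water period as covariates, and the minimum
# annual estimates observed over the study.  These are published inputs,
# used for scenario prediction and as comparison baselines.
# ---------------------------------------------------------------------------

REFERENCE_MINIMUM_ENERGY_DENSITY = 12475.0   # MJ kg^-1 (population total)
REFERENCE_MINIMUM_STORAGE_ENERGY = 1398529.0  # MJ


def reference_env_fits() -> dict[str, RegressionFit]:
    """The published best multiple-regression models for the WH population.

    Keys "energy_density" (MJ kg^-1) and "storage_energy" (MJ); both use
    covariates breakup_doy and open_water_days_lag1.
    """
    return {
        "energy_density": RegressionFit(
            response="ed_mean",
            covariates=["breakup_doy", "open_water_days_lag1"],
            intercept=5186.56,
            coef={"breakup_doy": 176.60, "open_water_days_lag1": -117.10},
            se={"breakup_doy": 45.82, "open_water_days_lag1": 33.59},
            pvalues={"breakup_doy": 0.001, "open_water_days_lag1": 0.001},
            r2=0.54, fvalue=18.42, n=34, kind="published",
        ),
        "storage_energy": RegressionFit(
            response="se_mean",
            covariates=["breakup_doy", "open_water_days_lag1"],
            intercept=392250.0,
            coef={"breakup_doy": 21970.0, "open_water_days_lag1": -14241.0},
            se={"breakup_doy": 5261.0, "open_water_days_lag1": 3857.0},
            pvalues={"breakup_doy": 0.001, "open_water_days_lag1": 0.001},
            r2=0.58, fvalue=21.18, n=34, kind="published",
        ),
    }
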