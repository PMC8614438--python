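"""Linear mixed models, AIC selection and model averaging for
environmental drivers of activity.

The modelling protocol: linear mixed models (identity link, Gaussian
errors) with a per-animal random intercept, fit by maximum likelihood;
predictors not already on a 0-1 scale are z-scored.  Candidate
covariates pass a univariate screen (AIC below the intercept-only
model), correlated pairs (|Pearson r| > 0.7 by default) keep only the
lower-AIC member, all subsets of the survivors are fit, models within
Delta-AIC < 2 of the best are retained, and full (zero-substituted)
Akaike-weight averaging yields the reported coefficients.  Significance
uses a normal approximation to the t statistic with a 0.001 threshold
(appropriate at these sample sizes); goodness of fit is the squared
correlation between fitted (including random effects) and observed
values.

AIC is computed as ``2k - 2 logLik`` with ``k`` counting the fixed
effects (intercept included), the random-intercept variance and the
residual variance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "CandidateModel",
    "SelectionResult",
    "fit_lmm",
    "select_and_average",
    "location_activity_model",
    "standardize_covariates",
]

SIGNIFICANCE_ALPHA = 0.001
CORR_THRESHOLD = 0.7
DELTA_AIC_CUT = 2.0


@dataclass
class CandidateModel:
    """One fitted mixed model of a candidate fixed-effect set."""

    response: str
    fixed: tuple[str, ...]
    params: pd.Series          # fixed-effect estimates (incl. intercept)
    bse: pd.Series             # their standard errors
    llf: float
    k: int                     # parameter count used in AIC
    aic: float
    n: int
    group_var: float           # random-intercept variance
    resid_var: float
    singular: bool
    fitted: np.ndarray = field(repr=False)
    observed: np.ndarray = field(repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)
    weight: float | None = None

    @property
    def r2(self) -> float:
        """Squared correlation of fitted (incl. random effects) vs observed."""
        if np.std(self.fitted) == 0 or np.std(self.observed) == 0:
            return 0.0
        return float(np.corrcoef(self.fitted, self.observed)[0, 1] ** 2)


def standardize_covariates(
    table: pd.DataFrame, covariates: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score covariates whose observed values leave the 0-1 scale.

    Covariates already expressed as proportions (day length, moon phase,
    darkness) are left untouched.  Returns the transformed copy and the
    list of covariates that were standardized.
    """
    df = table.copy()
    touched = []
    for c in covariates:
        x = df[c].to_numpy(dtype=float)
        if x.min() < 0.0 or x.max() > 1.0:
            sd = x.std()
            df[c] = (x - x.mean()) / (sd if sd > 0 else 1.0)
            touched.append(c)
    return df, touched


def _degenerate_model(response, fixed, y, n) -> CandidateModel:
    names = ["intercept", *fixed]
    params = pd.Series([float(y[0])] + [0.0] * len(fixed), index=names)
    bse = pd.Series(0.0, index=names)
    k = len(names) + 2
    return CandidateModel(
        response=response, fixed=tuple(fixed), params=params, bse=bse,
        llf=np.inf, k=k, aic=-np.inf, n=n, group_var=0.0, resid_var=0.0,
        singular=True, fitted=y.copy(), observed=y.copy(),
        diagnostics={"note": "constant response"},
    )


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...] = (),
    group: str = "animal",
) -> CandidateModel:
    """Fit a per-animal random-intercept linear mixed model by ML.

    ``fixed`` names columns of ``table``; an intercept is always added.
    Requires at least two animals.  Residual diagnostics (normality test
    p-value, |residual|-vs-fitted correlation as a heteroscedasticity
    cue) are attached; a near-zero random-intercept variance flags the
    fit as singular but it is still returned.
    """
    groups = table[group]
    if groups.nunique() < 2:
        raise ValueError("mixed model needs at least two animals")
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        return _degenerate_model(response, fixed, y, n)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=table.index)
    for c in fixed:
        X[c] = table[c].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=False, method=method)
            except Exception:
                continue
            if np.isfinite(cand.llf) and cand.converged:
                res = cand
                break
            if res is None and np.isfinite(cand.llf):
                res = cand
        if res is None:
            raise RuntimeError("mixed model failed to converge")
        bse_fe = np.asarray(res.bse_fe)
    bse_fe = np.where(np.isfinite(bse_fe), bse_fe, 0.0)

    k = X.shape[1] + 2  # fixed effects + group variance + residual variance
    llf = float(res.llf)
    group_var = float(np.squeeze(res.cov_re))
    resid_var = float(res.scale)
    singular = bool(group_var < 1e-8 * max(resid_var, 1e-12))

    fe = res.fe_params
    fitted_fe = X.to_numpy() @ np.asarray(fe)
    try:
        re = res.random_effects
        re_map = {g: float(np.squeeze(v)) for g, v in re.items()}
    except ValueError:  # singular covariance: BLUPs are all zero
        re_map = {}
        singular = True
    fitted = fitted_fe + groups.map(re_map).fillna(0.0).to_numpy(dtype=float)
    resid = y - fitted

    diagnostics = {}
    if n >= 20:
        diagnostics["normality_p"] = float(stats.normaltest(resid).pvalue)
    if np.std(fitted) > 0 and np.std(np.abs(resid)) > 0:
        diagnostics["abs_resid_fitted_corr"] = float(
            np.corrcoef(np.abs(resid), fitted)[0, 1]
        )

    params = pd.Series(np.asarray(fe), index=list(X.columns))
    bse = pd.Series(bse_fe, index=list(X.columns))
    return CandidateModel(
        response=response, fixed=tuple(fixed), params=params, bse=bse,
        llf=llf, k=k, aic=2 * k - 2 * llf, n=n, group_var=group_var,
        resid_var=resid_var, singular=singular, fitted=fitted, observed=y,
        diagnostics=diagnostics,
    )


@dataclass
class SelectionResult:
    """Outcome of screening, all-subsets selection and model averaging."""

    response: str
    survivors: list[str]
    dropped_correlated: list[str]
    models: pd.DataFrame          # fixed set, AIC, dAIC, retained, weight
    retained: list[CandidateModel]
    coefficients: pd.DataFrame    # averaged estimate, SE, z, p, significant
    r2_global: float
    note: str = ""


def _akaike_weights(aics: np.ndarray) -> np.ndarray:
    d = aics - aics.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def _full_average(
    retained: list[CandidateModel], weights: np.ndarray, terms: list[str]
) -> pd.DataFrame:
    """Full (zero-substituted) model averaging of coefficients and SEs."""
    rows = []
    for term in terms:
        betas = np.array(
            [m.params.get(term, 0.0) for m in retained]
        )
        ses = np.array([m.bse.get(term, 0.0) for m in retained])
        est = float(np.sum(weights * betas))
        se = float(np.sum(weights * np.sqrt(ses**2 + (betas - est) ** 2)))
        z = abs(est) / se if se > 0 else np.inf
        p = 2.0 * (1.0 - stats.norm.cdf(z)) if np.isfinite(z) else 0.0
        rows.append(
            {"term": term, "estimate": est, "se": se, "z": z, "p": p}
        )
    out = pd.DataFrame(rows).set_index("term")
    out["significant"] = out["p"] < SIGNIFICANCE_ALPHA
    return out


def select_and_average(
    table: pd.DataFrame,
    response: str,
    candidate_vars: list[str],
    group: str = "animal",
    corr_threshold: float = CORR_THRESHOLD,
    delta_aic: float = DELTA_AIC_CUT,
    standardize: bool = True,
) -> SelectionResult:
    """Run the full selection protocol for one activity response.

    Steps: (1) univariate AIC screen against the intercept-only model;
    (2) among informative variables correlated above ``corr_threshold``
    keep the one with the lower univariate AIC; (3) fit all subsets of
    the survivors (intercept-only included); (4) retain the
    Delta-AIC < ``delta_aic`` set, renormalising Akaike weights within
    it; (5) full model averaging of coefficients with normal-theory
    p-values; R^2 is reported for the global (all-survivors) model.
    """
    df = table
    if standardize:
        df, _ = standardize_covariates(table, candidate_vars)
    null = fit_lmm(df, response, (), group)
    uni = {v: fit_lmm(df, response, (v,), group) for v in candidate_vars}
    informative = [v for v in candidate_vars if uni[v].aic < null.aic]

    # Correlation filter, best-AIC variable first.
    informative.sort(key=lambda v: uni[v].aic)
    survivors: list[str] = []
    dropped: list[str] = []
    for v in informative:
        r = [abs(df[v].corr(df[s])) for s in survivors]
        if any(np.asarray(r) > corr_threshold):
            dropped.append(v)
        else:
            survivors.append(v)

    if not survivors:
        models = pd.DataFrame(
            {"fixed": ["(intercept)"], "aic": [null.aic], "daic": [0.0],
             "retained": [True], "weight": [1.0]}
        )
        coef = _full_average([null], np.array([1.0]), ["intercept"])
        return SelectionResult(
            response=response, survivors=[], dropped_correlated=dropped,
            models=models, retained=[null], coefficients=coef,
            r2_global=null.r2,
            note="no variable survived the univariate screen",
        )

    subsets = [
        combo
        for r in range(len(survivors) + 1)
        for combo in itertools.combinations(survivors, r)
    ]
    fits = {c: (null if c == () else fit_lmm(df, response, c, group)) for c in subsets}
    aics = np.array([fits[c].aic for c in subsets])
    daic = aics - aics.min()
    retained_mask = daic < delta_aic
    retained = [fits[c] for c, m in zip(subsets, retained_mask) if m]
    weights = _akaike_weights(np.array([m.aic for m in retained]))
    for m, w in zip(retained, weights):
        m.weight = float(w)

    models = pd.DataFrame(
        {
            "fixed": [" + ".join(c) if c else "(intercept)" for c in subsets],
            "aic": aics,
            "daic": daic,
            "retained": retained_mask,
        }
    ).sort_values("aic", ignore_index=True)
    models["weight"] = [
        next((m.weight for m in retained if " + ".join(m.fixed) == f or
              (not m.fixed and f == "(intercept)")), np.nan)
        for f in models["fixed"]
    ]

    coef = _full_average(retained, weights, ["intercept", *survivors])
    global_model = fits[tuple(survivors)]
    return SelectionResult(
        response=response, survivors=survivors, dropped_correlated=dropped,
        models=models, retained=retained, coefficients=coef,
        r2_global=global_model.r2,
    )


def location_activity_model(
    linked: pd.DataFrame,
    group: str = "animal",
    cover_col: str = "forest_cover",
    dark_col: str = "darkness",
    response: str = "mean_odba",
) -> tuple[CandidateModel, list[str]]:
    """Mixed model of non-resting location activity on habitat and light.

    Fits mean location ODBA on % forest cover (z-scored), its square,
    darkness (0/1) and the cover x darkness interaction, with a
    per-animal random intercept.  Columns without variation (e.g.
    darkness in an all-daylight subset) are inestimable: they are dropped
    from the design and reported in the returned flag list.
    """
    df = linked.loc[~linked["resting"]].copy()
    if df.empty:
        raise ValueError("no non-resting locations to model")
    cover = df[cover_col].to_numpy(dtype=float)
    sd = cover.std()
    cover_z = (cover - cover.mean()) / sd if sd > 0 else cover * 0.0
    df["cover"] = cover_z
    df["cover_sq"] = cover_z**2
    df["dark"] = df[dark_col].to_numpy(dtype=float)
    df["cover_x_dark"] = df["cover"] * df["dark"]

    terms = ["cover", "cover_sq", "dark", "cover_x_dark"]
    inestimable = [t for t in terms if np.ptp(df[t].to_numpy()) == 0]
    usable = tuple(t for t in terms if t not in inestimable)
    model = fit_lmm(df, response, usable, group)
    return model, inestimable
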