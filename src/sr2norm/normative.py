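"""Normative regression, Z-scoring, and outlier flagging.

The normative functions are ordinary least-squares regressions of the
track-estimated TMR thresholds (and SRM) on age and bilateral standard PTA:

    predicted threshold = constant + age * beta_age + PTA * beta_PTA

A candidate age x PTA interaction is fitted first and dropped when not
significant, after which non-significant main effects are eliminated
(largest p first, refitting after each removal).  The residual spread of the
final fit — "model error", RMSE by default, MAE as an option — is the SD
denominator of the Z-transform

    Z = (observed - predicted) / model error

and |Z| >= 2 (two-sided: both remarkably good and remarkably poor
performance) flags an individual as abnormal for their age and hearing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import predict_from_model
from .types import (
    AGE_RANGE,
    MEASURES,
    PTA_RANGE,
    RUN_LABELS,
    CohortTable,
    ExtrapolationWarning,
    NormativeModel,
    ZReportEntry,
    measure_column,
)

#: Number of correlations in the screening family (4 predictors x 3 outcomes
#: + 3 predictor-age pairs); fixes the Bonferroni criterion.
N_SCREEN_CORRELATIONS = 15

ALL_MODEL_KEYS: tuple[tuple[str, str], ...] = tuple(
    (m, r) for m in MEASURES for r in RUN_LABELS
)


@dataclass
class OLSFit:
    """Plain-container result of an ordinary least-squares fit."""

    names: tuple[str, ...]  # includes "const"
    params: np.ndarray
    bse: np.ndarray
    p_values: np.ndarray
    adj_r2: float
    residuals: np.ndarray
    n: int

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def p(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])


def ols_fit(design: np.ndarray | pd.DataFrame, response, names=None) -> OLSFit:
    """Ordinary least squares with an intercept.

    ``design`` holds the predictor columns (no intercept column); p-values are
    two-sided t-tests against zero with n - p - 1 degrees of freedom.
    """
    if isinstance(design, pd.DataFrame):
        names = tuple(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(names) if names else tuple(f"x{i + 1}" for i in range(X.shape[1]))
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit {p} predictors, got {n}")
    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, Xc).fit()
    return OLSFit(
        names=("const", *names),
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        adj_r2=float(res.rsquared_adj),
        residuals=np.asarray(res.resid, dtype=float),
        n=n,
    )


def _residual_error(residuals: np.ndarray, method: str) -> float:
    if method == "rmse":
        return float(np.sqrt(np.mean(np.square(residuals))))
    if method == "mae":
        return float(np.mean(np.abs(residuals)))
    raise ValueError(f"unknown model-error method {method!r}")


def fit_normative_vectors(
    age,
    pta,
    y,
    condition: str = "separated",
    run: str = "average",
    alpha: float = 0.05,
    error_method: str = "rmse",
) -> NormativeModel:
    """Fit one normative model from raw vectors with backward elimination.

    The full model is age + PTA + age x PTA.  The interaction is removed first
    when its p-value is at or above ``alpha``; afterwards non-significant main
    effects are removed one at a time (largest p first), refitting after each
    removal.  If the interaction survives, the main effects are retained
    regardless (model hierarchy).  With every predictor eliminated an
    intercept-only model is returned with a warning.
    """
    age = np.asarray(age, dtype=float)
    pta = np.asarray(pta, dtype=float)
    y = np.asarray(y, dtype=float)
    design = pd.DataFrame({"age": age, "pta": pta, "age_x_pta": age * pta})
    y_scale = max(float(np.std(y)), 1.0)

    def pval(f: OLSFit, name: str) -> float:
        # a term whose whole contribution is numerically negligible is treated
        # as nonsignificant even when a (near-)perfect fit degenerates the t
        contribution = abs(f.coef(name)) * float(np.std(design[name]))
        if contribution < 1e-8 * y_scale:
            return 1.0
        p = f.p(name)
        return 1.0 if np.isnan(p) else p

    fit = ols_fit(design, y)
    included = ["age", "pta", "age_x_pta"]
    if pval(fit, "age_x_pta") >= alpha:
        included.remove("age_x_pta")
        fit = ols_fit(design[included], y)
        while included:
            worst = max(included, key=lambda name: pval(fit, name))
            if pval(fit, worst) < alpha:
                break
            included.remove(worst)
            if included:
                fit = ols_fit(design[included], y)
    if not included:
        warnings.warn(
            f"{condition}/{run}: no predictor reached significance; "
            "returning an intercept-only model",
            UserWarning,
            stacklevel=2,
        )
        resid = y - y.mean()
        return NormativeModel(
            condition=condition, run=run, predictors=(),
            constant=float(y.mean()),
            model_error=_residual_error(resid, error_method),
            error_method=error_method,
            adj_r2=0.0, n=len(y), p_values={},
        )
    return NormativeModel(
        condition=condition,
        run=run,
        predictors=tuple(included),
        constant=fit.coef("const"),
        beta_age=fit.coef("age") if "age" in included else None,
        beta_pta=fit.coef("pta") if "pta" in included else None,
        beta_age_pta=fit.coef("age_x_pta") if "age_x_pta" in included else None,
        model_error=_residual_error(fit.residuals, error_method),
        error_method=error_method,
        adj_r2=fit.adj_r2,
        n=fit.n,
        p_values={name: fit.p(name) for name in ("const", *included)},
    )


def fit_normative_model(
    cohort: CohortTable,
    condition: str,
    run: str,
    alpha: float = 0.05,
    error_method: str = "rmse",
) -> NormativeModel:
    """Fit the normative model for one measure x run label from a cohort.

    Hearing loss enters as the bilateral standard PTA (recomputed from the
    audiogram), the variant least correlated with age in the original study.
    """
    return fit_normative_vectors(
        cohort.df["age"],
        cohort.df["pta_st"],
        cohort.outcome(condition, run),
        condition=condition,
        run=run,
        alpha=alpha,
        error_method=error_method,
    )


def fit_all_models(
    cohort: CohortTable, alpha: float = 0.05, error_method: str = "rmse"
) -> dict[tuple[str, str], NormativeModel]:
    """Fit all nine normative models (3 measures x runs 1, 2, average)."""
    return {
        key: fit_normative_model(cohort, *key, alpha=alpha, error_method=error_method)
        for key in ALL_MODEL_KEYS
    }


def model_error(
    model: NormativeModel, cohort: CohortTable, method: str = "rmse"
) -> float:
    """Recompute the model error of a fitted model on a cohort (RMSE or MAE)."""
    pred = predict_from_model(model, cohort.df["age"], cohort.df["pta_st"])
    resid = cohort.outcome(model.condition, model.run).to_numpy(dtype=float) - pred
    return _residual_error(resid, method)


def predict_threshold(
    model: NormativeModel,
    age: float | None = None,
    pta: float | None = None,
    warn_extrapolation: bool = True,
) -> float:
    """Normative prediction for one individual over the model's included terms."""
    needs_age = model.beta_age is not None or model.beta_age_pta is not None
    needs_pta = model.beta_pta is not None or model.beta_age_pta is not None
    if needs_age and age is None:
        raise ValueError(f"{model.condition}/{model.run}: model requires an age")
    if needs_pta and pta is None:
        raise ValueError(f"{model.condition}/{model.run}: model requires a PTA")
    if warn_extrapolation and _is_extrapolation(model, age, pta):
        warnings.warn(
            f"{model.condition}/{model.run}: prediction outside the supported "
            f"age {AGE_RANGE} / PTA {PTA_RANGE} ranges is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(predict_from_model(model, age if age is not None else 0.0,
                                    pta if pta is not None else 0.0))


def _is_extrapolation(model: NormativeModel, age, pta) -> bool:
    needs_age = model.beta_age is not None or model.beta_age_pta is not None
    needs_pta = model.beta_pta is not None or model.beta_age_pta is not None
    out = False
    if needs_age and age is not None:
        out |= not AGE_RANGE[0] <= age <= AGE_RANGE[1]
    if needs_pta and pta is not None:
        out |= not PTA_RANGE[0] <= pta <= PTA_RANGE[1]
    return out


def z_score(
    model: NormativeModel,
    observed: float,
    age: float | None = None,
    pta: float | None = None,
    k: float = 2.0,
    participant_id: str | None = None,
) -> ZReportEntry:
    """Z-transform one observed threshold against a normative model.

    Z = (observed - predicted) / model error; |Z| at or beyond ``k`` (default
    2 SDs) raises the abnormal-performance flag.
    """
    if model.model_error <= 0:
        raise ValueError("model error must be positive to compute a Z-score")
    extrap = _is_extrapolation(model, age, pta)
    pred = predict_threshold(model, age, pta, warn_extrapolation=False)
    z = (observed - pred) / model.model_error
    return ZReportEntry(
        participant_id=participant_id,
        measure=measure_column(model.condition, model.run),
        observed=float(observed),
        predicted=pred,
        z=float(z),
        # inclusive "at or beyond k SDs", robust to float dust at the boundary
        flagged=bool(abs(z) >= k - 1e-9),
        extrapolated=extrap,
    )


def flag_outliers(
    cohort: CohortTable,
    models: dict[tuple[str, str], NormativeModel],
    k: float = 2.0,
) -> tuple[list[str], pd.DataFrame]:
    """Flag participants abnormal on any of the nine measures.

    Requires all nine fitted models; returns the flagged participant ids (in
    cohort order) and a tidy frame of every Z-report entry.
    """
    missing = [key for key in ALL_MODEL_KEYS if key not in models]
    if missing:
        raise ValueError(f"missing normative models for: {missing}")
    rows = []
    for i, pid in enumerate(cohort.ids()):
        age = float(cohort.df.at[i, "age"])
        pta = float(cohort.df.at[i, "pta_st"])
        for key in ALL_MODEL_KEYS:
            entry = z_score(
                models[key],
                float(cohort.outcome(*key).iloc[i]),
                age=age, pta=pta, k=k, participant_id=pid,
            )
            rows.append(entry.__dict__)
    reports = pd.DataFrame(rows)
    flagged_ids = [
        pid for pid in cohort.ids()
        if reports.loc[reports["participant_id"] == pid, "flagged"].any()
    ]
    return flagged_ids, reports


# --- correlation screen -----------------------------------------------------


@dataclass
class CorrelationTable:
    """Pearson screen of predictors against outcomes with a Bonferroni criterion."""

    r: pd.DataFrame  # predictors x (age + outcomes)
    p: pd.DataFrame
    significant: pd.DataFrame
    criterion: float  # family alpha / number of correlations, rounded to 4 dp
    critical_r: float  # exact two-sided critical |r| at the criterion for this n
    n: int
    delay_correlations: pd.DataFrame | None = None


def correlation_table(
    cohort: CohortTable, family_alpha: float = 0.05, run: str = "average"
) -> CorrelationTable:
    """Correlate age/SRT/PTA variants with the outcome measures.

    The screening family comprises the 12 predictor x outcome cells plus the
    three hearing-measure-vs-age cells; the Bonferroni criterion is the family
    alpha divided by 15, reported rounded to four decimals.  When retest delay
    is recorded, its correlations with the run-2 minus run-1 difference scores
    are reported alongside (they never enter the normative models).  Constant
    columns yield an undefined r, reported as NaN.
    """
    df = cohort.df
    preds = {
        "age": df["age"].astype(float),
        "srt": (df["srt_left"].astype(float) + df["srt_right"].astype(float)) / 2.0
        if "srt_left" in df and "srt_right" in df and df["srt_left"].notna().all()
        else None,
        "pta_st": df["pta_st"],
        "pta_hf": df["pta_hf"],
    }
    outcomes = {m: cohort.outcome(m, run).astype(float) for m in MEASURES}
    cols = ["age", *MEASURES]
    r = pd.DataFrame(np.nan, index=list(preds), columns=cols)
    p = pd.DataFrame(np.nan, index=list(preds), columns=cols)
    for pname, pv in preds.items():
        if pv is None:
            continue
        targets = {**({"age": preds["age"]} if pname != "age" else {}), **outcomes}
        for tname, tv in targets.items():
            if pname == "age" and tname == "age":
                continue
            if np.std(pv) == 0 or np.std(tv) == 0:
                continue  # undefined, left NaN
            rr, pp = stats.pearsonr(pv, tv)
            r.at[pname, tname] = rr
            p.at[pname, tname] = pp
    criterion = round(family_alpha / N_SCREEN_CORRELATIONS, 4)
    n = len(df)
    tcrit = stats.t.ppf(1.0 - criterion / 2.0, n - 2)
    critical_r = float(np.sqrt(tcrit**2 / (tcrit**2 + n - 2)))
    delay = None
    if "retest_delay_days" in df and df["retest_delay_days"].notna().all() and n > 2:
        rows = []
        for m in MEASURES:
            diff = cohort.outcome(m, "2") - cohort.outcome(m, "1")
            dv = df["retest_delay_days"].astype(float)
            if np.std(diff) == 0 or np.std(dv) == 0:
                rows.append({"measure": m, "r": np.nan, "p": np.nan})
            else:
                rr, pp = stats.pearsonr(dv, diff)
                rows.append({"measure": m, "r": rr, "p": pp})
        delay = pd.DataFrame(rows)
    return CorrelationTable(
        r=r, p=p, significant=p < criterion, criterion=criterion,
        critical_r=critical_r, n=n, delay_correlations=delay,
    )


# --- normative bands --------------------------------------------------------


def normative_band(
    model: NormativeModel,
    grid,
    variable: str,
    fixed_age: float | None = None,
    fixed_pta: float | None = None,
    k: float = 1.0,
) -> pd.DataFrame:
    """Normative prediction line with a +-k * model-error band over a grid.

    ``variable`` names the gridded predictor ("age" or "pta"); the other is
    held at its fixed value (conventionally age 50 or PTA 10).  The band is
    homoscedastic: its half-width k * model_error is constant over the grid.
    """
    if variable not in ("age", "pta"):
        raise ValueError(f"unknown band variable {variable!r}")
    grid = np.asarray(grid, dtype=float)
    if variable == "age":
        center = predict_from_model(model, grid, np.full_like(grid, fixed_pta if fixed_pta is not None else 0.0))
    else:
        center = predict_from_model(model, np.full_like(grid, fixed_age if fixed_age is not None else 0.0), grid)
    half = k * model.model_error
    return pd.DataFrame(
        {variable: grid, "lower": center - half, "center": center, "upper": center + half}
    )


def cohort_summary(cohort: CohortTable) -> pd.DataFrame:
    """Mean and SD of each measure per run label (the layout of a norms table)."""
    rows = []
    for m in MEASURES:
        for run in RUN_LABELS:
            v = cohort.outcome(m, run).astype(float)
            rows.append(
                {"condition": m, "run": run,
                 "mean_db": float(v.mean()), "sd_db": float(v.std(ddof=1))}
            )
    return pd.DataFrame(rows)
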