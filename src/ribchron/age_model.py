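"""Age-at-death regression modelling on the 33-parameter feature table.

Workflow mirrors the standard multifactorial skeletal-ageing analysis:

1. :func:`screen` -- per-parameter normality (Shapiro-Wilk), sex effect
   (one-way ANOVA) and Pearson correlation with age;
2. :func:`stepwise_aic` -- bidirectional stepwise OLS selection minimising
   the Akaike information criterion, starting from the empty model, with a
   deterministic tie-break by candidate order;
3. :func:`fit_model` -- OLS fit with the full diagnostic block: VIF,
   condition index, Breusch-Pagan (Bonferroni-adjusted per-predictor),
   Shapiro-Wilk on residuals, Durbin-Watson (permutation p-value) and
   Cook's distances;
4. :func:`loo_cv` -- leave-one-out cross-validation (CV-R2, CV-RMSE,
   CV-MAE) by explicit refitting;
5. :func:`apply_published` -- evaluation of the published fixed equations
   (E1 full set, E2 mechanical, E3 physicochemical).

Missing values fail fast; there is no imputation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "FittedModel",
    "CvMetrics",
    "PublishedEquation",
    "screen",
    "fit_model",
    "stepwise_aic",
    "loo_cv",
    "load_published_equations",
    "apply_published",
]

VIF_CAP = 1e6  #: sentinel for perfectly collinear predictors


# --------------------------------------------------------------------------
# screening
# --------------------------------------------------------------------------

def screen(table: pd.DataFrame, parameters: Sequence[str] | None = None,
           alpha: float = 0.05) -> pd.DataFrame:
    """Univariate screening of every parameter against age and sex.

    Returns one row per parameter: Shapiro-Wilk (W, p), ANOVA by sex (F, p),
    Pearson correlation with age (r, p), plus significance flags at
    ``alpha``.  Constant columns get NaN statistics and a note.
    """
    if "age" not in table:
        raise ValueError("table must contain an 'age' column")
    if parameters is None:
        parameters = [c for c in table.columns if c not in ("specimen_id", "sex", "age")]
    rows = []
    age = table["age"].to_numpy(dtype=float)
    for name in parameters:
        x = table[name].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"missing values in column {name!r}")
        row: dict[str, object] = {"parameter": name}
        if np.ptp(x) == 0:
            row.update(shapiro_w=np.nan, shapiro_p=np.nan, anova_f=np.nan,
                       anova_p=np.nan, pearson_r=np.nan, pearson_p=np.nan,
                       note="constant column; statistics undefined")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # large-n Shapiro p-value notice
                sw = stats.shapiro(x)
            groups = [x[table["sex"].to_numpy() == s] for s in np.unique(table["sex"])]
            if len(groups) > 1 and all(len(g) >= 3 for g in groups):
                an = stats.f_oneway(*groups)
                f_val, f_p = float(an.statistic), float(an.pvalue)
            else:
                f_val, f_p = np.nan, np.nan
            pr = stats.pearsonr(x, age)
            row.update(shapiro_w=float(sw.statistic), shapiro_p=float(sw.pvalue),
                       anova_f=f_val, anova_p=f_p,
                       pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
                       note="")
        rows.append(row)
    out = pd.DataFrame(rows).set_index("parameter")
    out["non_normal"] = out["shapiro_p"] <= alpha
    out["sex_effect"] = out["anova_p"] <= alpha
    out["age_correlated"] = out["pearson_p"] <= alpha
    return out


# --------------------------------------------------------------------------
# fitting and diagnostics
# --------------------------------------------------------------------------


@dataclass
class FittedModel:
    predictors: list[str]
    coefficients: pd.Series            #: includes 'const'
    coef_se: pd.Series | None = None
    coef_p: pd.Series | None = None
    r2: float = np.nan
    adj_r2: float = np.nan
    rse: float = np.nan
    df_resid: int = 0
    f_statistic: float = np.nan
    f_df: tuple[int, int] = (0, 0)
    aic: float = np.nan
    bic: float = np.nan
    n: int = 0
    vif: dict[str, float] = field(default_factory=dict)
    condition_index: float = np.nan
    bp_lm: float = np.nan
    bp_p: float = np.nan
    bp_p_per_predictor: dict[str, float] = field(default_factory=dict)
    shapiro_w: float = np.nan
    shapiro_p: float = np.nan
    dw_statistic: float = np.nan
    dw_p: float = np.nan
    cooks_d: np.ndarray | None = None
    cooks_flagged: list[int] = field(default_factory=list)
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None

    def predict(self, table: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        if isinstance(table, Mapping) and not isinstance(table, pd.DataFrame):
            table = pd.DataFrame([table])
        x = np.column_stack([np.ones(len(table))] +
                            [table[p].to_numpy(dtype=float) for p in self.predictors])
        beta = np.concatenate([[self.coefficients["const"]],
                               [self.coefficients[p] for p in self.predictors]])
        return x @ beta

    def summary_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "coefficient_se": ({k: float(v) for k, v in self.coef_se.items()}
                               if self.coef_se is not None else None),
            "coefficient_p": ({k: float(v) for k, v in self.coef_p.items()}
                              if self.coef_p is not None else None),
            "r2": self.r2, "adj_r2": self.adj_r2, "rse": self.rse,
            "df_resid": self.df_resid, "f_statistic": self.f_statistic,
            "f_df": list(self.f_df), "aic": self.aic, "bic": self.bic, "n": self.n,
            "vif": self.vif, "condition_index": self.condition_index,
            "breusch_pagan": {"lm": self.bp_lm, "p": self.bp_p,
                              "p_per_predictor_bonferroni": self.bp_p_per_predictor},
            "residual_shapiro": {"w": self.shapiro_w, "p": self.shapiro_p},
            "durbin_watson": {"statistic": self.dw_statistic, "p": self.dw_p},
            "cooks_flagged": self.cooks_flagged,
        }


@dataclass
class CvMetrics:
    cv_r2: float
    cv_rmse: float
    cv_mae: float


def _design(table: pd.DataFrame, predictors: Sequence[str], response: str):
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise KeyError(f"predictors absent from table: {missing}")
    x = table[list(predictors)].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in design; no imputation is performed")
    return sm.add_constant(x, has_constant="add"), y


def _vif(x_no_const: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    k = x_no_const.shape[1]
    if k < 2:
        return {n: 1.0 for n in names}
    out = {}
    for j, name in enumerate(names):
        others = np.delete(x_no_const, j, axis=1)
        xj = x_no_const[:, j]
        res = sm.OLS(xj, sm.add_constant(others)).fit()
        r2 = min(res.rsquared, 1.0)
        out[name] = float(min(1.0 / (1.0 - r2), VIF_CAP)) if r2 < 1 else VIF_CAP
    return out


def _condition_index(x_with_const: np.ndarray) -> float:
    norms = np.linalg.norm(x_with_const, axis=0)
    norms[norms == 0] = 1.0
    s = np.linalg.svd(x_with_const / norms, compute_uv=False)
    return float(s.max() / s.min()) if s.min() > 0 else np.inf


def _dw_permutation_p(resid: np.ndarray, observed: float, n_perm: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    obs_dev = abs(observed - 2.0)
    count = 0
    r = resid.copy()
    for _ in range(n_perm):
        rng.shuffle(r)
        if abs(durbin_watson(r) - 2.0) >= obs_dev:
            count += 1
    return (count + 1) / (n_perm + 1)


def fit_model(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str = "age",
    dw_permutations: int = 2000,
    dw_seed: int = 0,
    cooks_threshold_factor: float = 4.0,
) -> FittedModel:
    """OLS fit with the complete diagnostic block populated."""
    predictors = list(predictors)
    x, y = _design(table, predictors, response)
    n, k1 = x.shape
    if n <= k1 + 1:
        raise ValueError(f"n={n} too small for {k1 - 1} predictors")
    res = sm.OLS(y, x).fit()
    if np.linalg.matrix_rank(x) < k1:
        raise np.linalg.LinAlgError(
            f"perfect collinearity among predictors {predictors}"
        )
    resid = np.asarray(res.resid)

    vif = _vif(x[:, 1:], predictors) if predictors else {}
    cond = _condition_index(x)

    if predictors:
        bp_lm, bp_p, *_ = het_breuschpagan(resid, x)
        per_pred = {}
        for j, name in enumerate(predictors):
            _, p_j, *_ = het_breuschpagan(resid, sm.add_constant(x[:, j + 1]))
            per_pred[name] = float(min(1.0, p_j * len(predictors)))
    else:
        bp_lm, bp_p, per_pred = np.nan, np.nan, {}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sw = stats.shapiro(resid)
    dw_stat = float(durbin_watson(resid))
    dw_p = _dw_permutation_p(resid, dw_stat, dw_permutations, dw_seed) if dw_permutations else np.nan

    infl = res.get_influence()
    cooks = np.asarray(infl.cooks_distance[0])
    threshold = cooks_threshold_factor / n
    flagged = [int(i) for i in np.flatnonzero(cooks > threshold)]

    names = ["const", *predictors]
    coefficients = pd.Series(np.asarray(res.params), index=names)
    f_df = (int(res.df_model), int(res.df_resid))
    return FittedModel(
        predictors=predictors,
        coefficients=coefficients,
        coef_se=pd.Series(np.asarray(res.bse), index=names),
        coef_p=pd.Series(np.asarray(res.pvalues), index=names),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        rse=float(np.sqrt(res.mse_resid)),
        df_resid=int(res.df_resid),
        f_statistic=float(res.fvalue) if predictors else np.nan,
        f_df=f_df,
        aic=float(res.aic),
        bic=float(res.bic),
        n=n,
        vif=vif,
        condition_index=cond,
        bp_lm=float(bp_lm),
        bp_p=float(bp_p),
        bp_p_per_predictor=per_pred,
        shapiro_w=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        dw_statistic=dw_stat,
        dw_p=float(dw_p),
        cooks_d=cooks,
        cooks_flagged=flagged,
        residuals=resid,
        fitted=np.asarray(res.fittedvalues),
    )


# --------------------------------------------------------------------------
# stepwise AIC
# --------------------------------------------------------------------------

def _aic_of(table: pd.DataFrame, predictors: Sequence[str], response: str) -> float:
    x, y = _design(table, predictors, response)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return np.inf
    return float(sm.OLS(y, x).fit().aic)


def stepwise_aic(
    table: pd.DataFrame,
    candidates: Sequence[str],
    response: str = "age",
    direction: str = "both",
    start: str = "empty",
    **fit_kwargs,
) -> FittedModel:
    """Stepwise AIC-minimising predictor selection, then a full diagnostic fit.

    ``direction`` is ``both`` (default), ``forward`` or ``backward``;
    ``start`` is ``empty`` or ``full``.  At every iteration all admissible
    single add/remove moves are scored and the best strict AIC improvement
    is taken; ties resolve to the earliest candidate in input order.
    """
    candidates = list(candidates)
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    current: list[str] = [] if start == "empty" else list(candidates)
    best_aic = _aic_of(table, current, response)

    while True:
        moves: list[tuple[float, list[str]]] = []
        if direction in ("both", "forward"):
            for c in candidates:
                if c not in current:
                    moves.append((_aic_of(table, current + [c], response), current + [c]))
        if direction in ("both", "backward"):
            for c in current:
                trial = [p for p in current if p != c]
                moves.append((_aic_of(table, trial, response), trial))
        improved = False
        for aic, trial in moves:  # input order => deterministic tie-break
            if aic < best_aic - 1e-10:
                best_aic, current, improved = aic, trial, True
        if not improved:
            break
    return fit_model(table, current, response, **fit_kwargs)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def loo_cv(table: pd.DataFrame, predictors: Sequence[str], response: str = "age") -> CvMetrics:
    """Leave-one-out cross-validation by explicit n-fold refitting."""
    predictors = list(predictors)
    x, y = _design(table, predictors, response)
    n = len(y)
    if n < len(predictors) + 3:
        raise ValueError(f"n={n} too small for LOO with {len(predictors)} predictors")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        beta, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
        preds[i] = x[i] @ beta
    err = y - preds
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CvMetrics(
        cv_r2=float(1.0 - np.sum(err**2) / ss_tot),
        cv_rmse=float(np.sqrt(np.mean(err**2))),
        cv_mae=float(np.mean(np.abs(err))),
    )


# --------------------------------------------------------------------------
# published equations
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PublishedEquation:
    name: str
    coefficients: Mapping[str, float]
    constant: float
    fit_statistics: Mapping[str, float] = field(default_factory=dict)

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients)


def load_published_equations(path: str | None = None) -> dict[str, PublishedEquation]:
    """The shipped fixed equations (E1/E2/E3), or a user-supplied JSON file."""
    if path is None:
        raw = resources.files("ribchron.data").joinpath("published_equations.json").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    doc = json.loads(raw)
    return {
        name: PublishedEquation(name, eq["coefficients"], eq["constant"], eq.get("fit", {}))
        for name, eq in doc["equations"].items()
    }


def apply_published(
    params: Mapping[str, float] | pd.DataFrame,
    eq: PublishedEquation,
) -> float | np.ndarray:
    """Predicted age = constant + sum(coefficient * value).

    Raises ``KeyError`` listing any missing predictor; warns when a
    prediction falls outside the plausible [0, 120] yr range.
    """
    frame = params if isinstance(params, pd.DataFrame) else pd.DataFrame([params])
    missing = [p for p in eq.predictors if p not in frame.columns]
    if missing:
        raise KeyError(f"equation {eq.name} missing predictor(s): {missing}")
    vals = frame[eq.predictors].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite predictor values for equation {eq.name}")
    pred = eq.constant + vals @ np.array([eq.coefficients[p] for p in eq.predictors])
    if np.any((pred < 0) | (pred > 120)):
        warnings.warn(f"{eq.name}: prediction(s) outside [0, 120] years", stacklevel=2)
    return float(pred[0]) if not isinstance(params, pd.DataFrame) else pred
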