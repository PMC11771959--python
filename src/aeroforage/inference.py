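"""GLMs, rank correlations, AICc model selection and multimodel averaging.

Model fitting is delegated to statsmodels (IRLS maximum likelihood); the
small-sample information criterion, Akaike weights, the all-subsets model
table and the study's ten-prediction battery are implemented here.  The
parameter count ``k`` includes the dispersion/scale parameter for both the
Gaussian and gamma families, so an intercept + two slopes + scale model has
k = 4.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

FAMILIES = ("gaussian-identity", "gamma-log", "gamma-inverse")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); requires n > k+1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) normalized over the candidate set (sums to 1)."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _family(name: str):
    if name == "gaussian-identity":
        return sm.families.Gaussian()
    if name == "gamma-log":
        return sm.families.Gamma(link=sm.families.links.Log())
    if name == "gamma-inverse":
        return sm.families.Gamma(link=sm.families.links.InversePower())
    raise ValueError(f"unknown family {name!r}; expected one of {FAMILIES}")


@dataclass
class FitResult:
    """One fitted GLM with Wald tests and information-criterion bookkeeping."""

    response: str
    predictors: Tuple[str, ...]
    family: str
    estimates: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series          # t-distribution, df = n - n_coef (default)
    p_values_normal: pd.Series   # Wald normal reference, also reported
    loglik: float
    k: int                       # coefficients + dispersion/scale
    n: int
    aicc: float
    delta_aicc: float = float("nan")
    weight: float = float("nan")
    degenerate: bool = False  # e.g. constant response; Wald quantities undefined

    def coef(self, name: str) -> float:
        return float(self.estimates[name])

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": list(self.predictors),
            "family": self.family,
            "estimates": self.estimates.to_dict(),
            "std_errors": self.std_errors.to_dict(),
            "t_values": self.t_values.to_dict(),
            "p_values": self.p_values.to_dict(),
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "delta_aicc": self.delta_aicc,
            "weight": self.weight,
        }


def fit_glm(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    family: str = "gaussian-identity",
) -> FitResult:
    """Maximum-likelihood GLM fit with two-tailed Wald tests.

    Rows with missing response or predictors are dropped.  Gamma families
    require a strictly positive response.
    """
    cols = [response, *predictors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    d = data[cols].dropna()
    y = d[response].to_numpy(dtype=float)
    n = len(d)
    n_coef = len(predictors) + 1
    k = n_coef + 1  # + dispersion/scale
    if n <= k + 1:
        raise ValueError(f"too few observations (n={n}) for {n_coef} coefficients")
    if family.startswith("gamma") and np.any(y <= 0):
        raise ValueError(f"gamma family requires positive response {response!r}")
    X = sm.add_constant(d[list(predictors)].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("perfectly collinear design matrix")

    names = ["intercept", *predictors]
    if np.ptp(y) == 0.0:
        # constant response: slope 0, intercept at the (link-scale) constant,
        # likelihood unbounded -> flagged degenerate rather than fitted
        link = _family(family).link
        est = pd.Series(0.0, index=names)
        est["intercept"] = float(link(y[0]))
        nan = pd.Series(np.nan, index=names)
        return FitResult(
            response=response, predictors=tuple(predictors), family=family,
            estimates=est, std_errors=nan, t_values=nan, p_values=nan,
            p_values_normal=nan, loglik=float("nan"), k=k, n=n,
            aicc=float("nan"), degenerate=True,
        )
    res = sm.GLM(y, X, family=_family(family)).fit()
    est = pd.Series(res.params, index=names)
    se = pd.Series(res.bse, index=names)
    tvals = est / se
    df_resid = n - n_coef
    p_t = pd.Series(2.0 * sps.t.sf(np.abs(tvals), df_resid), index=names)
    p_z = pd.Series(2.0 * sps.norm.sf(np.abs(tvals)), index=names)
    ll = float(res.llf)
    return FitResult(
        response=response,
        predictors=tuple(predictors),
        family=family,
        estimates=est,
        std_errors=se,
        t_values=tvals,
        p_values=p_t,
        p_values_normal=p_z,
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-tailed p."""
    rho, p = sps.spearmanr(x, y, nan_policy="omit")
    return float(rho), float(p)


def select_family(values: Sequence[float]) -> Dict[str, float | str]:
    """Choose gamma vs normal for a response by maximum-likelihood AIC.

    Both candidates use two estimated parameters.  Returns the chosen family
    name plus both AICs.  Requires at least 5 positive-capable observations.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError("need at least 5 observations to select a family")
    mu, sigma = v.mean(), v.std(ddof=0)
    ll_norm = float(np.sum(sps.norm.logpdf(v, mu, sigma)))
    aic_norm = 2 * 2 - 2 * ll_norm
    if np.all(v > 0):
        shape, _, scale = sps.gamma.fit(v, floc=0)
        ll_gamma = float(np.sum(sps.gamma.logpdf(v, shape, scale=scale)))
        aic_gamma = 2 * 2 - 2 * ll_gamma
    else:
        aic_gamma = float("inf")
    return {
        "family": "gamma" if aic_gamma < aic_norm else "normal",
        "aic_gamma": aic_gamma,
        "aic_normal": aic_norm,
    }


@dataclass
class ModelAverage:
    """All-subsets AICc ranking with averaged coefficients (delta < 2 set)."""

    table: pd.DataFrame                  # one row per candidate model
    fits: List[FitResult]
    averaged: pd.Series                  # full-average coefficients
    averaged_conditional: pd.Series
    delta_threshold: float = 2.0


def all_subsets_average(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    family: str = "gaussian-identity",
    delta_threshold: float = 2.0,
    conditional: bool = False,
) -> ModelAverage:
    """Fit every predictor subset (including intercept-only), rank by AICc.

    Akaike weights are computed over *all* candidates; coefficients are
    averaged over models with delta < ``delta_threshold`` using renormalized
    weights.  The full average treats a coefficient absent from a model as 0;
    the conditional average renormalizes over models containing it.
    """
    subsets = [
        tuple(c)
        for r in range(len(predictors) + 1)
        for c in itertools.combinations(predictors, r)
    ]
    # drop rows missing any candidate column once, so all models share data
    shared = data[[response, *predictors]].dropna()
    fits = [fit_glm(shared, response, list(s), family) for s in subsets]
    aiccs = np.array([f.aicc for f in fits])
    weights = akaike_weights(aiccs)
    deltas = aiccs - aiccs.min()
    for f, d, w in zip(fits, deltas, weights):
        f.delta_aicc = float(d)
        f.weight = float(w)

    order = np.argsort(aiccs, kind="stable")
    rows = []
    for rank, i in enumerate(order, start=1):
        f = fits[i]
        row = {"rank": rank, "df": f.k, "logLik": f.loglik, "AICc": f.aicc,
               "delta": f.delta_aicc, "weight": f.weight}
        for p in predictors:
            row[p] = f.estimates.get(p, np.nan)
        row["intercept"] = f.estimates["intercept"]
        rows.append(row)
    table = pd.DataFrame(rows)

    in_set = deltas < delta_threshold
    w_set = weights[in_set] / weights[in_set].sum()
    names = ["intercept", *predictors]
    full = pd.Series(0.0, index=names)
    cond_num = pd.Series(0.0, index=names)
    cond_den = pd.Series(0.0, index=names)
    for f, w in zip(np.asarray(fits, dtype=object)[in_set], w_set):
        for name in names:
            if name in f.estimates.index:
                full[name] += w * f.estimates[name]
                cond_num[name] += w * f.estimates[name]
                cond_den[name] += w
    cond = cond_num / cond_den.replace(0.0, np.nan)
    return ModelAverage(
        table=table,
        fits=[fits[i] for i in order],
        averaged=full,
        averaged_conditional=cond,
        delta_threshold=delta_threshold,
    )


# ---------------------------------------------------------------------------
# the study's model battery
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = [
    "date",
    "motr",
    "mean_colony_distance_m",
    "max_colony_distance_m",
    "daily_route_m",
    "foraging_hr",
    "visit_freq_per_tag_hr",
    "mean_flight_speed_ms",
    "arrival_offset_min",
    "departure_offset_min",
    "interindividual_distance_m",
]


def build_day_table(metrics: pd.DataFrame, daily_motr: pd.DataFrame) -> pd.DataFrame:
    """Join behavioral metrics with daily MoTR and add lagged columns."""
    df = metrics.merge(
        daily_motr.rename(columns={"daily_motr": "motr"}), on="date", how="inner"
    ).sort_values("date", ignore_index=True)
    df["ordinal_date"] = pd.to_datetime(df["date"]).map(lambda t: t.toordinal())
    prev = df.set_index("date")
    df["motr_prev"] = [
        prev["motr"].get(d - pd.Timedelta(days=1).to_pytimedelta()) for d in df["date"]
    ]
    df["arrival_offset_prev_min"] = [
        prev["arrival_offset_min"].get(d - pd.Timedelta(days=1).to_pytimedelta())
        for d in df["date"]
    ]
    return df


def run_paper_models(day_table: pd.DataFrame) -> Dict[str, object]:
    """Fit the full ten-prediction battery on a joined day table.

    Returns a dict keyed by prediction name with FitResult values (plus the
    seasonal Spearman tuple and the visit-frequency ModelAverage).  Daily
    route and foraging duration are fitted only on days where the route
    coverage rule produced a value, mirroring the reduced sample for those
    responses.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in day_table.columns]
    if missing:
        raise ValueError(f"day table lacks required columns: {missing}")
    if len(day_table.dropna(subset=["motr"])) < 8:
        raise ValueError("too few days with joined MoTR for the model battery")

    out: Dict[str, object] = {}
    out["seasonal_trend"] = spearman(day_table["ordinal_date"], day_table["motr"])
    out["p1_mean_distance"] = fit_glm(
        day_table, "mean_colony_distance_m", ["motr"], "gamma-log"
    )
    out["p2_max_distance"] = fit_glm(
        day_table, "max_colony_distance_m", ["motr"], "gaussian-identity"
    )
    route_days = day_table.dropna(subset=["daily_route_m"])
    if len(route_days) >= 6:
        out["p3_daily_route"] = fit_glm(route_days, "daily_route_m", ["motr"], "gamma-log")
        out["p4_foraging_duration"] = fit_glm(
            route_days, "foraging_hr", ["motr"], "gaussian-identity"
        )
    out["p5_visit_frequency"] = fit_glm(
        day_table, "visit_freq_per_tag_hr", ["motr", "mean_colony_distance_m"], "gamma-log"
    )
    out["p5_model_set"] = all_subsets_average(
        day_table,
        "visit_freq_per_tag_hr",
        ["motr", "mean_colony_distance_m"],
        "gamma-log",
    )
    out["p6_flight_speed"] = fit_glm(
        day_table, "mean_flight_speed_ms", ["motr"], "gaussian-identity"
    )
    out["p7_arrival"] = fit_glm(
        day_table, "arrival_offset_min", ["motr"], "gaussian-identity"
    )
    lagged = day_table.dropna(subset=["motr_prev"])
    if len(lagged) >= 6:
        out["p8_departure_prev_motr"] = fit_glm(
            lagged, "departure_offset_min", ["motr_prev"], "gaussian-identity"
        )
    lagged_arr = day_table.dropna(subset=["arrival_offset_prev_min"])
    if len(lagged_arr) >= 6:
        out["p9a_departure_prev_arrival"] = fit_glm(
            lagged_arr, "departure_offset_min", ["arrival_offset_prev_min"],
            "gaussian-identity",
        )
    out["p9b_departure_motr"] = fit_glm(
        day_table, "departure_offset_min", ["motr"], "gaussian-identity"
    )
    out["p10_interindividual"] = fit_glm(
        day_table,
        "interindividual_distance_m",
        ["motr", "mean_colony_distance_m"],
        "gamma-log",
    )
    return out


def report_to_json(report: Dict[str, object]) -> dict:
    """Machine-readable analogue of the study's result tables."""
    out: dict = {}
    for key, val in report.items():
        if isinstance(val, FitResult):
            out[key] = val.to_dict()
        elif isinstance(val, ModelAverage):
            out[key] = {
                "table": val.table.to_dict(orient="records"),
                "averaged": val.averaged.to_dict(),
                "averaged_conditional": {
                    k: (None if not np.isfinite(v) else v)
                    for k, v in val.averaged_conditional.items()
                },
            }
        elif isinstance(val, tuple):
            out[key] = {"rho": val[0], "p": val[1]}
    return out
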