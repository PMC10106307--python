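"""Latency statistics: outlier removal, the log-latency mixed model with
per-subject opportunity-cost sensitivity slopes, apathy regressions and the
rod-fixing comparison.

The pipeline mirrors the analysis chain of the behavioural study: raw
fishing latencies are cleaned per subject and environment with a
scaled-MAD rule, log transformed, and modelled with a linear mixed model
(price + environment dummy + cumulative taps as fixed effects, all three
plus the intercept as correlated subject-level random effects, REML).
Subject-level total slopes for price and environment are the individual
measures of sensitivity to the two opportunity-cost manipulations, and are
regressed on apathy with demographic and mood covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

#: normal-consistency constant: scaled MAD = 1.4826 * median |y - median(y)|
MAD_SCALE = 1.4826

YOUNG_BAND = (18, 35)
OLDER_BAND = (36, 65)
#: internal rescaling of cumulative taps inside the LMM (optimiser
#: conditioning); reported effects are per tap.
_CUMTAPS_SCALE = 100.0


def mad_outlier_mask(latencies, k: float = 3.0) -> np.ndarray:
    """True where an observation lies more than ``k`` scaled median absolute
    deviations from the median. A constant vector flags nothing (MAD = 0
    and the inequality is strict)."""
    y = np.asarray(latencies, dtype=float)
    if y.size == 0:
        raise ValueError("empty latency vector")
    med = np.median(y)
    scaled_mad = sps.median_abs_deviation(y, scale="normal")
    return np.abs(y - med) > k * scaled_mad


def prepare_long_table(
    records: pd.DataFrame, subjects: pd.DataFrame | None = None, k: float = 3.0
) -> pd.DataFrame:
    """Analysis table: fishing taps only, boundary-straddling latencies
    dropped, scaled-MAD outliers removed per subject x environment on the
    raw latencies, then a natural-log latency column is added."""
    fish = records[
        (records["action_type"] == "fish") & (records["straddles_boundary"] == 0)
    ].copy()

    def _mask(group: pd.DataFrame) -> pd.DataFrame:
        return group[~mad_outlier_mask(group["latency_s"].to_numpy(), k=k)]

    kept = (
        fish.groupby(["participant_id", "environment"], group_keys=False, sort=False)[
            fish.columns
        ].apply(_mask)
    ).reset_index(drop=True)
    kept["log_latency"] = np.log(kept["latency_s"])
    kept["env_high"] = (kept["environment"] == "high").astype(float)
    if subjects is not None:
        kept = kept.merge(subjects, on="participant_id", how="left", validate="m:1")
    return kept


@dataclass
class LMMResult:
    fixed_effects: pd.DataFrame  # index: intercept/price/environment/cumulative_taps
    subject_slopes: pd.DataFrame  # participant_id, intercept, price_slope, environment_slope, cumulative_taps_slope
    fit_method: str  # "reml-unstructured" or "reml-diagonal"
    converged: bool
    singular: bool = False

    def fixed_effect(self, name: str) -> pd.Series:
        return self.fixed_effects.loc[name]


def fit_latency_lmm(table: pd.DataFrame) -> LMMResult:
    """REML linear mixed model of log latency on price, environment dummy
    (high = 1) and cumulative taps, with correlated subject-level random
    intercept and slopes (unstructured covariance). Falls back to a
    diagonal random-effects covariance if the unstructured fit does not
    converge. Subject slopes are total (fixed + predicted random) effects.
    """
    data = table.copy().reset_index(drop=True)
    data["cumtaps_s"] = data["cumulative_taps"] / _CUMTAPS_SCALE
    if "env_high" not in data:
        data["env_high"] = (data["environment"] == "high").astype(float)
    formula = "log_latency ~ price + env_high + cumtaps_s"
    model = smf.mixedlm(
        formula, data, groups=data["participant_id"], re_formula="~price + env_high + cumtaps_s"
    )

    fit_method = "reml-unstructured"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True, method="lbfgs", maxiter=2000)
        if not result.converged:
            free = MixedLMParams.from_components(
                fe_params=np.ones(4), cov_re=np.eye(4)
            )
            result = model.fit(reml=True, free=free, method="lbfgs", maxiter=2000)
            fit_method = "reml-diagonal"

    singular = bool(np.linalg.matrix_rank(np.asarray(result.cov_re)) < result.cov_re.shape[0])

    names = {"Intercept": "intercept", "price": "price", "env_high": "environment",
             "cumtaps_s": "cumulative_taps"}
    scale = {"Intercept": 1.0, "price": 1.0, "env_high": 1.0,
             "cumtaps_s": 1.0 / _CUMTAPS_SCALE}
    ci = result.conf_int()
    fe_rows = {}
    for raw, nice in names.items():
        s = scale[raw]
        fe_rows[nice] = {
            "estimate": result.fe_params[raw] * s,
            "se": result.bse_fe[raw] * s,
            "ci_low": ci.loc[raw, 0] * s,
            "ci_high": ci.loc[raw, 1] * s,
            "p": result.pvalues[raw],
        }
    fixed = pd.DataFrame(fe_rows).T[["estimate", "se", "ci_low", "ci_high", "p"]]

    slope_rows = []
    for pid, re in result.random_effects.items():
        slope_rows.append(
            {
                "participant_id": pid,
                "intercept": result.fe_params["Intercept"] + re.get("Group", 0.0),
                "price_slope": result.fe_params["price"] + re.get("price", 0.0),
                "environment_slope": result.fe_params["env_high"] + re.get("env_high", 0.0),
                "cumulative_taps_slope": (
                    result.fe_params["cumtaps_s"] + re.get("cumtaps_s", 0.0)
                ) / _CUMTAPS_SCALE,
            }
        )
    slopes = pd.DataFrame(slope_rows)

    return LMMResult(
        fixed_effects=fixed,
        subject_slopes=slopes,
        fit_method=fit_method,
        converged=bool(result.converged),
        singular=singular,
    )


def _band_filter(df: pd.DataFrame, age_band: str) -> pd.DataFrame:
    if age_band in ("young", "18-35"):
        lo, hi = YOUNG_BAND
    elif age_band in ("older", "36-65"):
        lo, hi = OLDER_BAND
    elif age_band == "all":
        return df
    else:
        raise ValueError(f"unknown age band {age_band!r}")
    return df[(df["age"] >= lo) & (df["age"] <= hi)]


@dataclass
class ApathyModelResult:
    outcome: str
    predictor: str
    beta: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    covariates: pd.DataFrame = field(repr=False, default=None)


def apathy_regression(
    subject_slopes: pd.DataFrame,
    subjects: pd.DataFrame,
    outcome: str = "bAMI",
    predictor: str = "price_slope",
    age_band: str = "young",
    min_n: int = 15,
) -> ApathyModelResult:
    """OLS of an apathy outcome on one sensitivity slope, controlling for
    age, gender and HADS anxiety/depression, within an age band."""
    df = subject_slopes.merge(subjects, on="participant_id", validate="1:1")
    df = _band_filter(df, age_band).copy()
    if len(df) < min_n:
        raise ValueError(f"only {len(df)} subjects in band {age_band!r} (need >= {min_n})")
    for col in (outcome, predictor):
        if np.isclose(df[col].std(ddof=0), 0.0):
            raise ValueError(f"{col} is constant in the requested band")
    df["gender_male"] = (df["gender"] == "male").astype(float)
    X = sm.add_constant(df[[predictor, "age", "gender_male", "HADS_A", "HADS_D"]])
    res = sm.OLS(df[outcome], X).fit()
    ci = res.conf_int()
    cov = pd.DataFrame(
        {"beta": res.params, "t": res.tvalues, "p": res.pvalues}
    ).drop(index=predictor)
    return ApathyModelResult(
        outcome=outcome,
        predictor=predictor,
        beta=float(res.params[predictor]),
        t=float(res.tvalues[predictor]),
        p=float(res.pvalues[predictor]),
        ci_low=float(ci.loc[predictor, 0]),
        ci_high=float(ci.loc[predictor, 1]),
        n=len(df),
        covariates=cov,
    )


@dataclass
class RodFixResult:
    t: float
    p: float
    df: int
    per_subject: pd.DataFrame  # participant_id, mean_log_latency_high/low


def rod_fix_comparison(records: pd.DataFrame) -> RodFixResult:
    """Paired t-test across subjects of mean log rod-fixing latency,
    high minus low environment; t < 0 means faster fixing under high
    opportunity cost."""
    rod = records[records["action_type"] == "rod"]
    means = (
        rod.assign(log_latency=np.log(rod["latency_s"]))
        .groupby(["participant_id", "environment"])["log_latency"]
        .mean()
        .unstack("environment")
    )
    incomplete = means.index[means.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) without rod episodes in both environments"
        )
        means = means.dropna()
    diff = means["high"] - means["low"]
    if np.isclose(diff.std(ddof=1), 0.0):
        # degenerate pairing (e.g. identical latencies): no evidence either way
        t, p = (0.0, 1.0) if np.isclose(diff.mean(), 0.0) else (np.inf * np.sign(diff.mean()), 0.0)
    else:
        t, p = sps.ttest_rel(means["high"], means["low"])
    per_subject = means.rename(
        columns={"high": "mean_log_latency_high", "low": "mean_log_latency_low"}
    ).reset_index()
    return RodFixResult(t=float(t), p=float(p), df=len(means) - 1, per_subject=per_subject)


def correlation_battery(
    fits: pd.DataFrame,
    subject_slopes: pd.DataFrame,
    subjects: pd.DataFrame,
    age_band: str = "young",
) -> pd.DataFrame:
    """Spearman correlations of bAMI with the model- and behaviour-derived
    individual measures, within an age band."""
    df = subjects.merge(subject_slopes, on="participant_id", validate="1:1")
    df = df.merge(fits, on="participant_id", validate="1:1")
    df = _band_filter(df, age_band)
    pairs = {
        "price_slope": "price_slope",
        "reward_sensitivity_hat": "reward_sensitivity_hat",
        "delta_oct": "delta_oct",
        "median_latency_highest_state": "median_latency_highest_state",
    }
    rows = []
    for name, col in pairs.items():
        sub = df[["bAMI", col]].dropna()
        if len(sub) < 10:
            raise ValueError(f"fewer than 10 complete pairs for {name}")
        rho, p = sps.spearmanr(sub["bAMI"], sub[col])
        rows.append({"measure": name, "rho": float(rho), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
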