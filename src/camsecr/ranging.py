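"""Approximate home ranges from camera locations and sex-effect models.

A subject's approximate home range (AHR) is the minimum convex polygon
(MCP) around the cameras where it was detected.  Because detection
effort, not movement, drives how many cameras an animal is seen at, the
models for sex effects on log AHR include the (log-transformed,
z-scored) number of observations and its interaction with sex:

* an ordinary linear model with a full-vs-null F-test (suited to a
  single community of individually sampled animals), and
* a random-intercept linear mixed model with group identity as the
  random effect and a full-vs-null likelihood-ratio test (suited to
  species organised in groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import chi2, f as f_dist
from shapely.geometry import MultiPoint

from .datamodel import M2_PER_KM2, ParameterError

__all__ = [
    "HomeRangeEstimate", "SexEffectModel", "mcp_area", "transform_predictors",
    "sex_effect_lm", "sex_effect_lmm",
]


@dataclass
class HomeRangeEstimate:
    subject_id: str
    hull_xy: np.ndarray      # (V, 2) hull vertices (subset of the points)
    area_km2: float
    n_points: int
    degenerate: bool

    @property
    def hull_wkt(self) -> str:
        if self.degenerate:
            return MultiPoint(self.hull_xy).wkt
        from shapely.geometry import Polygon
        return Polygon(self.hull_xy).wkt


@dataclass
class SexEffectModel:
    kind: str                 # "lm" | "lmm"
    coefficients: pd.Series
    loglik_full: float
    loglik_null: float
    statistic: float          # F or chi-square
    df: tuple
    p_value: float
    n: int
    boundary: bool = False    # random-effect variance estimated at zero


def mcp_area(points, subject_id: str = "") -> HomeRangeEstimate:
    """Minimum convex polygon around planar points (metres), area in km².

    Fewer than three distinct non-collinear points give a degenerate hull
    with zero area (flagged, not an error).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ParameterError("no points supplied")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type == "Polygon":
        xy = np.asarray(hull.exterior.coords)[:-1]
        return HomeRangeEstimate(
            subject_id=subject_id, hull_xy=xy,
            area_km2=hull.area / M2_PER_KM2, n_points=len(pts), degenerate=False,
        )
    xy = np.unique(pts, axis=0)
    return HomeRangeEstimate(
        subject_id=subject_id, hull_xy=xy, area_km2=0.0,
        n_points=len(pts), degenerate=True,
    )


def transform_predictors(obs_counts) -> np.ndarray:
    """Log-transform then z-score observation counts (mean 0, sd 1).

    Uses the sample (n-1) standard deviation.  Constant counts leave the
    z-score undefined and raise.
    """
    c = np.asarray(obs_counts, dtype=float)
    if (c < 1).any():
        raise ParameterError("observation counts must be >= 1")
    lg = np.log(c)
    sd = lg.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ParameterError("constant observation counts: z-score undefined")
    return (lg - lg.mean()) / sd


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("area_km2", "sex", "n_observations"):
        if col not in data.columns:
            raise ParameterError(f"data must have a {col!r} column")
    df = data.copy()
    if (df["area_km2"] <= 0).any():
        raise ParameterError("home-range areas must be positive for the log model")
    df["log_ahr"] = np.log(df["area_km2"])
    df["z_obs"] = transform_predictors(df["n_observations"])
    df["sex"] = df["sex"].astype("category")
    if df["sex"].nunique() < 2:
        raise ParameterError("need both sexes represented")
    return df


def sex_effect_lm(data: pd.DataFrame) -> SexEffectModel:
    """OLS of log AHR on sex, z-scored log observations and interaction,
    with a full-vs-null F-test on the two sex terms (df = 2, n - 4)."""
    df = _prepare(data)
    n = len(df)
    if n < 5:
        raise ParameterError("too few subjects for the F-test")
    full = smf.ols("log_ahr ~ sex * z_obs", data=df).fit()
    null = smf.ols("log_ahr ~ z_obs", data=df).fit()
    df1, df2 = 2, n - 4
    F = ((null.ssr - full.ssr) / df1) / (full.ssr / df2)
    p = float(f_dist.sf(F, df1, df2))
    return SexEffectModel(
        kind="lm", coefficients=full.params, loglik_full=full.llf,
        loglik_null=null.llf, statistic=float(F), df=(df1, df2),
        p_value=p, n=n,
    )


def _fit_mixed_ml(formula: str, df: pd.DataFrame):
    """ML fit of a random-intercept model, robust at the zero-variance
    boundary: optimiser fallbacks, then the OLS limit (tau^2 = 0)."""
    import warnings
    model = smf.mixedlm(formula, data=df, groups=df["group_id"])
    for method in ("lbfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, method=method, maxiter=500)
            tau2 = float(res.cov_re.iloc[0, 0])
            if np.isfinite(res.llf):
                return float(res.llf), res.params, tau2
        except (np.linalg.LinAlgError, ValueError):
            continue
    # variance pinned at zero: the mixed model degenerates to OLS
    ols = smf.ols(formula, data=df).fit()
    return float(ols.llf), ols.params, 0.0


def sex_effect_lmm(data: pd.DataFrame) -> SexEffectModel:
    """Random-intercept mixed model (group identity) fitted by ML, with a
    full-vs-null likelihood-ratio test on the sex terms (chi², df = 2)."""
    df = _prepare(data)
    if "group_id" not in df.columns:
        raise ParameterError("data must have a 'group_id' column")
    if df["group_id"].nunique() < 2:
        raise ParameterError("need at least two groups for a random intercept")
    llf_full, params, tau2 = _fit_mixed_ml("log_ahr ~ sex * z_obs", df)
    llf_null, _, _ = _fit_mixed_ml("log_ahr ~ z_obs", df)
    lrt = max(2.0 * (llf_full - llf_null), 0.0)
    p = float(chi2.sf(lrt, 2))
    return SexEffectModel(
        kind="lmm", coefficients=params, loglik_full=llf_full,
        loglik_null=llf_null, statistic=float(lrt), df=(2,),
        p_value=p, n=len(df), boundary=tau2 < 1e-8,
    )
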