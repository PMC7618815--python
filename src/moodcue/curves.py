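"""Learning-curve estimation: epoching, power-law fits, normalized slopes.

Learning is quantified by the exponent of a power law of practice fitted by
nonlinear least squares on the raw RT scale.  For across-day conditions the
abscissa is the study week (weekly mean RT over weeks 1..n); for the
within-session analysis it is the within-session repetition index (mean RT
at repetitions 1..k pooled over all sessions).  A repeated condition's slope
is normalized by subtracting the novel condition's slope on the same axis;
negative normalized slopes indicate a contextual-cueing benefit beyond
generic practice.

Exponential and linear families are fitted on the same points for
model-family comparison by mean squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .design import week_of_day
from .mood import trmssd

FAMILIES = ("power", "exponential", "linear")


def _model(family: str):
    if family == "power":
        return lambda x, a, b: a * x ** b
    if family == "exponential":
        return lambda x, a, b: a * np.exp(b * x)
    if family == "linear":
        return lambda x, a, b: a + b * x
    raise ValueError(f"unknown curve family {family!r}")


def _initial_guess(x: np.ndarray, y: np.ndarray, family: str) -> tuple[float, float]:
    """Log-transform ordinary-least-squares initialization."""
    if family == "linear":
        b, a = np.polyfit(x, y, 1)
        return float(a), float(b)
    if np.any(y <= 0):
        return float(np.mean(np.abs(y)) or 1.0), 0.0
    ly = np.log(y)
    lx = np.log(x) if family == "power" else x
    b, la = np.polyfit(lx, ly, 1)
    return float(np.exp(la)), float(b)


class LearningCurveModel(BaseEstimator, RegressorMixin):
    """Two-parameter learning-curve fit by least squares on the raw RT scale.

    Parameters
    ----------
    family : {"power", "exponential", "linear"}
        Curve family: ``y = a * x**b``, ``y = a * exp(b*x)`` or
        ``y = a + b*x``.
    ftol : float
        Relative convergence tolerance on the least-squares cost.

    Attributes
    ----------
    a_ : float
        Level parameter (ms).
    b_ : float
        Slope/exponent parameter (the "learning slope").
    mse_ : float
        Mean squared error on the raw RT scale (ms^2).
    n_points_ : int
        Number of points fitted.
    converged_ : bool
        Whether the optimiser reported convergence.
    """

    def __init__(self, family: str = "power", ftol: float = 1e-12):
        self.family = family
        self.ftol = ftol

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 3:
            raise ValueError("curve fitting requires at least 3 points")
        if self.family in ("power",) and np.any(x <= 0):
            raise ValueError("power-law abscissa must be strictly positive")
        func = _model(self.family)
        p0 = _initial_guess(x, y, self.family)
        if self.family == "linear":
            b, a = np.polyfit(x, y, 1)
            self.a_, self.b_, self.converged_ = float(a), float(b), True
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(func, x, y, p0=p0, maxfev=20000,
                                        ftol=self.ftol, xtol=self.ftol)
                self.a_, self.b_ = float(popt[0]), float(popt[1])
                self.converged_ = True
            except RuntimeError:
                self.a_, self.b_ = p0
                self.converged_ = False
        self.n_points_ = int(x.size)
        self.mse_ = float(np.mean((func(x, self.a_, self.b_) - y) ** 2))
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return _model(self.family)(x, self.a_, self.b_)


@dataclass(frozen=True)
class CurveFit:
    """Fitted learning-curve parameters of one family on one series."""

    family: str
    a: float
    b: float
    mse: float
    n_points: int
    converged: bool


def fit_curve(x, y, family: str = "power", *, ftol: float = 1e-12) -> CurveFit:
    """Functional wrapper over :class:`LearningCurveModel`."""
    m = LearningCurveModel(family=family, ftol=ftol).fit(x, y)
    return CurveFit(family, m.a_, m.b_, m.mse_, m.n_points_, m.converged_)


def select_family_by_mse(fits) -> str:
    """Family with minimal MSE; ties prefer power, then exponential, then linear."""
    by_family = {f.family: f for f in fits}
    best = min(f.mse for f in fits)
    for fam in FAMILIES:
        if fam in by_family and by_family[fam].mse <= best * (1 + 1e-12) + 1e-12:
            return fam
    raise ValueError("no fits supplied")


# ---------------------------------------------------------------------------
# Epoching and slope sets
# ---------------------------------------------------------------------------

def weekly_epoch_means(rt_trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RT per participant x condition x study week.

    Weeks are calendar-day blocks (1-7, 8-14, ...).  Weeks without trials are
    simply absent (missing epochs).
    """
    df = rt_trials.copy()
    df["week"] = week_of_day(df["calendar_day"])
    out = (df.groupby(["participant_id", "condition", "week"], observed=True)
           ["rt_ms"].agg(mean_rt="mean", n_trials="size").reset_index())
    return out


def _safe_fit(x, y, family="power"):
    try:
        fit = fit_curve(x, y, family)
        return fit if fit.converged else None
    except ValueError:
        return None


def across_day_slopes(weekly: pd.DataFrame, *, min_epochs: int = 4,
                      family: str = "power",
                      order: str = "repeated_minus_novel") -> pd.DataFrame:
    """Week-axis power-law slopes and their novel-normalized differences.

    For each participant, fits ``mean_rt = a * week**b`` separately for the
    novel, alternate and daily conditions (at least ``min_epochs`` weekly
    epochs each), then normalizes: ``normalized_daily = b_daily - b_novel``
    and likewise for the alternate condition (``order`` flips the
    subtraction).  Participants lacking a convergent novel fit get NaN
    normalized slopes and are excluded from downstream group tests.
    """
    if order not in ("repeated_minus_novel", "novel_minus_repeated"):
        raise ValueError(f"unknown normalization order {order!r}")
    sign = 1.0 if order == "repeated_minus_novel" else -1.0
    rows = []
    for pid, sub in weekly.groupby("participant_id", sort=True):
        rec = {"participant_id": pid}
        slopes = {}
        for cond in ("novel", "alternate", "daily"):
            cell = sub[sub["condition"] == cond].sort_values("week")
            fit = (_safe_fit(cell["week"], cell["mean_rt"], family)
                   if len(cell) >= min_epochs else None)
            slopes[cond] = fit.b if fit is not None else np.nan
            rec[f"b_{cond}"] = slopes[cond]
        rec["normalized_daily"] = sign * (slopes["daily"] - slopes["novel"])
        rec["normalized_alternate"] = sign * (slopes["alternate"] - slopes["novel"])
        rows.append(rec)
    return pd.DataFrame(rows)


def within_day_slopes(rt_trials: pd.DataFrame, *, family: str = "power",
                      order: str = "repeated_minus_novel") -> pd.DataFrame:
    """Repetition-axis power-law slopes pooled across sessions.

    Mean RT at each within-session repetition index (1..k) is pooled over all
    sessions per participant, separately for the within-day and novel
    conditions; a power law is fitted to each and the within-day slope is
    normalized against the novel one.
    """
    if order not in ("repeated_minus_novel", "novel_minus_repeated"):
        raise ValueError(f"unknown normalization order {order!r}")
    sign = 1.0 if order == "repeated_minus_novel" else -1.0
    sub = rt_trials[rt_trials["condition"].isin(["within_day", "novel"])]
    pooled = (sub.groupby(["participant_id", "condition", "repetition_index"],
                          observed=True)["rt_ms"].mean().reset_index())
    rows = []
    for pid, psub in pooled.groupby("participant_id", sort=True):
        rec = {"participant_id": pid}
        slopes = {}
        for cond in ("novel", "within_day"):
            cell = psub[psub["condition"] == cond].sort_values("repetition_index")
            fit = (_safe_fit(cell["repetition_index"], cell["rt_ms"], family)
                   if len(cell) >= 3 else None)
            slopes[cond] = fit.b if fit is not None else np.nan
        rec["b_novel_within"] = slopes["novel"]
        rec["b_within"] = slopes["within_day"]
        rec["normalized_within"] = sign * (slopes["within_day"] - slopes["novel"])
        rows.append(rec)
    return pd.DataFrame(rows)


def novel_rt_instability(rt_trials: pd.DataFrame, *,
                         iqr_factor: float = 3.0) -> pd.DataFrame:
    """tRMSSD of each participant's daily mean novel RT.

    Daily mean novel-condition RT is computed per calendar day and its
    instability quantified with day-unit tRMSSD.  Participants whose value
    exceeds Q3 + ``iqr_factor`` * IQR of the cohort are flagged as extreme
    outliers (reported, and excluded from group tests downstream).
    Participants with fewer than two novel days get NaN.
    """
    novel = rt_trials[rt_trials["condition"] == "novel"]
    daily = (novel.groupby(["participant_id", "calendar_day"], observed=True)
             ["rt_ms"].mean().reset_index())
    rows = []
    for pid, sub in daily.groupby("participant_id", sort=True):
        sub = sub.sort_values("calendar_day")
        value = (trmssd(sub["rt_ms"], sub["calendar_day"].astype(float))
                 if len(sub) >= 2 else np.nan)
        rows.append({"participant_id": pid, "rt_trmssd": value,
                     "n_days": len(sub)})
    out = pd.DataFrame(rows)
    vals = out["rt_trmssd"].dropna()
    if len(vals):
        q1, q3 = np.percentile(vals, [25, 75])
        thresh = q3 + iqr_factor * (q3 - q1)
        out["is_extreme_outlier"] = out["rt_trmssd"] > thresh
    else:
        out["is_extreme_outlier"] = False
    return out
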