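"""Synthetic-cohort generator: daily mood ratings and trial-level RTs.

The generator emulates the statistical structure the analysis assumes:

* **Mood.**  Each participant's daily negative/positive affect sum follows a
  latent mean-reverting first-order autoregression sampled at calendar-day
  resolution, observed only on attended session days, rounded and clipped to
  the 5-25 affect-sum scale, and partitioned into five 1-5 Likert items.
  Because rounding, clipping and day gaps distort the latent moments,
  :func:`calibrate_mood_params` moment-matches the latent mean and
  successive-difference scale against realized simulated moments.

* **Reaction times.**  Clean RT level follows a power law of practice on the
  axes the analysis fits: study week ``w`` for across-day conditions and
  within-session repetition ``k`` for the within-day/novel conditions,
  with multiplicative lognormal noise normalized to mean one so intercepts
  are interpretable as mean RT in ms.  Contamination mirrors field data:
  error trials, out-of-bounds RTs, extreme-but-plausible RT outliers,
  unrecorded (NaN-correctness) trials, and skipped sessions.

Every planted contamination event is counted in the dataset manifest so the
cleaning cascade can be audited stage by stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import CalibrationError
from .mood import NEG_ITEMS, POS_ITEMS, trmssd
from .task_schedule import StudySchedule, schedule_study

#: Default week-axis practice exponent of the novel condition.  Chosen so the
#: novel curve declines from 1362 ms in week 1 to roughly 1290 ms by week 8,
#: the observed generic practice effect.
B_PRACTICE = -0.027


@dataclass
class GroupParams:
    """Generative parameters of one participant group.

    Mood fields are *targets* on the observed scale; ``latent_*`` fields hold
    the calibrated latent parameters and fall back to the targets when
    calibration has not been run.  RT exponents live on the analysis axes:
    ``b_daily``/``b_alt`` on the week axis, ``b_within``/``b_novel_within``
    on the within-session repetition axis, ``b_prac`` the generic week-axis
    practice exponent shared by the novel and within-day conditions.
    """

    label: str
    # -- mood targets (affect-sum scale 5-25, per-day successive differences)
    mood_mean_neg: float
    mood_mean_pos: float
    delta_neg: float
    delta_pos: float
    mean_reversion: float = 0.5
    # -- RT learning structure
    rt_intercepts: dict = field(default_factory=lambda: {
        "novel": 1362.0, "alternate": 1362.0, "daily": 1362.0, "within_day": 1362.0})
    b_prac: float = B_PRACTICE
    b_daily: float = B_PRACTICE
    b_alt: float = B_PRACTICE
    b_within: float = 0.0
    b_novel_within: float = 0.0
    # -- noise and contamination
    rt_noise_sigma: float = 0.25
    error_rate: float = 0.05
    outlier_rate: float = 0.017
    oob_rate: float = 0.0012
    unrecorded_rate: float = 0.0024
    compliance: float = 0.92
    # -- calibrated latent mood parameters (filled by calibrate_mood)
    latent_mean_neg: float | None = None
    latent_delta_neg: float | None = None
    latent_mean_pos: float | None = None
    latent_delta_pos: float | None = None

    def __post_init__(self) -> None:
        for name in ("error_rate", "outlier_rate", "oob_rate",
                     "unrecorded_rate", "compliance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("mood_mean_neg", "mood_mean_pos"):
            v = getattr(self, name)
            if not 5.0 <= v <= 25.0:
                raise ValueError(f"{name}={v} outside the 5-25 affect-sum scale")
        if not 0.0 < self.mean_reversion <= 1.0:
            raise ValueError("mean_reversion must lie in (0, 1]")
        if min(self.rt_intercepts.values()) <= 0:
            raise ValueError("RT intercepts must be positive")
        if self.rt_noise_sigma < 0 or min(self.delta_neg, self.delta_pos) < 0:
            raise ValueError("scale parameters must be non-negative")

    # Affect-sum latent parameters actually used by the simulator.
    def latent_mood(self, which: str) -> tuple[float, float]:
        if which == "neg":
            mean = self.latent_mean_neg if self.latent_mean_neg is not None else self.mood_mean_neg
            delta = self.latent_delta_neg if self.latent_delta_neg is not None else self.delta_neg
        elif which == "pos":
            mean = self.latent_mean_pos if self.latent_mean_pos is not None else self.mood_mean_pos
            delta = self.latent_delta_pos if self.latent_delta_pos is not None else self.delta_pos
        else:
            raise ValueError(f"unknown affect dimension {which!r}")
        return mean, delta

    def calibrate_mood(self, seed: int = 0, **kwargs) -> "GroupParams":
        """Moment-match both affect dimensions; fills the ``latent_*`` fields."""
        for which, mean, delta in (("neg", self.mood_mean_neg, self.delta_neg),
                                   ("pos", self.mood_mean_pos, self.delta_pos)):
            cal = calibrate_mood_params(mean, delta, self.mean_reversion,
                                        compliance=self.compliance, seed=seed, **kwargs)
            setattr(self, f"latent_mean_{which}", cal["latent_mean"])
            setattr(self, f"latent_delta_{which}", cal["latent_delta"])
        return self

    @classmethod
    def high_mdq(cls) -> "GroupParams":
        """High-MDQ group: unstable, more negative mood; shallower across-day cueing."""
        return cls(label="high", mood_mean_neg=7.75, mood_mean_pos=11.74,
                   delta_neg=2.81, delta_pos=3.97,
                   b_daily=B_PRACTICE - 0.0105, b_alt=B_PRACTICE - 0.0015,
                   b_within=-0.043, compliance=0.92)

    @classmethod
    def low_mdq(cls) -> "GroupParams":
        """Low-MDQ group: stable mood; steeper across-day and within-day cueing."""
        return cls(label="low", mood_mean_neg=5.90, mood_mean_pos=11.51,
                   delta_neg=1.61, delta_pos=3.35,
                   b_daily=B_PRACTICE - 0.0195, b_alt=B_PRACTICE - 0.0105,
                   b_within=-0.054, compliance=0.94)


# ---------------------------------------------------------------------------
# Mood simulation
# ---------------------------------------------------------------------------

def scheduled_days(n_days: int, sessions_per_week: int = 5) -> np.ndarray:
    """Calendar days of the first ``n_days`` scheduled sessions (5/week pattern)."""
    idx = np.arange(n_days)
    week, weekday = np.divmod(idx, sessions_per_week)
    return 7 * week + weekday + 1


def _simulate_latent(mean: float, delta: float, mean_reversion: float,
                     n_participants: int, n_cal_days: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Latent AR(1) affect sums, one row per participant, one column per day.

    ``delta`` is the stationary standard deviation of lag-1 (daily)
    successive differences: with persistence phi = 1 - mean_reversion,
    Var(x_{t+1} - x_t) = 2 * var_st * (1 - phi) = delta**2.
    """
    phi = 1.0 - mean_reversion
    x = np.empty((n_participants, n_cal_days))
    if delta == 0.0:
        x[:] = mean
        return x
    sd_st = delta / np.sqrt(2.0 * (1.0 - phi))
    sd_eps = sd_st * np.sqrt(1.0 - phi ** 2)
    x[:, 0] = rng.normal(mean, sd_st, n_participants)
    for t in range(1, n_cal_days):
        x[:, t] = mean + phi * (x[:, t - 1] - mean) + rng.normal(0.0, sd_eps, n_participants)
    return x


def _observe_sums(latent: np.ndarray) -> np.ndarray:
    """Observed integer affect sums: clip to the 5-25 scale and round."""
    return np.rint(np.clip(latent, 5.0, 25.0)).astype(int)


def _partition_sums(sums: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split integer affect sums (5-25) into five 1-5 items preserving the sum.

    Equal shares with largest-remainder rounding, then two random unit
    transfers between items (rejected where they would leave 1-5).
    """
    sums = np.asarray(sums, dtype=int)
    n = sums.size
    q, r = np.divmod(sums, 5)
    items = q[:, None] + (np.arange(5)[None, :] < r[:, None]).astype(int)
    for _ in range(2):
        src = rng.integers(0, 5, n)
        dst = rng.integers(0, 5, n)
        take = items[np.arange(n), src]
        give = items[np.arange(n), dst]
        ok = (src != dst) & (take > 1) & (give < 5)
        items[np.arange(n)[ok], src[ok]] -= 1
        items[np.arange(n)[ok], dst[ok]] += 1
    return items


def simulate_mood_series(params: GroupParams, n_days: int = 50, seed=None, *,
                         days=None, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one participant's daily mood ratings.

    Without an explicit ``days`` vector, ratings are scheduled five days a
    week for ``n_days`` sessions and thinned independently at rate
    ``1 - compliance``.  When ``days`` is given (already-attended calendar
    days) no further thinning is applied.

    Returns a frame with ``calendar_day``, ``item_1`` .. ``item_10`` in
    administration order, and the ``pos_sum``/``neg_sum`` affect scores.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if days is None:
        cal = scheduled_days(n_days)
        keep = rng.random(cal.size) < params.compliance
        days = cal[keep]
    days = np.asarray(days, dtype=int)
    n_cal = int(days.max()) if days.size else 1

    out = {"calendar_day": days}
    sums = {}
    for which in ("neg", "pos"):
        mean, delta = params.latent_mood(which)
        latent = _simulate_latent(mean, delta, params.mean_reversion, 1, n_cal, rng)
        sums[which] = _observe_sums(latent[0, days - 1])
    items_neg = _partition_sums(sums["neg"], rng)
    items_pos = _partition_sums(sums["pos"], rng)
    neg_cols = {f"item_{i}": items_neg[:, j] for j, i in enumerate(NEG_ITEMS)}
    pos_cols = {f"item_{i}": items_pos[:, j] for j, i in enumerate(POS_ITEMS)}
    for i in range(1, 11):
        out[f"item_{i}"] = {**neg_cols, **pos_cols}[f"item_{i}"]
    out["pos_sum"] = sums["pos"]
    out["neg_sum"] = sums["neg"]
    return pd.DataFrame(out)


def calibrate_mood_params(target_mean: float, target_delta: float,
                          mean_reversion: float = 0.5, *,
                          compliance: float = 0.93, n_participants: int = 400,
                          n_weeks: int = 10, sessions_per_week: int = 5,
                          seed: int = 0, tol: float = 0.02,
                          max_iter: int = 40) -> dict:
    """Moment-match latent AR parameters to observed-scale targets.

    Iteratively simulates a large cohort under the current latent parameters
    (with the attended-day pattern the study produces), measures the realized
    cohort-mean affect mean and tRMSSD, and adjusts the latent mean
    (additively) and latent difference scale (multiplicatively) until both
    realized moments are within ``tol`` (relative) of their targets.  Common
    random numbers (a fixed internal seed) make the iteration deterministic.
    """
    if not 5.0 <= target_mean <= 25.0:
        raise CalibrationError(f"target mean {target_mean} outside the 5-25 scale")
    if target_delta < 0:
        raise CalibrationError("target delta must be non-negative")
    if target_delta == 0.0:
        return {"latent_mean": float(target_mean), "latent_delta": 0.0,
                "realized_mean": float(np.rint(np.clip(target_mean, 5, 25))),
                "realized_trmssd": 0.0, "n_iter": 0}

    n_days = n_weeks * sessions_per_week
    cal = scheduled_days(n_days, sessions_per_week)
    latent_mean, latent_delta = float(target_mean), float(target_delta)
    history = []
    for it in range(1, max_iter + 1):
        rng = np.random.default_rng(seed)  # common random numbers
        latent = _simulate_latent(latent_mean, latent_delta, mean_reversion,
                                  n_participants, int(cal.max()), rng)
        keep = rng.random((n_participants, cal.size)) < compliance
        means, instabs = [], []
        for p in range(n_participants):
            days = cal[keep[p]]
            if days.size < 2:
                continue
            sums = _observe_sums(latent[p, days - 1])
            means.append(sums.mean())
            instabs.append(trmssd(sums, days))
        realized_mean = float(np.mean(means))
        realized_tr = float(np.mean(instabs))
        history.append((latent_mean, latent_delta, realized_mean, realized_tr))
        ok_mean = abs(realized_mean - target_mean) <= tol * target_mean
        ok_tr = abs(realized_tr - target_delta) <= tol * target_delta
        if ok_mean and ok_tr:
            return {"latent_mean": latent_mean, "latent_delta": latent_delta,
                    "realized_mean": realized_mean, "realized_trmssd": realized_tr,
                    "n_iter": it}
        latent_mean += target_mean - realized_mean
        if realized_tr > 0:
            latent_delta *= target_delta / realized_tr
        if latent_delta > 40.0:
            raise CalibrationError(
                f"implied latent scale {latent_delta:.1f} infeasible on the 5-25 "
                f"scale for targets mean={target_mean}, delta={target_delta}")
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations; "
        f"last iterations: {history[-3:]}")


# ---------------------------------------------------------------------------
# RT simulation
# ---------------------------------------------------------------------------

def _clean_rt_level(params: GroupParams, condition: np.ndarray, week: np.ndarray,
                    repetition: np.ndarray) -> np.ndarray:
    a = np.array([params.rt_intercepts[c] for c in condition])
    w = week.astype(float)
    k = repetition.astype(float)
    mu = np.where(
        condition == "daily", a * w ** params.b_daily,
        np.where(condition == "alternate", a * w ** params.b_alt,
                 np.where(condition == "novel",
                          a * w ** params.b_prac * k ** params.b_novel_within,
                          a * w ** params.b_prac * k ** params.b_within)))
    return mu


def simulate_rt_trials(params: GroupParams, schedule, seed=None, *,
                       rng: np.random.Generator | None = None,
                       attended_sessions=None) -> tuple[pd.DataFrame, dict]:
    """Simulate trial-level RTs and contamination over a study schedule.

    ``schedule`` is a :class:`~moodcue.task_schedule.StudySchedule` or its
    tidy frame.  Returns the trial table plus a dict of planted-contamination
    counts (out-of-bounds RTs, extreme outliers, unrecorded trials, error
    trials) keyed by the cleaning stage that should remove them.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    df = schedule.to_frame() if isinstance(schedule, StudySchedule) else schedule.copy()

    if attended_sessions is None:
        sessions = np.sort(df["session_index"].unique())
        keep = sessions[rng.random(sessions.size) < params.compliance]
    else:
        keep = np.asarray(sorted(attended_sessions))
    df = df[df["session_index"].isin(keep)].reset_index(drop=True)
    n = len(df)

    from .design import week_of_day
    week = week_of_day(df["calendar_day"].to_numpy())
    mu = _clean_rt_level(params, df["condition"].to_numpy(), week,
                         df["repetition_index"].to_numpy())
    sigma = params.rt_noise_sigma
    if sigma > 0:
        # lognormal noise normalized to mean 1: E[exp(N(-s^2/2, s^2))] = 1
        rt = mu * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, n))
    else:
        rt = mu.copy()

    # Mutually exclusive contamination categories per trial.
    u = rng.random(n)
    is_oob = u < params.oob_rate
    is_extreme = (~is_oob) & (u < params.oob_rate + params.outlier_rate)
    is_unrec = (~is_oob) & (~is_extreme) & (
        u < params.oob_rate + params.outlier_rate + params.unrecorded_rate)
    clean_mask = ~(is_oob | is_extreme | is_unrec)

    if is_oob.any():
        v = rng.random(is_oob.sum())
        rt[is_oob] = np.where(v < 0.5, -rng.uniform(1.0, 500.0, is_oob.sum()),
                              rng.uniform(8001.0, 16000.0, is_oob.sum()))
    if is_extreme.any():
        rt[is_extreme] = rng.uniform(4500.0, 7900.0, is_extreme.sum())

    correct = np.ones(n, dtype=float)
    # error trials only among otherwise-clean trials, so each cleaning stage
    # removes exactly its own planted process
    err = clean_mask & (rng.random(n) < params.error_rate)
    correct[err] = 0.0
    correct[is_unrec] = np.nan

    out = df.copy()
    out["rt_ms"] = rt
    out["correct"] = pd.array(np.where(np.isnan(correct), None,
                                       correct.astype(bool)), dtype="boolean")
    out["recorded"] = ~is_unrec
    counts = {"planted_oob": int(is_oob.sum()),
              "planted_extreme_outliers": int(is_extreme.sum()),
              "planted_unrecorded": int(is_unrec.sum()),
              "planted_errors": int(err.sum()),
              "n_trials": n,
              "n_sessions_attended": int(len(keep))}
    return out, counts


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A full simulated cohort: trials, mood, and the provenance manifest."""

    design: StudyDesign
    trials: pd.DataFrame
    mood: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> dict:
        from pathlib import Path
        import json
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"trials": outdir / "trials.csv", "mood": outdir / "mood.csv",
                 "manifest": outdir / "manifest.json"}
        self.trials.to_csv(paths["trials"], index=False)
        self.mood.to_csv(paths["mood"], index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        return {k: str(v) for k, v in paths.items()}


def _params_record(params: GroupParams) -> dict:
    return dataclasses.asdict(params)


def simulate_cohort(design: StudyDesign, high: GroupParams, low: GroupParams,
                    n_per_group: int = 37, seed: int = 0) -> SimulatedDataset:
    """Simulate a two-group cohort with seeded per-participant schedules.

    One attendance draw per scheduled session governs both the mood rating
    and the task session of that day, so mood-task pairing reflects shared
    attendance as it does in field data.
    """
    root = np.random.SeedSequence(seed)
    trial_frames, mood_frames = [], []
    totals = {"planted_oob": 0, "planted_extreme_outliers": 0,
              "planted_unrecorded": 0, "planted_errors": 0,
              "n_trials": 0}
    # deterministic, order-stable spawning: one child per participant
    children = root.spawn(2 * n_per_group)
    idx = 0
    for params in (high, low):
        for i in range(n_per_group):
            pid = f"{params.label}-{i + 1:02d}"
            sched_ss, att_ss, mood_ss, rt_ss = children[idx].spawn(4)
            idx += 1
            schedule = schedule_study(design, sched_ss)
            att_rng = np.random.default_rng(att_ss)
            sessions = np.arange(1, design.n_sessions + 1)
            attended = sessions[att_rng.random(sessions.size) < params.compliance]
            att_days = np.array([design.calendar_day(s) for s in attended], dtype=int)

            mood = simulate_mood_series(params, days=att_days,
                                        rng=np.random.default_rng(mood_ss))
            mood.insert(0, "participant_id", pid)
            mood.insert(1, "group", params.label)
            mood_frames.append(mood)

            trials, counts = simulate_rt_trials(
                params, schedule, rng=np.random.default_rng(rt_ss),
                attended_sessions=attended)
            trials["participant_id"] = pid
            trials.insert(1, "group", params.label)
            trial_frames.append(trials)
            for k in totals:
                totals[k] += counts[k]

    trials = pd.concat(trial_frames, ignore_index=True)
    mood = pd.concat(mood_frames, ignore_index=True)
    manifest = {"seed": seed, "n_per_group": n_per_group,
                "design": dataclasses.asdict(design),
                "params": {"high": _params_record(high), "low": _params_record(low)},
                **totals}
    return SimulatedDataset(design, trials, mood, manifest)
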