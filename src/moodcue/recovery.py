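"""Parameter-recovery harness: run the full pipeline on seeded replicate
cohorts and report the recovered cohort-level quantities.

These routines drive the same code path as a real analysis — simulate,
clean, epoch, fit, summarise — and exist so that recovery of the configured
generative parameters can be measured reproducibly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import GroupParams, simulate_cohort, simulate_mood_series
from .curves import across_day_slopes, weekly_epoch_means, within_day_slopes
from .design import StudyDesign
from .mood import trmssd
from .preprocess import clean_pipeline


def _spawn_rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def mood_moment_recovery(params: GroupParams, *, n_participants: int = 37,
                         n_days: int = 50, n_replicates: int = 10,
                         seed: int = 0) -> dict:
    """Recovered cohort-mean negative-affect mean and tRMSSD.

    Simulates ``n_replicates`` cohorts of ``n_participants`` each under the
    (calibrated) group parameters and averages the per-participant daily
    negative-affect mean and day-unit tRMSSD.
    """
    means, instabs = [], []
    for rng in _spawn_rngs(seed, n_replicates):
        for _ in range(n_participants):
            df = simulate_mood_series(params, n_days=n_days, rng=rng)
            if len(df) < 2:
                continue
            means.append(df["neg_sum"].mean())
            instabs.append(trmssd(df["neg_sum"], df["calendar_day"].astype(float)))
    return {"mean_neg": float(np.mean(means)),
            "trmssd_neg": float(np.mean(instabs)),
            "n": n_participants * n_replicates}


def slope_recovery(design: StudyDesign, high: GroupParams, low: GroupParams, *,
                   n_per_group: int = 37, n_replicates: int = 10,
                   seed: int = 0) -> dict:
    """Recovered normalized learning slopes and week-1 novel RT.

    Each replicate runs the full pipeline (simulation, cleaning cascade,
    weekly epoching, power-law fits, novel-normalization) and the recovered
    quantities are averaged across replicates:

    * grand-mean normalized daily and alternate-day week-axis slopes,
    * per-group mean normalized within-day repetition-axis slope,
    * grand mean of participants' week-1 novel-condition weekly mean RT (ms).
    """
    seeds = [int(c.generate_state(1)[0] % 2**31)
             for c in np.random.SeedSequence(seed).spawn(n_replicates)]
    rows = []
    for rep_seed in seeds:
        dataset = simulate_cohort(design, high, low, n_per_group=n_per_group,
                                  seed=rep_seed)
        clean = clean_pipeline(dataset.trials, dataset.mood)
        groups = (dataset.trials.drop_duplicates("participant_id")
                  .set_index("participant_id")["group"])
        weekly = weekly_epoch_means(clean.rt_trials)
        across = across_day_slopes(weekly)
        within = within_day_slopes(clean.rt_trials)
        within["group"] = within["participant_id"].map(groups)
        week1 = weekly[(weekly["condition"] == "novel") & (weekly["week"] == 1)]
        rows.append({
            "seed": rep_seed,
            "normalized_daily": across["normalized_daily"].mean(),
            "normalized_alternate": across["normalized_alternate"].mean(),
            "normalized_within_low":
                within.loc[within["group"] == "low", "normalized_within"].mean(),
            "normalized_within_high":
                within.loc[within["group"] == "high", "normalized_within"].mean(),
            "week1_novel_rt": week1["mean_rt"].mean(),
            "n_participants": across["participant_id"].nunique()})
    reps = pd.DataFrame(rows)
    out = {col: float(reps[col].mean()) for col in reps.columns
           if col not in ("seed", "n_participants")}
    out["replicates"] = reps
    out["n"] = int(2 * n_per_group * n_replicates)
    return out


def accuracy_recovery(design: StudyDesign, *, n_per_group: int = 37,
                      error_rate: float = 0.05, seed: int = 0) -> dict:
    """Overall percent accuracy with per-trial error probability planted and
    all other contamination disabled."""
    def only_errors(params: GroupParams) -> GroupParams:
        params.error_rate = error_rate
        params.outlier_rate = 0.0
        params.oob_rate = 0.0
        params.unrecorded_rate = 0.0
        return params

    high = only_errors(GroupParams.high_mdq())
    low = only_errors(GroupParams.low_mdq())
    dataset = simulate_cohort(design, high, low, n_per_group=n_per_group,
                              seed=seed)
    clean = clean_pipeline(dataset.trials, dataset.mood)
    acc = float(clean.accuracy_trials["correct"].mean()) * 100.0
    return {"accuracy_pct": acc, "n": len(clean.accuracy_trials)}


def null_type1_rate(*, n_per_group: int = 20, n_days: int = 50,
                    n_cohorts: int = 200, alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Type-I error of the pipeline's group test under the null.

    Simulates cohorts whose two groups share identical mood parameters, runs
    the group comparison of negative-affect tRMSSD, and reports the
    rejection rate at ``alpha``.
    """
    from .stats import two_sample_t
    params = GroupParams(label="null", mood_mean_neg=7.0, mood_mean_pos=12.0,
                         delta_neg=2.0, delta_pos=2.0)
    rejections = 0
    for rng in _spawn_rngs(seed, n_cohorts):
        values, labels = [], []
        for p in range(2 * n_per_group):
            df = simulate_mood_series(params, n_days=n_days, rng=rng)
            if len(df) < 2:
                continue
            values.append(trmssd(df["neg_sum"], df["calendar_day"].astype(float)))
            labels.append("a" if p < n_per_group else "b")
        res = two_sample_t(values, labels)
        rejections += res.p < alpha
    return {"rejection_rate": rejections / n_cohorts, "n_cohorts": n_cohorts}
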