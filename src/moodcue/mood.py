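"""Affect scoring, the tRMSSD instability statistic, pairing and compliance.

Daily mood is a 10-item short-form PANAS rating: five positive and five
negative items on a 1-5 Likert scale, summed to positive/negative affect
scores each ranging 5-25.  Day-to-day instability of those scores is
quantified with the time-adjusted root mean square of successive differences

    tRMSSD = sqrt( (1/N) * sum_{i=1}^{N-1} ((x_{i+1} - x_i) / (t_{i+1} - t_i))^2 )

where the x_i are the N ratings and the t_i their timestamps in days.
Dividing each successive difference by its elapsed time keeps the statistic
from inflating when ratings are missing.  Note the divisor is N (the number
of ratings), not the conventional N-1; the ``divisor`` option exposes the
N-1 variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import week_of_day

#: PANAS-SF item names in administration order.
ITEM_NAMES = ("upset", "hostile", "alert", "ashamed", "inspired",
              "nervous", "determined", "attentive", "afraid", "active")
#: 1-based item indices contributing to the negative / positive affect sums.
NEG_ITEMS = (1, 2, 4, 6, 9)
POS_ITEMS = (3, 5, 7, 8, 10)


def trmssd(values, times, *, divisor: str = "n") -> float:
    """Time-adjusted root mean square of successive differences.

    Parameters
    ----------
    values : sequence of float
        The N observations x_i, in time order.
    times : sequence of float
        Strictly increasing timestamps t_i, in days.
    divisor : {"n", "n-1"}
        Averaging divisor.  ``"n"`` follows the statistic as used here;
        ``"n-1"`` is the conventional successive-difference normalisation.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.shape != t.shape or x.ndim != 1:
        raise ValueError("values and times must be 1-D sequences of equal length")
    n = x.size
    if n < 2:
        raise ValueError("tRMSSD requires at least two observations")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    rates = np.diff(x) / dt
    if divisor == "n":
        denom = n
    elif divisor == "n-1":
        denom = n - 1
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    return float(np.sqrt(np.sum(rates ** 2) / denom))


def affect_scores(items) -> tuple[int, int]:
    """Positive and negative affect sums of one 10-item rating.

    ``items`` are the ten responses in administration order, each in 1-5.
    Returns ``(pos_sum, neg_sum)``, each in 5-25.
    """
    arr = np.asarray(items)
    if arr.shape != (10,):
        raise ValueError("expected exactly 10 item scores")
    if np.any((arr < 1) | (arr > 5)):
        raise ValueError("item scores must lie in 1-5")
    pos = int(sum(arr[i - 1] for i in POS_ITEMS))
    neg = int(sum(arr[i - 1] for i in NEG_ITEMS))
    return pos, neg


def pair_with_task_days(mood: pd.DataFrame, trials: pd.DataFrame) -> pd.DataFrame:
    """Keep mood records only for days with same-participant task data.

    Both frames must carry ``participant_id`` and ``calendar_day`` columns.
    """
    task_days = trials[["participant_id", "calendar_day"]].drop_duplicates()
    keys = pd.MultiIndex.from_frame(task_days)
    idx = pd.MultiIndex.from_frame(mood[["participant_id", "calendar_day"]])
    return mood.loc[idx.isin(keys)].copy()


def compliance_per_week(paired_mood: pd.DataFrame, n_weeks: int = 10) -> pd.DataFrame:
    """Paired mood+task days per participant and study week.

    Weeks are calendar-day blocks 1-7, 8-14, ...; all ``n_weeks`` weeks are
    reported for every participant, with zero counts where no day is paired.
    """
    df = paired_mood[["participant_id", "calendar_day"]].drop_duplicates().copy()
    df["week"] = week_of_day(df["calendar_day"])
    counts = (df.groupby(["participant_id", "week"]).size()
              .rename("n_days").reset_index())
    participants = paired_mood["participant_id"].unique()
    full = pd.MultiIndex.from_product(
        [participants, range(1, n_weeks + 1)], names=["participant_id", "week"])
    return (counts.set_index(["participant_id", "week"])
            .reindex(full, fill_value=0).reset_index())


def group_instability_summary(mood: pd.DataFrame, *, divisor: str = "n") -> pd.DataFrame:
    """Per-participant affect means and tRMSSD instability.

    Expects a mood frame with ``participant_id``, ``calendar_day``,
    ``pos_sum`` and ``neg_sum`` (pairing and inclusion already applied).
    Participants with fewer than two ratings get NaN instability.
    """
    rows = []
    for pid, sub in mood.sort_values("calendar_day").groupby("participant_id", sort=True):
        t = sub["calendar_day"].to_numpy(dtype=float)
        rec = {"participant_id": pid, "n_ratings": len(sub),
               "mean_pos": float(sub["pos_sum"].mean()),
               "mean_neg": float(sub["neg_sum"].mean()),
               "trmssd_pos": np.nan, "trmssd_neg": np.nan}
        if len(sub) >= 2:
            rec["trmssd_pos"] = trmssd(sub["pos_sum"], t, divisor=divisor)
            rec["trmssd_neg"] = trmssd(sub["neg_sum"], t, divisor=divisor)
        if "group" in sub.columns:
            rec["group"] = sub["group"].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)
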