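"""Trial-cleaning cascade and participant-inclusion rule.

Cleaning stages, in application order:

1. **bounds** — remove RTs outside the closed interval [0, 8000] ms,
2. **unrecorded** — remove trials whose correctness was lost to a technical
   error (``recorded`` is false),
3. **errors** — on the RT-analysis branch only, remove incorrect trials
   (the accuracy analysis sees pre-error-removal data),
4. **3 SD trim** — within each participant x condition cell, remove RTs more
   than three sample standard deviations above the cell mean (one-sided,
   single pass; RT distributions are long-tailed upward).

The inclusion rule drops participants who provide paired mood+task data in
fewer than three distinct study weeks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .design import week_of_day
from .mood import pair_with_task_days

RT_LOWER_MS = 0.0
RT_UPPER_MS = 8000.0
MIN_INCLUSION_WEEKS = 3


@dataclass
class CleaningStage:
    name: str
    n_input: int
    n_removed: int

    @property
    def fraction(self) -> float:
        """Fraction removed relative to this stage's input."""
        return self.n_removed / self.n_input if self.n_input else 0.0


@dataclass
class CleaningReport:
    """Per-stage removal accounting for one cleaning run."""

    n_initial: int = 0
    stages: list = field(default_factory=list)
    excluded_participants: list = field(default_factory=list)

    def add(self, name: str, n_input: int, n_removed: int) -> None:
        self.stages.append(CleaningStage(name, n_input, n_removed))

    def stage(self, name: str) -> CleaningStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def total_removed(self) -> int:
        return sum(s.n_removed for s in self.stages)

    @property
    def total_fraction(self) -> float:
        """Total removed as a fraction of the initial trial count."""
        return self.total_removed / self.n_initial if self.n_initial else 0.0

    def to_dict(self) -> dict:
        return {"n_initial": self.n_initial,
                "stages": [{"name": s.name, "n_input": s.n_input,
                            "n_removed": s.n_removed, "fraction": s.fraction,
                            "fraction_of_initial": (s.n_removed / self.n_initial
                                                    if self.n_initial else 0.0)}
                           for s in self.stages],
                "total_removed": self.total_removed,
                "total_fraction": self.total_fraction,
                "excluded_participants": list(self.excluded_participants)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [f"initial trials: {self.n_initial}"]
        for s in self.stages:
            lines.append(f"  {s.name}: removed {s.n_removed} of {s.n_input} "
                         f"({100 * s.fraction:.2f}%)")
        lines.append(f"total removed: {self.total_removed} "
                     f"({100 * self.total_fraction:.2f}% of initial)")
        if self.excluded_participants:
            lines.append(f"excluded participants: {sorted(self.excluded_participants)}")
        return "\n".join(lines)


def filter_rt_bounds(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove RTs outside [0, 8000] ms; boundary values are retained."""
    keep = (trials["rt_ms"] >= RT_LOWER_MS) & (trials["rt_ms"] <= RT_UPPER_MS)
    return trials[keep].copy(), int((~keep).sum())


def drop_unrecorded(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove trials whose correctness was not recorded."""
    keep = trials["recorded"].astype(bool)
    return trials[keep].copy(), int((~keep).sum())


def drop_errors(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove incorrect trials (RT-analysis branch only)."""
    keep = trials["correct"].fillna(False).astype(bool)
    return trials[keep].copy(), int((~keep).sum())


def trim_outliers_3sd(trials: pd.DataFrame, *, n_sd: float = 3.0,
                      two_sided: bool = False) -> tuple[pd.DataFrame, int]:
    """Trim per participant x condition cell RTs beyond ``n_sd`` sample SDs.

    Cell mean and SD (ddof=1) are computed once on the cell as given, not
    iteratively.  The default is one-sided (upper tail only); cells with
    fewer than two trials are left untrimmed with a warning.
    """
    if trials.empty:
        return trials.copy(), 0
    g = trials.groupby(["participant_id", "condition"], observed=True)["rt_ms"]
    mean = g.transform("mean")
    sd = g.transform("std")
    size = g.transform("size")
    if (size < 2).any():
        warnings.warn("cells with fewer than 2 trials were not trimmed",
                      stacklevel=2)
    upper = trials["rt_ms"] > mean + n_sd * sd
    keep = ~upper
    if two_sided:
        keep &= ~(trials["rt_ms"] < mean - n_sd * sd)
    keep |= size < 2
    keep = keep.fillna(True)
    return trials[keep].copy(), int((~keep).sum())


def apply_inclusion(trials: pd.DataFrame, mood: pd.DataFrame, *,
                    min_weeks: int = MIN_INCLUSION_WEEKS
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Exclude participants with paired mood+task data in < ``min_weeks`` weeks.

    Returns the filtered ``(trials, mood, excluded_ids)``.
    """
    paired = pair_with_task_days(mood, trials)
    weeks = paired[["participant_id", "calendar_day"]].drop_duplicates().copy()
    weeks["week"] = week_of_day(weeks["calendar_day"])
    n_weeks = weeks.groupby("participant_id")["week"].nunique()
    all_ids = set(trials["participant_id"]) | set(mood["participant_id"])
    included = set(n_weeks[n_weeks >= min_weeks].index)
    excluded = sorted(all_ids - included)
    return (trials[trials["participant_id"].isin(included)].copy(),
            mood[mood["participant_id"].isin(included)].copy(),
            excluded)


@dataclass
class CleanResult:
    """Output of the full cleaning cascade.

    ``accuracy_trials`` is the branch for accuracy analyses (bounds and
    unrecorded filters applied, error trials retained); ``rt_trials`` is the
    RT-analysis branch (errors removed, then 3 SD trimmed).
    """

    accuracy_trials: pd.DataFrame
    rt_trials: pd.DataFrame
    mood: pd.DataFrame
    report: CleaningReport


def clean_pipeline(trials: pd.DataFrame, mood: pd.DataFrame | None = None, *,
                   min_weeks: int = MIN_INCLUSION_WEEKS,
                   two_sided_trim: bool = False) -> CleanResult:
    """Run inclusion and the full cleaning cascade with removal accounting."""
    report = CleaningReport()
    excluded: list = []
    if mood is not None:
        trials, mood, excluded = apply_inclusion(trials, mood, min_weeks=min_weeks)
        report.excluded_participants = excluded
    else:
        mood = pd.DataFrame(columns=["participant_id", "calendar_day"])

    n0 = len(trials)
    report.n_initial = n0
    trials, n_bounds = filter_rt_bounds(trials)
    report.add("bounds", n0, n_bounds)
    n1 = len(trials)
    accuracy_trials, n_unrec = drop_unrecorded(trials)
    report.add("unrecorded", n1, n_unrec)
    n2 = len(accuracy_trials)
    rt_trials, n_err = drop_errors(accuracy_trials)
    report.add("errors", n2, n_err)
    n3 = len(rt_trials)
    rt_trials, n_trim = trim_outliers_3sd(rt_trials, two_sided=two_sided_trim)
    report.add("trim_3sd", n3, n_trim)
    return CleanResult(accuracy_trials, rt_trials, mood, report)
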