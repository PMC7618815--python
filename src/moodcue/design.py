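"""Study-design description for the multi-timescale contextual-cueing protocol.

The protocol runs for ``n_weeks`` weeks with ``sessions_per_week`` testing
sessions per week.  Each session presents ``trials_per_session`` visual-search
trials split across four cueing conditions:

``novel``
    distinct configurations presented once and never repeated,
``alternate``
    configurations repeated once per session on alternating sessions
    (one set on odd sessions, another on even sessions),
``daily``
    configurations repeated once per session, every session,
``within_day``
    a single configuration repeated several times within one session and
    never shown on any other day.

Search displays place one rotated-``T`` target among rotated-``L`` distractors
on an invisible grid.  The grid geometry is parameterized here; the analysis
only consumes trial metadata, never pixel positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError

#: Cueing conditions, in canonical order.
CONDITIONS = ("novel", "alternate", "daily", "within_day")


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the longitudinal protocol.

    Defaults reproduce the 10-week, 5-sessions-per-week, 40-trial protocol
    with ten trials per cueing condition and 12-stimulus displays
    (1 target + 11 distractors) on an invisible 8 x 6 grid.
    """

    n_weeks: int = 10
    sessions_per_week: int = 5
    trials_per_session: int = 40
    novel_trials: int = 10
    alternate_trials: int = 10
    daily_trials: int = 10
    within_day_trials: int = 10
    grid_rows: int = 6
    grid_cols: int = 8
    n_distractors: int = 11
    # Presentation timing, carried as metadata only; never enters analysis.
    prestimulus_ms: int = 500
    iti_ms: int = 1000

    def __post_init__(self) -> None:
        if min(self.n_weeks, self.sessions_per_week, self.trials_per_session) < 1:
            raise ConfigurationError("study dimensions must be positive")
        if min(self.novel_trials, self.alternate_trials, self.daily_trials,
               self.within_day_trials) < 0 or self.n_distractors < 0:
            raise ConfigurationError("trial and distractor counts must be non-negative")
        total = (self.novel_trials + self.alternate_trials
                 + self.daily_trials + self.within_day_trials)
        if total != self.trials_per_session:
            raise ConfigurationError(
                f"per-condition trials sum to {total}, "
                f"expected trials_per_session={self.trials_per_session}")
        if self.n_distractors + 1 > self.grid_rows * self.grid_cols:
            raise ConfigurationError(
                "grid too small to place target and distractors on distinct cells")

    @property
    def n_sessions(self) -> int:
        return self.n_weeks * self.sessions_per_week

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def per_condition_trials(self) -> dict[str, int]:
        return {"novel": self.novel_trials, "alternate": self.alternate_trials,
                "daily": self.daily_trials, "within_day": self.within_day_trials}

    def calendar_day(self, session_index: int) -> int:
        """Map a 1-based session index to a 1-based calendar-day offset.

        Week ``w``, weekday ``d`` -> day ``7*(w-1) + d``; the remaining two
        days of each week are rest days.
        """
        if not 1 <= session_index <= self.n_sessions:
            raise ValueError(f"session_index {session_index} outside study")
        week, weekday = divmod(session_index - 1, self.sessions_per_week)
        return 7 * week + weekday + 1

    def week_of_session(self, session_index: int) -> int:
        return (session_index - 1) // self.sessions_per_week + 1


def week_of_day(calendar_day) -> "int":
    """Study week of a 1-based calendar day (weeks are day blocks 1-7, 8-14, ...)."""
    return (calendar_day - 1) // 7 + 1
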