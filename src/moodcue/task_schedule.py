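"""Generation of the multi-timescale contextual-cueing trial schedule.

Builds configuration libraries (the repeated and never-repeated search
displays), per-session 40-trial lists honouring the no-adjacent-repeat
constraint for within-day trials, and the full study schedule as a tidy
table.  Everything is a pure function of ``(design, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import ConfigurationError, SchedulingError

#: Retry cap for rejection-sampled trial orders.
MAX_SHUFFLE_ATTEMPTS = 10_000


@dataclass(frozen=True)
class StimulusDisplay:
    """One search display: a rotated-T target among rotated-L distractors.

    Cells are 0-based ``(row, col)`` grid coordinates; orientations are one of
    four right-angle rotations coded 0-3.  Distractors are stored sorted so
    that equal configurations compare and hash equal regardless of draw order.
    """

    target_cell: tuple[int, int]
    target_orientation: int
    distractors: tuple[tuple[tuple[int, int], int], ...]

    def __post_init__(self) -> None:
        cells = [self.target_cell] + [cell for cell, _ in self.distractors]
        if len(set(cells)) != len(cells):
            raise ConfigurationError("display has overlapping stimuli")

    @property
    def n_stimuli(self) -> int:
        return 1 + len(self.distractors)


def generate_display(design: StudyDesign, rng: np.random.Generator) -> StimulusDisplay:
    """Draw one display: distinct cells, orientations uniform over 4 rotations."""
    n = design.n_distractors + 1
    cells = rng.choice(design.n_cells, size=n, replace=False)
    orients = rng.integers(0, 4, size=n)
    coords = [(int(c) // design.grid_cols, int(c) % design.grid_cols) for c in cells]
    distractors = tuple(sorted(zip(coords[1:], (int(o) for o in orients[1:]))))
    return StimulusDisplay(coords[0], int(orients[0]), distractors)


@dataclass(frozen=True)
class ConfigurationLibrary:
    """All display configurations of one study, keyed by role.

    ``daily_set``, ``odd_set`` and ``even_set`` are repeated across sessions
    with target location and all distractor identities preserved; ``novel``
    holds per-session globally unique displays and ``within_day`` one unique
    display per session.  Mappings are ``config_id -> StimulusDisplay``.
    """

    daily_set: tuple[tuple[str, StimulusDisplay], ...]
    odd_set: tuple[tuple[str, StimulusDisplay], ...]
    even_set: tuple[tuple[str, StimulusDisplay], ...]
    novel: tuple[tuple[tuple[str, StimulusDisplay], ...], ...]  # [session-1][i]
    within_day: tuple[tuple[str, StimulusDisplay], ...]         # [session-1]

    def displays(self) -> dict[str, StimulusDisplay]:
        out: dict[str, StimulusDisplay] = {}
        for pair in (*self.daily_set, *self.odd_set, *self.even_set,
                     *(p for sess in self.novel for p in sess), *self.within_day):
            out[pair[0]] = pair[1]
        return out


def build_configuration_library(design: StudyDesign, seed: int) -> ConfigurationLibrary:
    """Build the full, globally duplicate-free configuration library.

    Draws are rejection-sampled against the set of displays generated so far,
    so no display identity ever serves two roles and novel displays never
    repeat anywhere in the study.
    """
    rng = np.random.default_rng(seed)
    seen: set[StimulusDisplay] = set()

    def draw_unique() -> StimulusDisplay:
        for _ in range(1000):
            disp = generate_display(design, rng)
            if disp not in seen:
                seen.add(disp)
                return disp
        raise ConfigurationError(
            "could not draw a globally unique display; grid likely too small")

    def named_set(prefix: str, n: int) -> tuple[tuple[str, StimulusDisplay], ...]:
        return tuple((f"{prefix}-{i + 1:02d}", draw_unique()) for i in range(n))

    daily = named_set("daily", design.daily_trials)
    odd = named_set("odd", design.alternate_trials)
    even = named_set("even", design.alternate_trials)
    novel = tuple(
        tuple((f"novel-s{s + 1:02d}-{i + 1:02d}", draw_unique())
              for i in range(design.novel_trials))
        for s in range(design.n_sessions))
    within = tuple((f"wd-s{s + 1:02d}", draw_unique())
                   for s in range(design.n_sessions))
    return ConfigurationLibrary(daily, odd, even, novel, within)


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled trial within a session."""

    condition: str
    config_id: str
    repetition_index: int  # occurrence 1..k for novel/within_day; week for daily/alternate


@dataclass(frozen=True)
class SessionPlan:
    """Ordered trial list of one testing session."""

    session_index: int
    calendar_day: int
    trials: tuple[TrialSlot, ...]


def schedule_session(library: ConfigurationLibrary, design: StudyDesign,
                     session_index: int, rng: np.random.Generator) -> SessionPlan:
    """Randomise one session's trial order.

    Alternate-day trials draw from the odd set on odd session indices and the
    even set on even ones.  The order is uniform over all permutations in
    which no two within-day trials are adjacent (rejection sampling).
    Repetition indices are assigned by occurrence order within the session for
    the novel and within-day conditions, and by study week for the daily and
    alternate conditions.
    """
    if not 1 <= session_index <= design.n_sessions:
        raise ValueError(f"session_index {session_index} outside study")
    alt_set = library.odd_set if session_index % 2 == 1 else library.even_set
    entries: list[tuple[str, str]] = []
    entries += [("novel", cid) for cid, _ in library.novel[session_index - 1]]
    entries += [("alternate", cid) for cid, _ in alt_set]
    entries += [("daily", cid) for cid, _ in library.daily_set]
    wd_id = library.within_day[session_index - 1][0]
    entries += [("within_day", wd_id)] * design.within_day_trials

    order = np.arange(len(entries))
    for _ in range(MAX_SHUFFLE_ATTEMPTS):
        rng.shuffle(order)
        conds = [entries[i][0] for i in order]
        if not any(a == b == "within_day" for a, b in zip(conds, conds[1:])):
            break
    else:
        raise SchedulingError(
            "no admissible trial order found: too many within-day trials "
            f"({design.within_day_trials}/{design.trials_per_session})")

    week = design.week_of_session(session_index)
    counters = {"novel": 0, "within_day": 0}
    slots = []
    for i in order:
        cond, cid = entries[i]
        if cond in counters:
            counters[cond] += 1
            rep = counters[cond]
        else:
            rep = week
        slots.append(TrialSlot(cond, cid, rep))
    return SessionPlan(session_index, design.calendar_day(session_index), tuple(slots))


@dataclass(frozen=True)
class StudySchedule:
    """Full schedule for one participant-protocol: library plus session plans."""

    design: StudyDesign
    library: ConfigurationLibrary
    sessions: tuple[SessionPlan, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tidy trial table (one row per scheduled trial)."""
        displays = self.library.displays()
        rows = []
        for plan in self.sessions:
            for t_idx, slot in enumerate(plan.trials, start=1):
                disp = displays[slot.config_id]
                rows.append((plan.session_index, plan.calendar_day, t_idx,
                             slot.condition, slot.config_id, slot.repetition_index,
                             disp.target_cell[0], disp.target_cell[1],
                             disp.target_orientation))
        df = pd.DataFrame(rows, columns=[
            "session_index", "calendar_day", "trial_index", "condition",
            "config_id", "repetition_index", "target_row", "target_col",
            "target_orient"])
        df.insert(0, "participant_id", pd.NA)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_layouts_json(self, path) -> None:
        payload = {
            cid: {"target": list(d.target_cell),
                  "target_orientation": d.target_orientation,
                  "distractors": [[*cell, orient] for cell, orient in d.distractors]}
            for cid, d in self.library.displays().items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)


def schedule_study(design: StudyDesign, seed: int) -> StudySchedule:
    """Generate the complete, seeded study schedule (pure in ``(design, seed)``)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    lib_seed, order_seed = ss.spawn(2)
    library = build_configuration_library(design, lib_seed)
    rng = np.random.default_rng(order_seed)
    sessions = tuple(schedule_session(library, design, s, rng)
                     for s in range(1, design.n_sessions + 1))
    return StudySchedule(design, library, sessions)
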