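"""Task paradigm: the temporal skeleton of the experiment.

The study design is an interleaved slow event-related paradigm: 24 trials,
each a 6-s task period followed by 24 s of rest, cycling through
word-reading (WR), pattern-viewing (PV) and finger-tapping (FT) eight times
at TR = 2.5 s, for 288 volumes in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

TASKS: tuple[str, ...] = ("WR", "PV", "FT")

#: The seven task-association categories: every non-empty subset of the
#: three tasks, ordered single tasks first, then pairs, then the triple.
CATEGORIES: tuple[tuple[str, ...], ...] = (
    ("WR",),
    ("PV",),
    ("FT",),
    ("WR", "PV"),
    ("WR", "FT"),
    ("PV", "FT"),
    ("WR", "PV", "FT"),
)


def category_name(category: Sequence[str]) -> str:
    """Canonical string form of a category, e.g. ``('WR','PV') -> 'WR_PV'``."""
    return "_".join(category)


def category_from_name(name: str) -> tuple[str, ...]:
    cat = tuple(name.split("_"))
    if cat not in CATEGORIES:
        raise ValueError(f"unknown category name {name!r}")
    return cat


@dataclass(frozen=True)
class Trial:
    """A single trial: task period onset/duration plus the task label."""

    onset_s: float
    duration_s: float
    task: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task label {self.task!r}")
        if self.duration_s <= 0:
            raise ValueError("trial duration must be positive")
        if self.onset_s < 0:
            raise ValueError("trial onset must be non-negative")


@dataclass(frozen=True)
class TaskParadigm:
    """Ordered trial list plus the sampling grid (TR and series length).

    Trials must be sorted by onset, task periods must not overlap, and
    every task period must lie inside the acquired run.
    """

    trials: tuple[Trial, ...]
    tr_s: float
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")
        total_s = self.n_timepoints * self.tr_s
        prev_end = 0.0
        for t in self.trials:
            if t.onset_s < prev_end - 1e-9:
                raise ValueError("trials must be sorted with non-overlapping task periods")
            if t.onset_s + t.duration_s > total_s + 1e-9:
                raise ValueError("trial extends beyond the acquired run")
            prev_end = t.onset_s + t.duration_s

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        return self.n_timepoints * self.tr_s

    @property
    def onsets_s(self) -> tuple[float, ...]:
        return tuple(t.onset_s for t in self.trials)

    @property
    def task_labels(self) -> tuple[str, ...]:
        return tuple(t.task for t in self.trials)

    def task_trial_indices(self, task: str) -> tuple[int, ...]:
        """0-based indices of the trials of one task."""
        if task not in TASKS:
            raise ValueError(f"unknown task label {task!r}")
        idx = tuple(i for i, t in enumerate(self.trials) if t.task == task)
        if not idx:
            raise ValueError(f"task {task!r} absent from paradigm")
        return idx


def make_default_paradigm(
    tr_s: float = 2.5,
    n_cycles: int = 8,
    task_duration_s: float = 6.0,
    trial_period_s: float = 30.0,
) -> TaskParadigm:
    """The study paradigm: 24 interleaved trials (WR, PV, FT cycled 8 times).

    Trial k starts at ``k * trial_period_s`` (a 6-s task period followed by
    24 s of rest); the run is 720 s = 288 volumes at TR 2.5 s.
    """
    trials = []
    for k in range(n_cycles * len(TASKS)):
        trials.append(
            Trial(onset_s=k * trial_period_s, duration_s=task_duration_s, task=TASKS[k % len(TASKS)])
        )
    n_timepoints = int(round(n_cycles * len(TASKS) * trial_period_s / tr_s))
    return TaskParadigm(trials=tuple(trials), tr_s=tr_s, n_timepoints=n_timepoints)


def write_events(paradigm: TaskParadigm, path: str | Path) -> None:
    """Write the trial list as a BIDS-style events TSV (onset, duration, trial_type)."""
    df = pd.DataFrame(
        {
            "onset": [t.onset_s for t in paradigm.trials],
            "duration": [t.duration_s for t in paradigm.trials],
            "trial_type": [t.task for t in paradigm.trials],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path, tr_s: float, n_timepoints: int) -> TaskParadigm:
    """Read a BIDS-style events TSV and validate it against the sampling grid."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    trials = tuple(
        Trial(onset_s=float(r.onset), duration_s=float(r.duration), task=str(r.trial_type))
        for r in df.itertuples()
    )
    return TaskParadigm(trials=trials, tr_s=tr_s, n_timepoints=n_timepoints)
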