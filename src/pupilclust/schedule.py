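"""Trial lattice of the escalating-load color-matching task.

The task is organised as ``n_blocks`` blocks, each containing
``n_levels_per_block`` difficulty levels of ``n_trials_per_level`` trials.
The default lattice is 3 x 6 x 17 = 306 trials, with deliberately wrong
("deceptive") feedback delivered in block 2, levels 3-6.  Every other signal
in the pipeline (pupil vectors, HRV segments, eye-event windows) is sliced
against this lattice, so trial indexing lives here and nowhere else.

Blocks and levels are reported 1-based, matching how psychophysiology
papers describe task structure; trial indices are 0-based half-open for
unambiguous slicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

DEFAULT_DECEPTIVE_CELLS = frozenset({(2, 3), (2, 4), (2, 5), (2, 6)})


@dataclass(frozen=True)
class TaskSchedule:
    """The block x level x trial lattice plus deceptive-feedback cells."""

    n_blocks: int = 3
    n_levels_per_block: int = 6
    n_trials_per_level: int = 17
    deceptive_cells: frozenset[tuple[int, int]] = field(default=DEFAULT_DECEPTIVE_CELLS)

    def __post_init__(self) -> None:
        for name in ("n_blocks", "n_levels_per_block", "n_trials_per_level"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        object.__setattr__(self, "deceptive_cells", frozenset(self.deceptive_cells))
        for block, level in self.deceptive_cells:
            if not (1 <= block <= self.n_blocks and 1 <= level <= self.n_levels_per_block):
                raise ValueError(
                    f"deceptive cell ({block}, {level}) outside the "
                    f"{self.n_blocks} x {self.n_levels_per_block} lattice"
                )

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.n_levels_per_block * self.n_trials_per_level

    @property
    def trials_per_block(self) -> int:
        return self.n_levels_per_block * self.n_trials_per_level

    def cell_of_trial(self, trial: int) -> tuple[int, int]:
        """Map a 0-based trial index to its 1-based (block, level) cell."""
        if not 0 <= trial < self.total_trials:
            raise IndexError(f"trial {trial} outside [0, {self.total_trials})")
        block = trial // self.trials_per_block
        level = (trial % self.trials_per_block) // self.n_trials_per_level
        return block + 1, level + 1

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial table: trial, block, level, deceptive."""
        trials = np.arange(self.total_trials)
        blocks = trials // self.trials_per_block + 1
        levels = (trials % self.trials_per_block) // self.n_trials_per_level + 1
        deceptive = deceptive_trial_mask(self)
        return pd.DataFrame(
            {"trial": trials, "block": blocks, "level": levels, "deceptive": deceptive}
        )

    def to_yaml(self, path) -> None:
        payload = {
            "n_blocks": self.n_blocks,
            "n_levels_per_block": self.n_levels_per_block,
            "n_trials_per_level": self.n_trials_per_level,
            "deceptive_cells": sorted([list(c) for c in self.deceptive_cells]),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "TaskSchedule":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cells = frozenset(tuple(c) for c in payload.pop("deceptive_cells", []))
        return cls(deceptive_cells=cells, **payload)


@dataclass(frozen=True)
class LevelWindow:
    """Half-open trial-index span of one difficulty level.

    ``block``/``level`` are 1-based; ``first_trial`` inclusive and
    ``last_trial`` exclusive, so windows tile [0, total_trials).
    """

    block: int
    level: int
    first_trial: int
    last_trial: int

    @property
    def width(self) -> int:
        return self.last_trial - self.first_trial


def build_schedule(
    n_blocks: int = 3,
    n_levels: int = 6,
    n_trials: int = 17,
    deceptive_cells=DEFAULT_DECEPTIVE_CELLS,
) -> TaskSchedule:
    """Construct a validated :class:`TaskSchedule`.

    Defaults reproduce the study task: 3 blocks x 6 levels x 17 trials
    (306 trials, 102 per block) with deceptive feedback in block 2,
    levels 3-6.
    """
    return TaskSchedule(
        n_blocks=n_blocks,
        n_levels_per_block=n_levels,
        n_trials_per_level=n_trials,
        deceptive_cells=frozenset(deceptive_cells),
    )


def level_windows(schedule: TaskSchedule) -> list[LevelWindow]:
    """All level windows in (block, level) lexicographic order."""
    windows = []
    start = 0
    for block in range(1, schedule.n_blocks + 1):
        for level in range(1, schedule.n_levels_per_block + 1):
            windows.append(
                LevelWindow(block, level, start, start + schedule.n_trials_per_level)
            )
            start += schedule.n_trials_per_level
    return windows


def deceptive_trial_mask(schedule: TaskSchedule) -> np.ndarray:
    """Boolean vector over trials, true exactly on deceptive-feedback cells."""
    mask = np.zeros(schedule.total_trials, dtype=bool)
    for win in level_windows(schedule):
        if (win.block, win.level) in schedule.deceptive_cells:
            mask[win.first_trial : win.last_trial] = True
    return mask
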