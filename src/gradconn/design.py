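"""Block-design task timing for the main (three-condition) and localiser tasks.

The main task presents three conditions — pairing objects by canonical
*colour*, pairing by *semantic* relatedness, and a non-conceptual visual
*control* — in 19-s blocks of five trials (0.8 s task cue + 3 s stimulus),
with 19-s rest periods interleaved.  The localiser alternates *coloured* and
*greyscale* stimulus blocks of 15 s (five trials of 0.5 + 2.5 s) with a 10-s
rest after every block.  Block orders are counterbalanced per run from a
seeded permutation schedule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MAIN_CONDITIONS",
    "LOCALISER_CONDITIONS",
    "TimingError",
    "Block",
    "Trial",
    "TaskDesign",
    "AcquisitionSpec",
    "build_main_task_design",
    "build_localiser_design",
]

MAIN_CONDITIONS = ("colour", "semantic", "control")
LOCALISER_CONDITIONS = ("coloured", "greyscale")


class TimingError(ValueError):
    """Raised when requested block/trial timing is internally inconsistent."""


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Trial:
    condition: str
    onset_s: float
    fixation_s: float
    stimulus_s: float

    @property
    def duration_s(self) -> float:
        return self.fixation_s + self.stimulus_s


@dataclass
class TaskDesign:
    """A tiling of a run into condition blocks and rest periods."""

    conditions: tuple[str, ...]
    blocks: list[Block]
    trials: list[Trial]
    rests: list[tuple[float, float]]  # (onset_s, duration_s)
    total_s: float

    def __post_init__(self) -> None:
        events = [(b.onset_s, b.duration_s) for b in self.blocks] + list(self.rests)
        events.sort()
        t = 0.0
        for onset, dur in events:
            if onset < t - 1e-9:
                raise TimingError(
                    f"overlapping events: segment at {onset:.3f}s starts before {t:.3f}s"
                )
            if abs(onset - t) > 1e-9:
                raise TimingError(f"gap in run tiling at {t:.3f}s")
            t = onset + dur
        if events and abs(t - self.total_s) > 1e-9:
            raise TimingError(
                f"total duration {self.total_s:.3f}s != last offset {t:.3f}s"
            )

    # ------------------------------------------------------------------
    def n_volumes(self, tr_s: float) -> int:
        """Smallest volume count n with n * TR >= total duration."""
        return int(math.ceil(self.total_s / tr_s - 1e-9))

    def condition_boxcar(
        self, condition: str | tuple[str, ...], dt: float, n_steps: int | None = None
    ) -> np.ndarray:
        """Unit boxcar of the given condition(s) sampled at t = k*dt."""
        if isinstance(condition, str):
            condition = (condition,)
        unknown = set(condition) - set(self.conditions)
        if unknown:
            raise KeyError(f"unknown condition(s): {sorted(unknown)}")
        if n_steps is None:
            n_steps = int(round(self.total_s / dt))
        t = np.arange(n_steps) * dt
        u = np.zeros(n_steps)
        for b in self.blocks:
            if b.condition in condition:
                u[(t >= b.onset_s - 1e-9) & (t < b.offset_s - 1e-9)] = 1.0
        return u

    def block_onsets(self, condition: str) -> np.ndarray:
        return np.array([b.onset_s for b in self.blocks if b.condition == condition])


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner timing/grid: TR, volume count, voxel size and grid shape."""

    tr_s: float
    n_volumes: int
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    shape: tuple[int, int, int] = (40, 48, 36)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.n_volumes < 0:
            raise ValueError("volume count must be non-negative")

    @classmethod
    def for_design(
        cls,
        design: TaskDesign,
        tr_s: float = 2.8,
        voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
        shape: tuple[int, int, int] = (40, 48, 36),
    ) -> "AcquisitionSpec":
        return cls(tr_s, design.n_volumes(tr_s), voxel_size_mm, shape)

    @property
    def volume_times(self) -> np.ndarray:
        """Mid-volume sampling times (TR/2 offset)."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr_s

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s


def _check_block_timing(
    block_s: float, trials_per_block: int, fixation_s: float, stimulus_s: float
) -> None:
    expected = trials_per_block * (fixation_s + stimulus_s)
    if abs(expected - block_s) > 1e-9:
        raise TimingError(
            f"block duration {block_s}s != {trials_per_block} trials x "
            f"({fixation_s} + {stimulus_s})s = {expected}s"
        )


def _make_trials(block: Block, trials_per_block: int, fixation_s: float, stimulus_s: float):
    step = fixation_s + stimulus_s
    return [
        Trial(block.condition, block.onset_s + i * step, fixation_s, stimulus_s)
        for i in range(trials_per_block)
    ]


def build_main_task_design(
    blocks_per_condition: int = 6,
    block_s: float = 19.0,
    rest_s: float = 19.0,
    trials_per_block: int = 5,
    fixation_s: float = 0.8,
    stimulus_s: float = 3.0,
    order_seed: int = 0,
    rest_every: int = 3,
) -> TaskDesign:
    """Three-condition main-task run: counterbalanced triples of task blocks
    with a rest block after each triple.

    The default arguments give the study run: 6 blocks x 19 s per condition
    plus six 19-s rests = 456 s.  Condition order within each triple is drawn
    from a seeded permutation schedule in which every permutation of the three
    conditions is used equally often before any repeats (Latin-square style).
    """
    _check_block_timing(block_s, trials_per_block, fixation_s, stimulus_s)
    conditions = MAIN_CONDITIONS
    if blocks_per_condition == 0:
        return TaskDesign(conditions, [], [], [], 0.0)
    if blocks_per_condition < 0:
        raise ValueError("blocks_per_condition must be >= 0")

    rng = np.random.default_rng(order_seed)
    perms = list(itertools.permutations(conditions))
    schedule: list[tuple[str, ...]] = []
    while len(schedule) < blocks_per_condition:
        schedule.extend(perms[i] for i in rng.permutation(len(perms)))
    schedule = schedule[:blocks_per_condition]

    blocks: list[Block] = []
    trials: list[Trial] = []
    rests: list[tuple[float, float]] = []
    t = 0.0
    n_since_rest = 0
    for triple in schedule:
        for cond in triple:
            b = Block(cond, t, block_s)
            blocks.append(b)
            trials.extend(_make_trials(b, trials_per_block, fixation_s, stimulus_s))
            t += block_s
            n_since_rest += 1
            if n_since_rest == rest_every:
                rests.append((t, rest_s))
                t += rest_s
                n_since_rest = 0
    return TaskDesign(conditions, blocks, trials, rests, t)


def build_localiser_design(
    blocks_per_condition: int = 10,
    block_s: float = 15.0,
    rest_s: float = 10.0,
    trials_per_block: int = 5,
    fixation_s: float = 0.5,
    stimulus_s: float = 2.5,
    order_seed: int = 0,
) -> TaskDesign:
    """Two-condition hue localiser: randomly interleaved coloured/greyscale
    blocks, each followed by a rest period (defaults: 20 x (15 + 10) s = 500 s).
    """
    _check_block_timing(block_s, trials_per_block, fixation_s, stimulus_s)
    conditions = LOCALISER_CONDITIONS
    if blocks_per_condition == 0:
        return TaskDesign(conditions, [], [], [], 0.0)
    if blocks_per_condition < 0:
        raise ValueError("blocks_per_condition must be >= 0")

    rng = np.random.default_rng(order_seed)
    labels = list(conditions) * blocks_per_condition
    order = rng.permutation(len(labels))
    blocks: list[Block] = []
    trials: list[Trial] = []
    rests: list[tuple[float, float]] = []
    t = 0.0
    for idx in order:
        b = Block(labels[idx], t, block_s)
        blocks.append(b)
        trials.extend(_make_trials(b, trials_per_block, fixation_s, stimulus_s))
        t += block_s
        rests.append((t, rest_s))
        t += rest_s
    return TaskDesign(conditions, blocks, trials, rests, t)
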