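"""Experimental design for the two-interval duration-discrimination task.

A session compares a standard interval S of fixed duration against a
comparison interval C whose duration varies trial by trial among values
symmetric about S (method of constant stimuli).  The two intervals are
separated by a silent inter-stimulus interval (ISI); one ISI per block.
Group ``SC`` presents the standard first, group ``CS`` presents the
comparison first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Group = Literal["SC", "CS"]

#: Canonical ISI levels (ms) used throughout the default design.
DEFAULT_ISIS: tuple[int, ...] = (400, 800, 1600, 2000)


class InvalidDesignError(ValueError):
    """Raised when a design specification cannot produce a valid session."""


@dataclass(frozen=True)
class Trial:
    """One two-interval forced-choice presentation.

    ``delta_sign`` is +1 when the comparison is longer than the standard
    and -1 when it is shorter; ``delta_level`` is the unsigned step in ms.
    """

    group: Group
    s_duration: float
    c_duration: float
    delta_level: float
    delta_sign: int
    isi: float
    iti: float
    block_index: int
    trial_index: int

    def __post_init__(self) -> None:
        expected = self.s_duration + self.delta_sign * self.delta_level
        if not math.isclose(self.c_duration, expected):
            raise InvalidDesignError(
                f"c_duration {self.c_duration} inconsistent with "
                f"s {self.s_duration} and step {self.delta_sign}*{self.delta_level}"
            )
        if self.c_duration <= 0:
            raise InvalidDesignError("comparison duration must be positive")

    @property
    def first_duration(self) -> float:
        return self.s_duration if self.group == "SC" else self.c_duration

    @property
    def second_duration(self) -> float:
        return self.c_duration if self.group == "SC" else self.s_duration


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one session: standard, steps, ISI blocks, block size."""

    s_duration: float = 120.0
    deltas: tuple[float, ...] = (20.0, 60.0, 100.0)
    isis: tuple[float, ...] = DEFAULT_ISIS
    trials_per_block: int = 120
    iti_range: tuple[float, float] = (1000.0, 3000.0)

    def __post_init__(self) -> None:
        n_comparisons = 2 * len(self.deltas)
        if n_comparisons and self.trials_per_block % n_comparisons:
            raise InvalidDesignError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{n_comparisons} comparison durations"
            )


def derive_comparisons(s_duration: float, deltas: Iterable[float]) -> list[float]:
    """Comparison durations ``s ± δ`` for each step δ, sorted ascending.

    Raises :class:`InvalidDesignError` if any resulting duration is
    non-positive.
    """
    deltas = sorted(set(deltas))
    out = sorted([s_duration - d for d in deltas] + [s_duration + d for d in deltas])
    if any(c <= 0 for c in out):
        raise InvalidDesignError(
            f"steps {deltas} around {s_duration} ms yield non-positive durations"
        )
    return out


def to_frames(
    duration: float,
    refresh_hz: float,
    convention: Literal["ceiling", "nearest"] = "ceiling",
) -> int:
    """Convert a duration in ms to an integer number of video frames.

    Fractional frame counts must be resolved to integers on a real
    display.  ``ceiling`` rounds any fractional part up (a stimulus is
    shown for at least its nominal duration); ``nearest`` is standard
    half-away-from-zero rounding.  At 144 Hz the six default comparisons
    map to 3, 9, 15, 21, 26 and 32 frames under the ceiling convention.
    """
    if duration <= 0 or refresh_hz <= 0:
        raise ValueError("duration and refresh rate must be positive")
    frames = duration * refresh_hz / 1000.0
    if convention == "ceiling":
        # tolerate float dust: 220*144/1000 = 31.68 -> 32, but 144.000000001 -> 144
        if math.isclose(frames, round(frames), abs_tol=1e-9):
            return int(round(frames))
        return math.ceil(frames)
    if convention == "nearest":
        return int(math.floor(frames + 0.5))
    raise ValueError(f"unknown rounding convention {convention!r}")


def label_longer_first(trial: Trial) -> bool:
    """True iff the physically longer interval occupies first position."""
    if trial.s_duration == trial.c_duration:
        raise ValueError("ordinal-position label undefined for equal durations")
    longer_is_c = trial.c_duration > trial.s_duration
    c_is_first = trial.group == "CS"
    return longer_is_c == c_is_first


def build_design(
    spec: DesignSpec, group: Group, rng: np.random.Generator
) -> list[Trial]:
    """Build one session: one block per ISI, blocks in seeded-random order.

    Within a block every comparison duration appears exactly
    ``trials_per_block / (2·|deltas|)`` times, shuffled.  Inter-trial
    intervals are drawn uniformly from ``spec.iti_range``.  The generator
    is consumed in a fixed order (block permutation, then per block the
    within-block shuffle, then the block's ITIs), so equal seeds give
    identical sessions.
    """
    if group not in ("SC", "CS"):
        raise InvalidDesignError(f"unknown group {group!r}")
    comparisons = derive_comparisons(spec.s_duration, spec.deltas)
    if not comparisons:
        return []
    reps = spec.trials_per_block // len(comparisons)
    block_order = rng.permutation(len(spec.isis))
    trials: list[Trial] = []
    for block_index, isi_idx in enumerate(block_order):
        isi = spec.isis[isi_idx]
        block_cs = np.repeat(comparisons, reps)
        rng.shuffle(block_cs)
        itis = rng.uniform(*spec.iti_range, size=len(block_cs))
        for trial_index, (c, iti) in enumerate(zip(block_cs, itis)):
            delta = c - spec.s_duration
            trials.append(
                Trial(
                    group=group,
                    s_duration=spec.s_duration,
                    c_duration=float(c),
                    delta_level=abs(delta),
                    delta_sign=1 if delta > 0 else -1,
                    isi=float(isi),
                    iti=float(iti),
                    block_index=block_index,
                    trial_index=trial_index,
                )
            )
    return trials


def design_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Long-format table of a trial list (one row per trial)."""
    return pd.DataFrame(
        {
            "group": [t.group for t in trials],
            "block_index": [t.block_index for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "isi_ms": [t.isi for t in trials],
            "s_ms": [t.s_duration for t in trials],
            "c_ms": [t.c_duration for t in trials],
            "delta_level": [t.delta_level for t in trials],
            "delta_sign": ["+" if t.delta_sign > 0 else "-" for t in trials],
            "iti_ms": [t.iti for t in trials],
        }
    )


def write_design_csv(trials: Sequence[Trial], path) -> None:
    design_to_frame(trials).to_csv(path, index=False)
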