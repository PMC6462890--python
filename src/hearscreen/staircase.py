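"""Threshold-estimation staircases used for calibration.

Implements the ascending-method calibration chain: a coarse ascending
pre-scan locates the lowest level a subject responds to, then a fine
transformed up-down staircase (2-down-1-up, 1 dB steps) starting 10 dB
below that level tracks the threshold and terminates after a fixed number
of reversals. The 2-down-1-up rule converges to the level where
P(heard) = 2^(-1/2) ~ 70.7%; the threshold estimate is the mean of the
reversal levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .errors import ConfigError

Responder = Callable[[float], bool]


@dataclass(frozen=True)
class StaircaseConfig:
    """2-down-1-up staircase parameters.

    ``initial_offset_db`` positions the start relative to a predetermined
    lowest-response level (default 10 dB below it). ``floor_db`` /
    ``ceiling_db`` clamp the track; hitting a bound with no way to converge
    flags the run as non-converged at ``max_trials``.
    """

    step_db: float = 1.0
    initial_offset_db: float = -10.0
    n_reversals: int = 3
    max_trials: int = 400
    floor_db: Optional[float] = None
    ceiling_db: Optional[float] = None

    def __post_init__(self):
        if self.step_db <= 0:
            raise ConfigError("step_db must be positive")
        if self.n_reversals < 1:
            raise ConfigError("n_reversals must be >= 1")
        if self.max_trials < 1:
            raise ConfigError("max_trials must be >= 1")


@dataclass(frozen=True)
class StaircaseRun:
    """Trial-by-trial record of one staircase.

    ``estimate_db`` is the mean of the reversal levels (NaN if the run
    produced none); ``converged`` is False when the trial cap was hit
    before the required reversal count.
    """

    trials: Tuple[Tuple[float, bool], ...]
    reversal_levels: Tuple[float, ...]
    estimate_db: float
    converged: bool

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def run_staircase(
    responder: Responder,
    start_level_db: float,
    config: Optional[StaircaseConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> StaircaseRun:
    """Track a threshold with a 2-down-1-up staircase.

    The level drops one step after two consecutive heard responses since
    the last level change and rises one step after every miss. A reversal
    is a trial at which the direction of the level change flips; the run
    terminates once ``config.n_reversals`` reversals are recorded (or at
    ``max_trials``, flagged non-converged). *rng* is unused by the rule
    itself and accepted only so stochastic responders can share a seeding
    convention with the rest of the package.
    """
    config = StaircaseConfig() if config is None else config
    level = float(start_level_db)
    trials: List[Tuple[float, bool]] = []
    reversals: List[float] = []
    consecutive_heard = 0
    last_direction = 0  # -1 down, +1 up, 0 no move yet

    for _ in range(config.max_trials):
        heard = bool(responder(level))
        trials.append((level, heard))

        if heard:
            consecutive_heard += 1
            if consecutive_heard < 2:
                continue  # stay at this level, await a second heard
            direction = -1
        else:
            direction = +1
        consecutive_heard = 0

        if last_direction != 0 and direction != last_direction:
            reversals.append(level)
            if len(reversals) >= config.n_reversals:
                break
        last_direction = direction

        level += direction * config.step_db
        if config.floor_db is not None:
            level = max(level, config.floor_db)
        if config.ceiling_db is not None:
            level = min(level, config.ceiling_db)

    converged = len(reversals) >= config.n_reversals
    estimate = float(np.mean(reversals)) if reversals else float("nan")
    return StaircaseRun(
        trials=tuple(trials),
        reversal_levels=tuple(reversals),
        estimate_db=estimate,
        converged=converged,
    )


def ascending_prescan(
    responder: Responder,
    start_level_db: float,
    step_db: float = 5.0,
    ceiling_db: float = 120.0,
) -> Optional[float]:
    """Coarse ascending pass locating the lowest level with a response.

    Ascends in ``step_db`` increments from *start_level_db* and returns the
    first level the responder reports hearing, or None if the ceiling is
    reached without a response. Stands in for the conventional-audiometer
    determination of the lowest subject response level.
    """
    if step_db <= 0:
        raise ConfigError("step_db must be positive")
    level = float(start_level_db)
    while level <= ceiling_db:
        if responder(level):
            return level
        level += step_db
    return None


def calibration_threshold(
    responder: Responder,
    lowest_response_level_db: float,
    config: Optional[StaircaseConfig] = None,
) -> StaircaseRun:
    """Fine staircase seeded by a known lowest-response level.

    Starts ``config.initial_offset_db`` (default -10 dB) relative to the
    predetermined lowest-response level and runs the 2-down-1-up track.
    """
    config = StaircaseConfig() if config is None else config
    return run_staircase(
        responder, lowest_response_level_db + config.initial_offset_db, config
    )
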