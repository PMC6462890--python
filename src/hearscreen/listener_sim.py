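"""Simulated listeners and cohorts.

A :class:`SimulatedListener` answers heard/not-heard queries through a
psychometric function: P(heard) rises from the guess rate far below the
true threshold to 1 - lapse rate far above it, with a logistic transition
of spread ``slope_db``; a spread of 0 degenerates to the idealized step
listener (heard iff level >= threshold, closed at equality).

Listeners carry two kinds of level information that deliberately differ:

* ``thresholds_db_hl`` — per-frequency thresholds in the *app domain*, the
  levels the screening device actually produces at the eardrum; these drive
  the simulated responses.
* ``booth_pta_db`` — the reference pure-tone average measured in a
  sound-treated booth with clinical equipment; this is the label against
  which screening sensitivity/specificity are scored (impairment is
  PTA > 25 dB).

The validation-study cohort is reconstructed from its published per-scale
group summary: 170 ears distributed 16/58/59/27/8 over scales S_1..S_5 with
normal booth PTAs, plus one ear at S_7 (booth PTA 31 dB) and one at S_8
(36 dB). Each fixture listener gets flat app-domain thresholds equal to its
group's 1000 Hz scale level, which pins its minimum audible scale to the
group's scale exactly, and its group's mean booth PTA as reference label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, DomainError
from .protocols import ScaleTable

#: Booth pure-tone averages above this value define reference impairment.
IMPAIRMENT_PTA_DB = 25.0


@dataclass(frozen=True)
class SimulatedListener:
    thresholds_db_hl: Mapping[int, float]
    slope_db: float = 0.0
    guess_rate: float = 0.0
    lapse_rate: float = 0.0
    booth_pta_db: float = float("nan")
    ear: str = "unspecified"

    def __post_init__(self):
        if self.slope_db < 0:
            raise ConfigError("slope_db must be >= 0")
        if not (0 <= self.guess_rate and 0 <= self.lapse_rate
                and self.guess_rate + self.lapse_rate < 1):
            raise ConfigError("need 0 <= guess_rate + lapse_rate < 1")

    @property
    def impaired(self) -> bool:
        """Reference impairment label: booth PTA strictly above 25 dB."""
        return self.booth_pta_db > IMPAIRMENT_PTA_DB

    def responder(
        self, rng: Optional[np.random.Generator] = None
    ) -> Callable[[int, float], bool]:
        """Bind this listener (and a response rng) into a response callback."""
        return lambda f, level: respond(self, f, level, rng)


def respond(
    listener: SimulatedListener,
    frequency_hz: int,
    level_db_hl: float,
    rng: Optional[np.random.Generator] = None,
) -> bool:
    """One heard/not-heard decision from the psychometric model.

    P(heard) = guess + (1 - guess - lapse) * F((level - threshold) / slope)
    with logistic F; slope 0 gives the step F = 1[level >= threshold]. The
    rng is consumed only when the probability is strictly between 0 and 1,
    so the deterministic step listener draws no randomness.
    """
    f = int(frequency_hz)
    if f not in listener.thresholds_db_hl:
        raise DomainError(
            f"listener has no threshold at {f} Hz "
            f"(have {sorted(listener.thresholds_db_hl)})"
        )
    thr = float(listener.thresholds_db_hl[f])
    if listener.slope_db == 0:
        core = 1.0 if level_db_hl >= thr else 0.0
    else:
        core = 1.0 / (1.0 + math.exp(-(level_db_hl - thr) / listener.slope_db))
    p = listener.guess_rate + (1.0 - listener.guess_rate - listener.lapse_rate) * core
    if p <= 0.0:
        return False
    if p >= 1.0:
        return True
    rng = np.random.default_rng() if rng is None else rng
    return bool(rng.random() < p)


@dataclass(frozen=True)
class CohortGroup:
    """One per-scale row of a cohort summary: n ears at a given scale with
    the stated mean (SD) booth PTA."""

    scale: int
    n: int
    mean_booth_pta_db: float
    sd_booth_pta_db: float = float("nan")
    ear: str = "both"

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError("group count must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    groups: Tuple[CohortGroup, ...]
    total: Optional[int] = None

    def __post_init__(self):
        if self.total is not None and sum(g.n for g in self.groups) != self.total:
            raise ConfigError(
                f"group counts sum to {sum(g.n for g in self.groups)}, "
                f"declared total is {self.total}"
            )

    @property
    def size(self) -> int:
        return sum(g.n for g in self.groups)


# Published per-scale summaries of the 170-ear validation cohort:
# (scale, n, mean booth PTA dB, SD dB). SD is NaN for single-ear groups.
_STUDY_ROWS = {
    "pooled": (
        (1, 16, 5.0, 2.9), (2, 58, 7.0, 3.0), (3, 59, 9.0, 2.8),
        (4, 27, 11.0, 3.8), (5, 8, 12.0, 3.6),
        (7, 1, 31.0, float("nan")), (8, 1, 36.0, float("nan")),
    ),
    "left": (
        (1, 11, 4.0, 3.14), (2, 32, 7.0, 2.7), (3, 28, 8.0, 2.9),
        (4, 9, 11.0, 4.2), (5, 4, 14.0, 4.3),
        (7, 1, 31.0, float("nan")),
    ),
    "right": (
        (1, 5, 6.0, 2.1), (2, 26, 7.0, 3.3), (3, 31, 10.0, 2.6),
        (4, 18, 11.0, 3.8), (5, 4, 11.0, 2.6),
        (8, 1, 36.0, float("nan")),
    ),
}


def study_cohort_spec(ears: str = "pooled") -> CohortSpec:
    """The validation-study cohort summary (170 ears pooled, or one side).

    ``ears`` is ``"pooled"`` (both ears, N=170), ``"left"`` (85) or
    ``"right"`` (85).
    """
    if ears not in _STUDY_ROWS:
        raise KeyError(f"unknown cohort {ears!r}; available: pooled, left, right")
    label = "both" if ears == "pooled" else ears
    groups = tuple(
        CohortGroup(scale=s, n=n, mean_booth_pta_db=m, sd_booth_pta_db=sd, ear=label)
        for s, n, m, sd in _STUDY_ROWS[ears]
    )
    return CohortSpec(groups=groups, total=sum(g.n for g in groups))


def cohort_from_groups(
    spec: CohortSpec, table: Optional[ScaleTable] = None
) -> List[SimulatedListener]:
    """Deterministic listeners realizing a per-scale cohort summary.

    Each listener in a group at scale s gets flat app-domain thresholds
    equal to the 1000 Hz level of scale s — which guarantees the minimum
    audible scale is exactly s, because the 500 Hz offset only adds
    headroom — and the group's mean booth PTA as its reference label.
    """
    table = ScaleTable() if table is None else table
    listeners: List[SimulatedListener] = []
    for g in spec.groups:
        if not 1 <= g.scale <= table.max_scale:
            raise DomainError(
                f"group scale S_{g.scale} outside the table (max S_{table.max_scale})"
            )
        thr = table.level(1000, g.scale)
        for _ in range(g.n):
            listeners.append(
                SimulatedListener(
                    thresholds_db_hl={f: thr for f in table.frequencies_hz},
                    slope_db=0.0,
                    booth_pta_db=g.mean_booth_pta_db,
                    ear=g.ear,
                )
            )
    return listeners


@dataclass(frozen=True)
class ThresholdModel:
    """Distribution parameters for randomly sampled cohorts.

    Booth PTAs are drawn from a normal-hearing component (mean 8, SD 5 dB)
    or an impaired component (mean 40, SD 10 dB), resampled until they land
    on the correct side of the 25 dB impairment boundary; per-frequency
    thresholds jitter around the PTA with SD ``freq_jitter_sd_db``.
    """

    normal_pta_mean_db: float = 8.0
    normal_pta_sd_db: float = 5.0
    impaired_pta_mean_db: float = 40.0
    impaired_pta_sd_db: float = 10.0
    freq_jitter_sd_db: float = 3.0
    slope_db: float = 0.0
    guess_rate: float = 0.0
    lapse_rate: float = 0.0


def sample_cohort(
    n: int,
    prevalence: float,
    threshold_model: Optional[ThresholdModel] = None,
    rng: Optional[np.random.Generator] = None,
    table: Optional[ScaleTable] = None,
) -> List[SimulatedListener]:
    """Randomly sampled cohort with a given impairment prevalence.

    Each listener's impairment status is an independent Bernoulli draw;
    impaired listeners get booth PTA > 25 dB, normal listeners <= 25 dB,
    and per-frequency app-domain thresholds scattered around the PTA.
    Reproducible under a seeded *rng*.
    """
    if not 0 <= prevalence <= 1:
        raise ConfigError(f"prevalence {prevalence!r} outside [0, 1]")
    if n < 0:
        raise ConfigError("n must be non-negative")
    model = ThresholdModel() if threshold_model is None else threshold_model
    rng = np.random.default_rng() if rng is None else rng
    table = ScaleTable() if table is None else table

    out: List[SimulatedListener] = []
    for _ in range(n):
        impaired = bool(rng.random() < prevalence)
        if impaired:
            pta = float(rng.normal(model.impaired_pta_mean_db, model.impaired_pta_sd_db))
            while pta <= IMPAIRMENT_PTA_DB:
                pta = float(
                    rng.normal(model.impaired_pta_mean_db, model.impaired_pta_sd_db)
                )
        else:
            pta = float(rng.normal(model.normal_pta_mean_db, model.normal_pta_sd_db))
            while pta > IMPAIRMENT_PTA_DB:
                pta = float(
                    rng.normal(model.normal_pta_mean_db, model.normal_pta_sd_db)
                )
        thresholds = {
            f: pta + float(rng.normal(0.0, model.freq_jitter_sd_db))
            for f in table.frequencies_hz
        }
        out.append(
            SimulatedListener(
                thresholds_db_hl=thresholds,
                slope_db=model.slope_db,
                guess_rate=model.guess_rate,
                lapse_rate=model.lapse_rate,
                booth_pta_db=pta,
            )
        )
    return out
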