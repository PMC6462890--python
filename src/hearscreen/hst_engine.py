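"""Adaptive hearing-scale screening engine.

The engine runs the stratified-scale state machine: it starts at the
mid-ladder scale S_5 (25 dB at 500 Hz, 20 dB at the other tones), presents
the four test tones in a fixed order (1000, 2000, 4000, 500 Hz), and

* if every tone at the current scale is heard, descends one scale at a time
  until it reaches a scale with a miss (or the bottom of the ladder),
  returning the last fully heard scale;
* if the start scale has a miss, ascends one scale at a time until a fully
  heard scale, returning it;
* if the top scale still has a miss, returns the no-response outcome NR.

For a deterministic listener (heard iff level >= threshold) the assigned
scale equals the minimum audible scale — the smallest scale whose levels
meet or exceed the listener's threshold at every frequency — which
:func:`minimum_audible_scale_oracle` computes by exhaustion and the test
suite uses as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np

from .errors import ConfigError, DomainError
from .protocols import (
    DEFAULT_TONE_ORDER,
    ResponseCallback,
    ScaleTable,
    classify_scale,
)
from .results import NR, Presentation, ScaleOrNR, ScreeningResult, is_nr


@dataclass(frozen=True)
class EngineConfig:
    """Tunable parameters of the adaptive scale search.

    ``abort_scale_on_first_miss`` skips the remaining tones of a scale once
    one is missed (the outcome at that scale is already decided); strict
    mode presents all four for log fidelity. Timing parameters control the
    simulated session clock only.
    """

    start_scale: int = 5
    tone_order: Tuple[int, ...] = DEFAULT_TONE_ORDER
    abort_scale_on_first_miss: bool = True
    pass_cutoff: int = 5
    tone_duration_s: float = 1.5
    isi_bounds_s: Tuple[float, float] = (2.0, 3.0)

    def __post_init__(self):
        lo, hi = self.isi_bounds_s
        if lo < 0 or hi < lo:
            raise ConfigError(f"invalid ISI bounds {self.isi_bounds_s!r}")
        if self.tone_duration_s <= 0:
            raise ConfigError("tone_duration_s must be positive")


@dataclass(frozen=True)
class RetestAgreement:
    """Exact-scale agreement between a test and retest run.

    The scale difference ranks NR as ``max_scale + 1`` so that two NR runs
    agree with difference 0 and an NR-vs-scale pair has a defined gap.
    """

    exact_match: bool
    scale_difference: int
    first: ScaleOrNR
    second: ScaleOrNR


def _validate(table: ScaleTable, config: EngineConfig) -> None:
    if not 1 <= config.start_scale <= table.max_scale:
        raise ConfigError(
            f"start_scale {config.start_scale} outside 1..{table.max_scale}"
        )
    if sorted(config.tone_order) != sorted(table.frequencies_hz):
        raise ConfigError(
            f"tone_order {config.tone_order} is not a permutation of the "
            f"table frequencies {table.frequencies_hz}"
        )


def run_hst(
    responder: ResponseCallback,
    table: Optional[ScaleTable] = None,
    config: Optional[EngineConfig] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    ear: str = "unspecified",
) -> ScreeningResult:
    """Run the adaptive scale search on one ear.

    *responder* answers heard/not-heard for a ``(frequency_hz, level_db_hl)``
    query; *rng* drives only the randomized inter-stimulus intervals of the
    logged session clock. Returns a :class:`ScreeningResult` whose
    ``assigned_scale`` is the minimum audible scale or :data:`NR` and whose
    classification follows the scale-to-pass/fail rule.
    """
    table = ScaleTable() if table is None else table
    config = EngineConfig() if config is None else config
    _validate(table, config)
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = config.isi_bounds_s

    presentations = []
    clock = [0.0]

    def present_scale(s: int) -> bool:
        all_heard = True
        for f in config.tone_order:
            level = table.level(f, s)
            try:
                heard = bool(responder(f, level))
            except Exception as exc:
                exc.add_note(
                    f"while presenting {f} Hz at {level} dB HL (scale S_{s})"
                )
                raise
            isi = float(rng.uniform(lo, hi))
            presentations.append(Presentation(f, level, s, heard, clock[0], isi))
            clock[0] += config.tone_duration_s + isi
            if not heard:
                all_heard = False
                if config.abort_scale_on_first_miss:
                    break
        return all_heard

    assigned: ScaleOrNR
    s = config.start_scale
    if present_scale(s):
        # Descend whole scales until one is not fully heard.
        last_heard = s
        while last_heard > 1 and present_scale(last_heard - 1):
            last_heard -= 1
        assigned = last_heard
    else:
        # Ascend until a fully heard scale; NR past the top of the ladder.
        assigned = NR
        while s < table.max_scale:
            s += 1
            if present_scale(s):
                assigned = s
                break

    return ScreeningResult(
        assigned_scale=assigned,
        classification=classify_scale(assigned, config.pass_cutoff, table.max_scale),
        presentations=tuple(presentations),
        n_procedures=1,
        ear=ear,
    )


def minimum_audible_scale_oracle(
    thresholds_db_hl: Mapping[int, float], table: Optional[ScaleTable] = None
) -> ScaleOrNR:
    """Brute-force minimum audible scale for a deterministic listener.

    Exhaustively returns the smallest scale whose level meets or exceeds the
    listener's threshold at every table frequency (closed at equality), or
    :data:`NR` if no scale does. Independent of the adaptive engine; used to
    cross-check it.
    """
    table = ScaleTable() if table is None else table
    missing = [f for f in table.frequencies_hz if f not in thresholds_db_hl]
    if missing:
        raise DomainError(f"thresholds missing frequencies {missing}")
    for s in table.scales():
        if all(
            table.level(f, s) >= thresholds_db_hl[f] for f in table.frequencies_hz
        ):
            return s
    return NR


def test_retest(
    responder: ResponseCallback,
    table: Optional[ScaleTable] = None,
    config: Optional[EngineConfig] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    ear: str = "unspecified",
) -> Tuple[ScreeningResult, ScreeningResult, RetestAgreement]:
    """Run the scale search twice (test and retest) and score agreement."""
    table = ScaleTable() if table is None else table
    rng = np.random.default_rng() if rng is None else rng
    first = run_hst(responder, table, config, rng, ear=ear)
    second = run_hst(responder, table, config, rng, ear=ear)

    def rank(x: ScaleOrNR) -> int:
        return table.max_scale + 1 if is_nr(x) else int(x)

    diff = rank(first.assigned_scale) - rank(second.assigned_scale)
    agreement = RetestAgreement(
        exact_match=(diff == 0),
        scale_difference=diff,
        first=first.assigned_scale,
        second=second.assigned_scale,
    )
    return first, second, agreement


def estimate_session_duration(
    result: ScreeningResult,
    tone_duration_s: float = 1.5,
    isi_bounds_s: Tuple[float, float] = (2.0, 3.0),
) -> float:
    """Total session time in seconds: per-presentation tone + silent interval.

    Uses the realized inter-stimulus intervals recorded in the presentation
    log; a log without them (e.g. reconstructed from a summary) falls back
    to the midpoint of *isi_bounds_s*.
    """
    mid = 0.5 * (isi_bounds_s[0] + isi_bounds_s[1])
    total = 0.0
    for p in result.presentations:
        isi = p.isi_s if p.isi_s is not None and not np.isnan(p.isi_s) else mid
        total += tone_duration_s + isi
    return total
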