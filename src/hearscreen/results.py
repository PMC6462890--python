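"""Screening outcome containers.

A screening run — adaptive scale search or fixed-level protocol — produces a
:class:`ScreeningResult`: the assigned hearing scale (or the no-response
sentinel :data:`NR`), the dichotomous pass/fail classification, and the full
presentation log with realized stimulus timing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union


class _NoResponse:
    """Sentinel for a screening run that never reached a fully heard scale.

    A single instance, :data:`NR`, is used everywhere; it compares unequal
    to every scale index and serializes as the string ``"NR"``.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NR"

    def __reduce__(self):
        return (_NoResponse, ())


#: No-response outcome: the highest scale was not fully heard.
NR = _NoResponse()

ScaleOrNR = Union[int, _NoResponse]


def is_nr(value: object) -> bool:
    """True if *value* denotes the no-response outcome (sentinel or "NR")."""
    return value is NR or (isinstance(value, str) and value.upper() == "NR")


class ScreenClass(enum.Enum):
    """Dichotomous screening outcome for one ear."""

    PASS = "pass"
    FAIL = "fail"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Presentation:
    """One tone presentation and the listener's response.

    ``scale`` is the hearing-scale index for adaptive runs and ``None`` for
    fixed-level protocols. ``isi_s`` is the realized silent interval that
    followed this tone, so summing ``tone duration + isi_s`` over the log
    reproduces the session duration exactly.
    """

    frequency_hz: int
    level_db_hl: float
    scale: Optional[int]
    heard: bool
    onset_s: float
    isi_s: float
    procedure: int = 1


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of screening one ear.

    Invariants (established by the engines, asserted in tests):

    * ``assigned_scale`` is a valid scale index, :data:`NR`, or ``None``
      (fixed-level protocols assign no scale);
    * ``classification`` agrees with the scale-to-pass/fail rule;
    * logged levels are consistent with the scale table at each logged scale.
    """

    assigned_scale: Optional[ScaleOrNR]
    classification: ScreenClass
    presentations: Tuple[Presentation, ...] = field(default_factory=tuple)
    n_procedures: int = 1
    ear: str = "unspecified"

    @property
    def passed(self) -> bool:
        return self.classification is ScreenClass.PASS

    def scales_visited(self) -> Tuple[int, ...]:
        """Distinct adaptive scales in presentation order (deduplicated runs)."""
        out = []
        for p in self.presentations:
            if p.scale is not None and (not out or out[-1] != p.scale):
                out.append(p.scale)
        return tuple(out)
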