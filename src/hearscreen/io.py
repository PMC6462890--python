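"""Session and cohort persistence.

Sessions (one screening run per ear) round-trip through JSON with a schema
version from day one; tabular summaries (per-scale groups, protocol
comparisons) round-trip through CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Union

import pandas as pd

from .errors import SessionFormatError
from .results import NR, Presentation, ScreenClass, ScreeningResult, is_nr

SCHEMA_VERSION = 1


@dataclass
class SessionRecord:
    """One persisted screening session.

    ``seed`` must be present whenever ``stochastic`` is set — a stochastic
    run without its seed cannot be reproduced, so saving one is refused.
    ``assigned_scale`` is an int, the string ``"NR"``, or None for
    fixed-level protocols.
    """

    subject_id: str
    ear: str
    protocol: str
    classification: str
    assigned_scale: Union[int, str, None] = None
    n_procedures: int = 1
    presentations: List[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    stochastic: bool = False
    seed: Optional[int] = None
    started_at: Optional[str] = None
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if self.stochastic and self.seed is None:
            raise SessionFormatError(
                "stochastic session without a seed cannot be reproduced; refusing"
            )
        if self.classification not in ("pass", "fail"):
            raise SessionFormatError(
                f"classification must be 'pass' or 'fail', got {self.classification!r}"
            )


def session_from_result(
    result: ScreeningResult,
    subject_id: str,
    protocol: str,
    *,
    stochastic: bool = False,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
    started_at: Optional[str] = None,
) -> SessionRecord:
    """Build a persistable record from a screening result."""
    scale = result.assigned_scale
    return SessionRecord(
        subject_id=subject_id,
        ear=result.ear,
        protocol=protocol,
        classification=result.classification.value,
        assigned_scale="NR" if is_nr(scale) else scale,
        n_procedures=result.n_procedures,
        presentations=[dataclasses.asdict(p) for p in result.presentations],
        config=config or {},
        stochastic=stochastic,
        seed=seed,
        started_at=started_at,
    )


def result_from_session(record: SessionRecord) -> ScreeningResult:
    """Reconstruct the in-memory result from a session record."""
    scale = record.assigned_scale
    return ScreeningResult(
        assigned_scale=NR if is_nr(scale) else scale,
        classification=ScreenClass(record.classification),
        presentations=tuple(Presentation(**p) for p in record.presentations),
        n_procedures=record.n_procedures,
        ear=record.ear,
    )


def save_session(record: SessionRecord, path) -> None:
    record.validate()
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(record), fh, indent=2)


def load_session(path) -> SessionRecord:
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SessionFormatError(
            f"cannot parse session file {path}: {exc.msg} "
            f"(line {exc.lineno}, column {exc.colno})"
        ) from exc
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SessionFormatError(
            f"session schema version {version!r} unsupported "
            f"(this package reads version {SCHEMA_VERSION})"
        )
    try:
        record = SessionRecord(**raw)
    except TypeError as exc:
        raise SessionFormatError(f"malformed session file {path}: {exc}") from exc
    record.validate()
    return record


def export_cohort_csv(frame: pd.DataFrame, path, *, index: bool = False) -> None:
    """Write a tabular summary (group rows or protocol metrics) to CSV."""
    frame.to_csv(path, index=index)


def import_cohort_csv(path, *, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)
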