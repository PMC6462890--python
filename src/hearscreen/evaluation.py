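"""Screening-test evaluation against a booth reference.

Screening outcomes (pass/fail per ear) are scored against the reference
impairment label (booth pure-tone average > 25 dB) in a 2x2 contingency
table; sensitivity, specificity, predictive values and false rates follow.
Per-scale group summaries (count, mean booth PTA, SD) and the scale-vs-PTA
product-moment correlation describe how the stratified scales track the
reference thresholds. ``compare_protocols`` runs several protocols on the
same cohort with matched seeds and tabulates the metrics side by side.

Undefined ratios (zero denominators, single-ear SDs, zero-variance
correlations) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError
from .hst_engine import EngineConfig, run_hst
from .listener_sim import SimulatedListener
from .protocols import ProtocolSpec, ScaleTable, fixed_level_screen
from .results import ScreenClass, ScreeningResult, is_nr

#: Sentinel for metrics whose denominator is empty.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; test positive = screen *fail*, reference positive =
    impaired (booth PTA > 25 dB)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transposed(self) -> "ContingencyTable":
        """Swap the roles of test and reference (tp<->tn unchanged axes swap)."""
        return ContingencyTable(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class ScreenMetrics:
    """Diagnostic accuracy of one screening protocol, as fractions in [0, 1].

    NaN marks a metric whose denominator was empty (e.g. sensitivity with
    no impaired ears in the cohort).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    false_positive_rate: float
    false_negative_rate: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
        }


def contingency(
    test_results: Sequence[ScreenClass],
    reference_impaired: Sequence[bool],
) -> ContingencyTable:
    """Cross-tabulate screen outcomes against reference impairment labels."""
    if len(test_results) != len(reference_impaired):
        raise DomainError(
            f"length mismatch: {len(test_results)} screen results vs "
            f"{len(reference_impaired)} reference labels"
        )
    tp = fp = fn = tn = 0
    for res, imp in zip(test_results, reference_impaired):
        failed = res is ScreenClass.FAIL
        if failed and imp:
            tp += 1
        elif failed and not imp:
            fp += 1
        elif not failed and imp:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def screen_metrics(table: ContingencyTable) -> ScreenMetrics:
    """Sensitivity, specificity, predictive values and false rates."""
    sens = _ratio(table.tp, table.tp + table.fn)
    spec = _ratio(table.tn, table.tn + table.fp)
    return ScreenMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        false_positive_rate=1.0 - spec if not math.isnan(spec) else UNDEFINED,
        false_negative_rate=1.0 - sens if not math.isnan(sens) else UNDEFINED,
    )


def scale_group_summary(
    results: Sequence[ScreeningResult],
    booth_pta_db: Sequence[float],
) -> Tuple[pd.DataFrame, int]:
    """Per-scale summary rows: count, mean and SD of the booth PTA.

    Returns ``(frame, n_nr)`` where the frame has one row per occupied
    scale (columns ``scale, n, mean_pta_db, sd_pta_db``; SD is NaN for
    single-ear groups) and ``n_nr`` counts no-response ears, which carry no
    scale and are reported separately.
    """
    if len(results) != len(booth_pta_db):
        raise DomainError(
            f"length mismatch: {len(results)} results vs {len(booth_pta_db)} PTAs"
        )
    scales, ptas = [], []
    n_nr = 0
    for r, pta in zip(results, booth_pta_db):
        if is_nr(r.assigned_scale):
            n_nr += 1
        elif r.assigned_scale is not None:
            scales.append(int(r.assigned_scale))
            ptas.append(float(pta))
    if not scales:
        frame = pd.DataFrame(columns=["scale", "n", "mean_pta_db", "sd_pta_db"])
        return frame, n_nr
    df = pd.DataFrame({"scale": scales, "pta": ptas})
    grouped = df.groupby("scale")["pta"]
    frame = pd.DataFrame(
        {
            "scale": grouped.mean().index,
            "n": grouped.size().to_numpy(),
            "mean_pta_db": grouped.mean().to_numpy(),
            # pandas ddof=1 SD is NaN for n=1, matching the undefined-SD convention
            "sd_pta_db": grouped.std(ddof=1).to_numpy(),
        }
    ).reset_index(drop=True)
    return frame, n_nr


def scale_pta_correlation(
    results: Sequence[ScreeningResult],
    booth_pta_db: Sequence[float],
    include_nr: bool = False,
    max_scale: int = 10,
) -> float:
    """Pearson correlation between assigned scale index and booth PTA.

    No-response ears are excluded by default; with ``include_nr`` they are
    ranked ``max_scale + 1``. Needs at least 3 usable ears; zero-variance
    input yields NaN.
    """
    if len(results) != len(booth_pta_db):
        raise DomainError("results and booth PTAs must align")
    xs, ys = [], []
    for r, pta in zip(results, booth_pta_db):
        if is_nr(r.assigned_scale):
            if include_nr:
                xs.append(max_scale + 1)
                ys.append(float(pta))
        elif r.assigned_scale is not None:
            xs.append(int(r.assigned_scale))
            ys.append(float(pta))
    if len(xs) < 3:
        raise DomainError(f"need >= 3 ears with defined scales, got {len(xs)}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        return UNDEFINED
    return float(stats.pearsonr(xs, ys).statistic)


def run_protocol_on_cohort(
    cohort: Sequence[SimulatedListener],
    spec: ProtocolSpec,
    seed: int = 0,
    engine_config: Optional[EngineConfig] = None,
) -> List[ScreeningResult]:
    """Screen every cohort listener under one protocol.

    Each listener gets child rngs derived from *seed* and its position, so
    different protocols run on the same cohort with the same seed see
    identical random streams per listener (matched comparison).
    """
    missing = [
        f
        for f in spec.frequencies_hz
        if any(f not in lst.thresholds_db_hl for lst in cohort)
    ]
    if missing:
        raise ConfigError(
            f"cohort listeners lack thresholds at {missing} Hz required by "
            f"protocol {spec.name!r}"
        )
    results: List[ScreeningResult] = []
    root = np.random.SeedSequence(seed)
    for child, listener in zip(root.spawn(len(cohort)), cohort):
        resp_ss, timing_ss = child.spawn(2)
        responder = listener.responder(np.random.default_rng(resp_ss))
        timing_rng = np.random.default_rng(timing_ss)
        if spec.mode == "adaptive-scale":
            results.append(
                run_hst(
                    responder,
                    spec.scale_table,
                    engine_config,
                    timing_rng,
                    ear=listener.ear,
                )
            )
        else:
            results.append(
                fixed_level_screen(responder, spec, timing_rng, ear=listener.ear)
            )
    return results


def compare_protocols(
    cohort: Sequence[SimulatedListener],
    protocols: Sequence[ProtocolSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Run each protocol on the same cohort and tabulate the metrics.

    Returns a frame indexed by protocol name with metric columns as
    fractions; deterministic for deterministic cohorts.
    """
    reference = [lst.impaired for lst in cohort]
    rows = {}
    for spec in protocols:
        results = run_protocol_on_cohort(cohort, spec, seed=seed)
        table = contingency([r.classification for r in results], reference)
        rows[spec.name] = screen_metrics(table).as_dict()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "protocol"
    return frame
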