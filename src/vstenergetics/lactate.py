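"""Six-timepoint plasma-lactate curves and their summaries.

Sampling schedule: T0 at rest before exercise, T1–T3 immediately after each
of the three races, T4 at 30 min and T5 at 240 min of recovery.  Because the
clock times of T1–T3 depend on unrecorded race timing, every operation works
on the ordered labels, not on minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd

from .errors import AnalysisError, DomainError, FormatError
from .telemetry_io import Role

__all__ = [
    "TIMEPOINTS",
    "RECOVERY_MINUTES",
    "ANAEROBIC_THRESHOLD_MMOL_L",
    "LactateCurve",
    "CurveSummary",
    "curve_summary",
    "threshold_exceedance",
    "recovery_assessment",
    "read_lactate_csv",
    "write_lactate_csv",
    "group_mean_curves",
]

#: Schedule order of the sampling labels.
TIMEPOINTS = ("T0", "T1", "T2", "T3", "T4", "T5")
#: Nominal recovery times (min after exercise end) where defined.
RECOVERY_MINUTES = {"T4": 30.0, "T5": 240.0}
#: Conventional anaerobic threshold (mmol/L).
ANAEROBIC_THRESHOLD_MMOL_L = 4.0


@dataclass(frozen=True)
class LactateCurve:
    """Ordered plasma-lactate concentrations (mmol/L) for one subject.

    ``values`` maps timepoint labels to concentrations; labels must be unique,
    drawn from T0–T5, and stored in schedule order.
    """

    subject_id: str
    role: Role
    values: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        items = dict(self.values)
        unknown = [k for k in items if k not in TIMEPOINTS]
        if unknown:
            raise DomainError(f"unknown timepoint label(s) {unknown}; expected {TIMEPOINTS}")
        ordered = {tp: float(items[tp]) for tp in TIMEPOINTS if tp in items}
        if list(ordered) != list(items):
            raise DomainError("timepoints must appear in schedule order T0..T5")
        for label, conc in ordered.items():
            if not math.isfinite(conc) or conc <= 0:
                raise DomainError(f"{label}: concentration must be positive, got {conc!r}")
        if len(ordered) < 2:
            raise DomainError("a curve needs at least 2 timepoints")
        object.__setattr__(self, "values", ordered)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.values)


class CurveSummary(NamedTuple):
    baseline_mmol_l: float
    peak_mmol_l: float
    peak_timepoint: str
    delta_mmol_l: float


def curve_summary(curve: LactateCurve) -> CurveSummary:
    """Baseline (T0), peak concentration and label, and delta = peak - baseline.

    Ties at the peak resolve to the earliest timepoint.
    """
    if "T0" not in curve.values:
        raise AnalysisError(f"curve {curve.subject_id!r} has no T0 baseline sample")
    baseline = curve.values["T0"]
    peak_label, peak = max(curve.values.items(), key=lambda kv: (kv[1], -TIMEPOINTS.index(kv[0])))
    return CurveSummary(baseline, peak, peak_label, peak - baseline)


def threshold_exceedance(
    curve: LactateCurve, threshold: float = ANAEROBIC_THRESHOLD_MMOL_L
) -> set[str]:
    """Labels whose concentration strictly exceeds ``threshold``."""
    if threshold <= 0:
        raise DomainError(f"threshold must be > 0, got {threshold!r}")
    return {label for label, conc in curve.values.items() if conc > threshold}


def recovery_assessment(curve: LactateCurve, tolerance: float = 0.5) -> str | None:
    """Earliest post-peak label back within ``baseline + tolerance``, or None.

    "Recovered" is judged against the subject's own T0 because no absolute
    criterion was published; the default tolerance is 0.5 mmol/L.
    """
    if tolerance < 0:
        raise DomainError(f"tolerance must be >= 0, got {tolerance!r}")
    summary = curve_summary(curve)
    past_peak = False
    for label, conc in curve.values.items():
        if past_peak and conc <= summary.baseline_mmol_l + tolerance:
            return label
        if label == summary.peak_timepoint:
            past_peak = True
    return None


_CSV_COLUMNS = ("subject_id", "role", "timepoint", "lactate_mmol_l")


def read_lactate_csv(path: str | Path) -> list[LactateCurve]:
    """Read long-format lactate CSV (subject_id, role, timepoint, lactate_mmol_l)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    for column in _CSV_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"missing required column {column!r} in {path}")
    curves = []
    for (subject_id, role), group in frame.groupby(["subject_id", "role"], sort=False):
        group = group.copy()
        group["_order"] = group["timepoint"].map(
            {tp: i for i, tp in enumerate(TIMEPOINTS)}
        )
        group = group.sort_values("_order")
        curves.append(
            LactateCurve(
                subject_id=str(subject_id),
                role=Role(role),
                values=dict(zip(group["timepoint"], group["lactate_mmol_l"])),
            )
        )
    return curves


def write_lactate_csv(curves: list[LactateCurve], path: str | Path) -> None:
    rows = [
        {"subject_id": c.subject_id, "role": c.role.value, "timepoint": tp, "lactate_mmol_l": v}
        for c in curves
        for tp, v in c.values.items()
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def group_mean_curves() -> dict[Role, LactateCurve]:
    """The published group-mean lactate curves, shipped as a packaged fixture."""
    with resources.files("vstenergetics.data").joinpath("lactate_group_means.csv").open() as fh:
        curves = read_lactate_csv(fh)  # type: ignore[arg-type]
    return {curve.role: curve for curve in curves}
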