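"""Heart-rate-derived energetic indices: EE, COT and Pmet.

All three indices are computed from the 1 Hz heart-rate stream and the total
carried mass (horse + rider + tack):

* ``EE (J/kg/min) = ee_coeff * HR ** ee_exp`` (defaults 0.0566, 1.9955);
* ``COT`` = beats above a 35 bpm baseline per kg per metre, scaled by 10^3;
* ``Pmet`` = beats above baseline per minute per kg, scaled by 10^3.

The published COT/Pmet unit strings are dimensionally ambiguous, so COT has
two explicit modes: ``dimensional`` (beats accumulated over the segment
duration divided by mass x distance — time-consistent, the default) and
``paper_numeric`` ((HR - baseline)/(speed x mass), which reproduces the
printed magnitudes).  Reports always name the mode used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, DomainError, ParameterError
from .gait_segmentation import Gait, RaceSegment
from .telemetry_io import ExerciseSession, total_carried_mass

__all__ = [
    "EnergeticsConfig",
    "EnergeticsSummary",
    "DEFAULT_CONFIG",
    "energy_expenditure",
    "cost_of_transport",
    "metabolic_power",
    "summarize_session",
    "hr_zone_fractions",
]

CotMode = Literal["dimensional", "paper_numeric"]


@dataclass(frozen=True)
class EnergeticsConfig:
    """Coefficients and conventions for the three indices.

    ``scale_factor`` (default 10^3) multiplies COT and Pmet, matching the
    "x 10^3" in the published COT unit and the printed Pmet magnitudes; with
    ``scale_factor=1`` the operations return the literal formulas.
    ``ee_from_mean_hr=True`` evaluates segment EE at the segment-mean HR
    instead of averaging per-sample EE values.
    """

    baseline_hr_bpm: float = 35.0
    ee_coeff: float = 0.0566
    ee_exp: float = 1.9955
    scale_factor: float = 1000.0
    cot_mode: CotMode = "dimensional"
    ee_from_mean_hr: bool = False

    def __post_init__(self) -> None:
        if self.ee_coeff <= 0 or self.ee_exp <= 0:
            raise ParameterError("ee_coeff and ee_exp must be > 0")
        if self.baseline_hr_bpm < 0:
            raise ParameterError("baseline_hr_bpm must be >= 0")
        if self.cot_mode not in ("dimensional", "paper_numeric"):
            raise ParameterError(f"unknown cot_mode {self.cot_mode!r}")


DEFAULT_CONFIG = EnergeticsConfig()


def energy_expenditure(hr_bpm, config: EnergeticsConfig = DEFAULT_CONFIG):
    """EE (J/kg/min) = ee_coeff * HR ** ee_exp; strictly increasing in HR.

    Accepts a scalar or array of heart rates.
    """
    hr = np.asarray(hr_bpm, dtype=float)
    if np.any(~np.isfinite(hr)) or np.any(hr < 0):
        raise DomainError("heart rate must be finite and >= 0")
    out = config.ee_coeff * np.power(hr, config.ee_exp)
    return float(out) if np.isscalar(hr_bpm) or out.ndim == 0 else out


def _beats_above_baseline(mean_hr_bpm: float, config: EnergeticsConfig) -> float:
    excess = float(mean_hr_bpm) - config.baseline_hr_bpm
    if excess < 0:
        warnings.warn(
            f"mean HR {mean_hr_bpm:.1f} below baseline {config.baseline_hr_bpm:.0f}; "
            "clamping to zero cost",
            UserWarning,
            stacklevel=3,
        )
        return 0.0
    return excess


def cost_of_transport(
    mean_hr_bpm: float,
    mass_kg: float,
    distance_m: float | None = None,
    duration_s: float | None = None,
    mean_speed_mps: float | None = None,
    config: EnergeticsConfig = DEFAULT_CONFIG,
) -> float:
    """Beats above baseline per kg per metre, scaled by ``scale_factor``.

    ``dimensional`` mode needs ``distance_m`` and ``duration_s``:
    (HR - baseline) * duration_min / (mass * distance) * scale.
    ``paper_numeric`` mode needs ``mean_speed_mps``:
    (HR - baseline) / (speed * mass) * scale.
    HR below baseline is clamped to 0 with a warning.
    """
    if mass_kg <= 0 or not math.isfinite(mass_kg):
        raise DomainError(f"mass_kg must be positive, got {mass_kg!r}")
    excess = _beats_above_baseline(mean_hr_bpm, config)
    if config.cot_mode == "dimensional":
        if distance_m is None or duration_s is None:
            raise DomainError("dimensional COT needs distance_m and duration_s")
        if distance_m <= 0 or duration_s <= 0:
            raise DomainError("distance_m and duration_s must be positive")
        beats = excess * duration_s / 60.0
        return beats / (mass_kg * distance_m) * config.scale_factor
    if mean_speed_mps is None:
        raise DomainError("paper_numeric COT needs mean_speed_mps")
    if mean_speed_mps <= 0:
        raise DomainError("mean_speed_mps must be positive")
    return excess / (mean_speed_mps * mass_kg) * config.scale_factor


def metabolic_power(
    mean_hr_bpm: float, mass_kg: float, config: EnergeticsConfig = DEFAULT_CONFIG
) -> float:
    """Beats above baseline per minute per kg, scaled by ``scale_factor``."""
    if mass_kg <= 0 or not math.isfinite(mass_kg):
        raise DomainError(f"mass_kg must be positive, got {mass_kg!r}")
    return _beats_above_baseline(mean_hr_bpm, config) / mass_kg * config.scale_factor


@dataclass(frozen=True)
class EnergeticsSummary:
    """Per (race x gait) indices plus session totals for one subject.

    ``cells`` has one row per race x gait combination with at least one
    sample (columns: race, gait, n_samples, duration_s, distance_m,
    mean_hr_bpm, mean_speed_mps, ee_J_per_kg_min, cot_scaled, pmet_scaled).
    ``totals`` aggregates all non-transition samples of all race blocks.
    """

    subject_id: str
    mass_kg: float
    cot_mode: CotMode
    cells: pd.DataFrame = field(repr=False)
    totals: pd.Series = field(repr=False)
    transition_fraction: float = 0.0


def _cell_metrics(
    hr: np.ndarray,
    speed: np.ndarray,
    increments: np.ndarray,
    mass_kg: float,
    config: EnergeticsConfig,
) -> dict[str, float]:
    n = hr.size
    duration_s = float(n)  # 1 Hz grain: one second per available sample
    distance_m = float(np.sum(increments))
    mean_hr = float(np.mean(hr))
    mean_speed = float(np.mean(speed))
    if config.ee_from_mean_hr:
        ee = energy_expenditure(mean_hr, config)
    else:
        ee = float(np.mean(energy_expenditure(hr, config)))
    if config.cot_mode == "dimensional":
        cot = (
            cost_of_transport(mean_hr, mass_kg, distance_m=distance_m,
                              duration_s=duration_s, config=config)
            if distance_m > 0
            else float("nan")
        )
    else:
        cot = (
            cost_of_transport(mean_hr, mass_kg, mean_speed_mps=mean_speed, config=config)
            if mean_speed > 0
            else float("nan")
        )
    return {
        "n_samples": n,
        "duration_s": duration_s,
        "distance_m": distance_m,
        "mean_hr_bpm": mean_hr,
        "mean_speed_mps": mean_speed,
        "ee_J_per_kg_min": ee,
        "cot_scaled": cot,
        "pmet_scaled": metabolic_power(mean_hr, mass_kg, config),
    }


def summarize_session(
    session: ExerciseSession,
    labels: Sequence[Gait],
    races: Sequence[RaceSegment],
    config: EnergeticsConfig = DEFAULT_CONFIG,
) -> EnergeticsSummary:
    """Aggregate the three indices per race x gait cell and over the session.

    Samples are attributed to race blocks: block *i* runs from the start of
    the previous race's block (the session start for the first race) up to
    the start of race *i + 1*, so approach, race and following rest all
    belong to race *i*.  Transition-labelled samples are excluded from gait
    cells and from the totals but counted in ``transition_fraction``.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != session.n_samples:
        raise AnalysisError("labels not aligned to session samples")
    if not races:
        raise AnalysisError("no races detected; cannot build race x gait cells")
    # compare on .value: numpy would otherwise broadcast a str-enum scalar
    # as a character sequence, never matching elementwise
    label_values = np.array([label.value for label in labels])
    mass_kg = total_carried_mass(session.metadata)
    t = session.t_s
    increments = session.distance_increments()

    # race-block boundaries: [session start, race2.start, race3.start, ..., end)
    starts = [int(t[0])] + [r.start_s for r in races[1:]]
    ends = starts[1:] + [int(t[-1]) + 1]

    rows = []
    for race, (lo, hi) in zip(races, zip(starts, ends)):
        in_block = (t >= lo) & (t < hi)
        for gait in (Gait.WALK, Gait.TROT, Gait.GALLOP):
            mask = in_block & (label_values == gait.value)
            if not np.any(mask):
                continue
            metrics = _cell_metrics(
                session.hr_bpm[mask], session.speed_mps[mask], increments[mask],
                mass_kg, config,
            )
            rows.append({"race": race.index, "gait": gait.value, **metrics})
    cells = pd.DataFrame(rows)

    non_transition = label_values != Gait.TRANSITION.value
    totals = pd.Series(
        _cell_metrics(
            session.hr_bpm[non_transition],
            session.speed_mps[non_transition],
            increments[non_transition],
            mass_kg,
            config,
        )
    )
    return EnergeticsSummary(
        subject_id=session.metadata.subject_id,
        mass_kg=mass_kg,
        cot_mode=config.cot_mode,
        cells=cells,
        totals=totals,
        transition_fraction=float(np.mean(~non_transition)),
    )


def hr_zone_fractions(session: ExerciseSession, zone_bounds: Sequence[float]) -> np.ndarray:
    """Fraction of samples per HR zone defined by strictly increasing bounds.

    ``len(zone_bounds) + 1`` zones; zone *k* is [bounds[k-1], bounds[k]), the
    first zone is (-inf, bounds[0]).  Fractions sum to 1.
    """
    bounds = np.asarray(zone_bounds, dtype=float)
    if bounds.size == 0 or np.any(np.diff(bounds) <= 0):
        raise ParameterError("zone_bounds must be non-empty and strictly increasing")
    zone = np.searchsorted(bounds, session.hr_bpm, side="right")
    counts = np.bincount(zone, minlength=bounds.size + 1)
    return counts / session.n_samples
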