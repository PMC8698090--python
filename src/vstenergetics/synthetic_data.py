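"""Seeded generator for role-specific VST telemetry and lactate curves.

The study's raw recordings are not public, so this module produces 1 Hz
sessions with the structure the analysis assumes: a warm-up walk, then three
blocks of trot approach → gallop race (duration drawn from the configured
range) → trot deceleration → walking rest.  Heart rate follows a first-order
relaxation toward a gait-specific set-point with Gaussian observation
jitter; within-gait speeds are clipped Gaussians inside the gait's speed
band so labels stay recoverable.

Everything is deterministic given (seed, role, subject_index): the global
seed expands to per-subject substreams, so cohorts are stable under
re-ordering.  The ``coelho2021`` preset tunes set-points to the published
group means (pull horses gallop higher, helper horses trot higher) with
relaxation constants fast enough that bout-mean HR sits within ±2 bpm of
the set-point.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .errors import ParameterError
from .gait_segmentation import (
    GALLOP_MIN_MPS,
    TROT_MAX_MPS,
    TROT_MIN_MPS,
    WALK_MAX_MPS,
    Gait,
)
from .lactate import TIMEPOINTS, LactateCurve
from .telemetry_io import ExerciseSession, Role, SubjectMetadata

__all__ = [
    "GaitTargets",
    "LactateKinetics",
    "RoleParams",
    "VSTGeneratorConfig",
    "Cohort",
    "preset",
    "PRESETS",
    "generate_session",
    "generate_lactate",
    "generate_cohort",
]

_BAND_MARGIN = 0.01
_SPEED_BANDS = {
    Gait.WALK: (0.05, WALK_MAX_MPS - _BAND_MARGIN),
    Gait.TROT: (TROT_MIN_MPS + _BAND_MARGIN, TROT_MAX_MPS - _BAND_MARGIN),
    Gait.GALLOP: (GALLOP_MIN_MPS + _BAND_MARGIN, 12.0),
}


@dataclass(frozen=True)
class GaitTargets:
    """Set-point mean and per-sample SD for HR and speed within one gait."""

    hr_bpm: float
    hr_sd_bpm: float
    speed_mps: float
    speed_sd_mps: float

    def __post_init__(self) -> None:
        if self.hr_sd_bpm < 0 or self.speed_sd_mps < 0:
            raise ParameterError("SDs must be >= 0")


@dataclass(frozen=True)
class LactateKinetics:
    """Piecewise kinetic model: per-race increments then exponential clearance.

    T0 is the baseline; T1–T3 add ``increments_mmol_l`` cumulatively; T4/T5
    decay toward ``floor_mmol_l`` (the baseline when None) with the given
    half-life.  A non-positive half-life means instant clearance.
    ``noise_cv`` applies multiplicative lognormal jitter per timepoint.
    """

    baseline_mmol_l: float
    increments_mmol_l: tuple[float, ...]
    half_life_min: float
    floor_mmol_l: float | None = None
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_mmol_l <= 0:
            raise ParameterError("baseline_mmol_l must be > 0")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")


@dataclass(frozen=True)
class RoleParams:
    rider_mass_kg: float
    gaits: dict[Gait, GaitTargets]
    lactate: LactateKinetics


def _coelho2021_roles() -> dict[Role, RoleParams]:
    # Set-points are the across-race averages of the published group means;
    # the directional contrasts (PH > HH at gallop, HH > PH at trot) are
    # built in.  Within-gait SDs are configurable, not the study's.
    return {
        Role.PH: RoleParams(
            rider_mass_kg=75.0,
            gaits={
                Gait.WALK: GaitTargets(105.4, 6.0, 0.97, 0.25),
                Gait.TROT: GaitTargets(135.6, 6.0, 3.12, 0.40),
                Gait.GALLOP: GaitTargets(185.2, 6.0, 6.88, 0.35),
            },
            lactate=LactateKinetics(
                baseline_mmol_l=2.2,
                increments_mmol_l=(5.8, 1.5, 1.1),
                half_life_min=15.5,
                floor_mmol_l=1.8,
                noise_cv=0.2,
            ),
        ),
        Role.HH: RoleParams(
            rider_mass_kg=72.5,
            gaits={
                Gait.WALK: GaitTargets(121.2, 6.0, 1.18, 0.25),
                Gait.TROT: GaitTargets(156.4, 6.0, 2.88, 0.40),
                Gait.GALLOP: GaitTargets(179.1, 6.0, 6.65, 0.35),
            },
            lactate=LactateKinetics(
                baseline_mmol_l=2.1,
                increments_mmol_l=(3.5, 0.7, 0.4),
                half_life_min=6.0,
                floor_mmol_l=2.3,
                noise_cv=0.2,
            ),
        ),
    }


@dataclass(frozen=True)
class VSTGeneratorConfig:
    """Full parameterization of the synthetic VST cohort."""

    n_pairs: int = 4
    n_races: int = 3
    race_duration_s: tuple[int, int] = (40, 50)
    #: Nominal course length (m), recorded for provenance.  The simulated
    #: gallop distance emerges as speed x duration, which for the published
    #: speed and duration ranges necessarily exceeds the course length.
    race_distance_m: tuple[float, float] = (130.0, 150.0)
    rest_s: int = 300
    warmup_s: int = 60
    approach_s: int = 15
    decel_s: int = 5
    resting_hr_bpm: float = 40.0
    hr_rise_tau_s: float = 0.5
    hr_decay_tau_s: float = 1.0
    horse_mass_kg: float = 428.0
    tack_mass_kg: float = 10.0
    roles: dict[Role, RoleParams] = field(default_factory=_coelho2021_roles)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_races < 1:
            raise ParameterError("n_pairs and n_races must be >= 1")
        lo, hi = self.race_duration_s
        if not (1 <= lo <= hi):
            raise ParameterError(f"empty race_duration_s range {self.race_duration_s}")
        if self.race_distance_m[0] > self.race_distance_m[1]:
            raise ParameterError(f"empty race_distance_m range {self.race_distance_m}")
        if min(self.rest_s, self.warmup_s, self.approach_s) < 1 or self.decel_s < 0:
            raise ParameterError("rest_s, warmup_s, approach_s must be >= 1 s")
        if set(self.roles) != {Role.PH, Role.HH}:
            raise ParameterError("roles must define exactly PH and HH")


PRESETS = {"coelho2021": VSTGeneratorConfig}


def preset(name: str = "coelho2021", **overrides) -> VSTGeneratorConfig:
    """Named generator preset; keyword overrides replace individual fields."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ParameterError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(factory(), **overrides) if overrides else factory()


class Cohort(NamedTuple):
    sessions: list[ExerciseSession]
    curves: list[LactateCurve]
    metadata: list[SubjectMetadata]


def _rng(config: VSTGeneratorConfig, role: Role, subject_index: int, stream: int):
    role_code = 0 if role is Role.PH else 1
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), role_code, int(subject_index), stream])
    )


def _subject_metadata(config: VSTGeneratorConfig, role: Role, subject_index: int) -> SubjectMetadata:
    return SubjectMetadata(
        subject_id=f"{role.value}{subject_index + 1}",
        role=role,
        horse_mass_kg=config.horse_mass_kg,
        rider_mass_kg=config.roles[role].rider_mass_kg,
        tack_mass_kg=config.tack_mass_kg,
    )


def _segment_plan(config: VSTGeneratorConfig, rng) -> list[tuple[Gait, int]]:
    lo, hi = config.race_duration_s
    plan: list[tuple[Gait, int]] = [(Gait.WALK, config.warmup_s)]
    for _ in range(config.n_races):
        gallop_s = int(rng.integers(lo, hi + 1))
        plan.append((Gait.TROT, config.approach_s))
        plan.append((Gait.GALLOP, gallop_s))
        if config.decel_s:
            plan.append((Gait.TROT, config.decel_s))
        plan.append((Gait.WALK, config.rest_s))
    return plan


def generate_session(
    config: VSTGeneratorConfig, role: Role | str, subject_index: int
) -> ExerciseSession:
    """One deterministic 1 Hz session for (config.seed, role, subject_index)."""
    role = Role(role)
    params = config.roles[role]
    rng = _rng(config, role, subject_index, stream=0)
    plan = _segment_plan(config, rng)

    speeds: list[np.ndarray] = []
    gait_seq: list[Gait] = []
    for gait, duration in plan:
        targets = params.gaits[gait]
        lo, hi = _SPEED_BANDS[gait]
        block = rng.normal(targets.speed_mps, targets.speed_sd_mps, size=duration)
        speeds.append(np.clip(block, lo, hi) if targets.speed_sd_mps > 0
                      else np.full(duration, float(np.clip(targets.speed_mps, lo, hi))))
        gait_seq.extend([gait] * duration)
    speed = np.concatenate(speeds)
    n = speed.size

    hr = np.empty(n)
    state = config.resting_hr_bpm
    for i, gait in enumerate(gait_seq):
        target = params.gaits[gait].hr_bpm
        tau = config.hr_rise_tau_s if target > state else config.hr_decay_tau_s
        if tau <= 0:
            state = target
        else:
            state += (target - state) * (1.0 - math.exp(-1.0 / tau))
        hr[i] = state
    sds = np.array([params.gaits[g].hr_sd_bpm for g in gait_seq])
    if np.any(sds > 0):
        hr = hr + rng.normal(0.0, 1.0, size=n) * sds
    hr = np.clip(hr, 25.0, 255.0)

    return ExerciseSession(
        metadata=_subject_metadata(config, role, subject_index),
        t_s=np.arange(n, dtype=np.int64),
        hr_bpm=hr,
        speed_mps=speed,
        cum_dist_m=np.cumsum(speed),
    )


def nominal_lactate(kinetics: LactateKinetics) -> dict[str, float]:
    """Noise-free timepoint values implied by the kinetic parameters."""
    values = {"T0": kinetics.baseline_mmol_l}
    level = kinetics.baseline_mmol_l
    for race, label in enumerate(("T1", "T2", "T3")):
        if race < len(kinetics.increments_mmol_l):
            level += kinetics.increments_mmol_l[race]
        values[label] = level
    floor = (
        kinetics.baseline_mmol_l if kinetics.floor_mmol_l is None else kinetics.floor_mmol_l
    )
    peak = values["T3"]
    for label in ("T4", "T5"):
        minutes = {"T4": 30.0, "T5": 240.0}[label]
        if kinetics.half_life_min <= 0:
            values[label] = floor
        else:
            values[label] = floor + (peak - floor) * 2.0 ** (-minutes / kinetics.half_life_min)
    return values


def generate_lactate(
    config: VSTGeneratorConfig, role: Role | str, subject_index: int
) -> LactateCurve:
    """One deterministic six-timepoint lactate curve."""
    role = Role(role)
    kinetics = config.roles[role].lactate
    rng = _rng(config, role, subject_index, stream=1)
    nominal = nominal_lactate(kinetics)
    values = {}
    for label in TIMEPOINTS:
        jitter = math.exp(rng.normal(0.0, kinetics.noise_cv)) if kinetics.noise_cv > 0 else 1.0
        values[label] = max(nominal[label] * jitter, 1e-6)
    return LactateCurve(
        subject_id=f"{role.value}{subject_index + 1}", role=role, values=values
    )


def generate_cohort(config: VSTGeneratorConfig) -> Cohort:
    """n_pairs PH + n_pairs HH subjects with sessions, curves and metadata."""
    sessions, curves, metadata = [], [], []
    for role in (Role.PH, Role.HH):
        for index in range(config.n_pairs):
            sessions.append(generate_session(config, role, index))
            curves.append(generate_lactate(config, role, index))
            metadata.append(_subject_metadata(config, role, index))
    return Cohort(sessions=sessions, curves=curves, metadata=metadata)


def config_to_dict(config: VSTGeneratorConfig) -> dict:
    """JSON-serializable dump of a generator config (for manifests)."""
    raw = asdict(config)
    raw["roles"] = {
        role.value: {
            "rider_mass_kg": rp["rider_mass_kg"],
            "gaits": {g.value: gt for g, gt in rp["gaits"].items()},
            "lactate": rp["lactate"],
        }
        for role, rp in raw["roles"].items()
    }
    return raw
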