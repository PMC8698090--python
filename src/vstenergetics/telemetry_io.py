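"""Read, validate and write 1 Hz exercise sessions and subject metadata.

The canonical on-disk format is a plain CSV with columns
``t_s, hr_bpm, speed_mps, cum_dist_m`` (decimal point ``.``), one row per
second of recording.  Subject metadata travels in a small ``key=value``
sidecar file.  No proprietary device export is parsed.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, SessionValidationError

__all__ = [
    "Role",
    "SubjectMetadata",
    "TelemetrySample",
    "ExerciseSession",
    "GapWarning",
    "HR_RANGE_BPM",
    "SPEED_RANGE_MPS",
    "SESSION_COLUMNS",
    "read_session_csv",
    "write_session_csv",
    "read_metadata",
    "write_metadata",
    "total_carried_mass",
    "study_mean_metadata",
]

#: Physiologically plausible heart-rate window (beats/min).
HR_RANGE_BPM = (20.0, 260.0)
#: Plausible ground-speed window (m/s).
SPEED_RANGE_MPS = (0.0, 25.0)
#: Canonical CSV header, in order.
SESSION_COLUMNS = ("t_s", "hr_bpm", "speed_mps", "cum_dist_m")


class GapWarning(UserWarning):
    """Emitted when a session has missing seconds between samples."""


class Role(str, enum.Enum):
    """Competition role of the horse: pull horse or helper horse."""

    PH = "PH"
    HH = "HH"


@dataclass(frozen=True)
class SubjectMetadata:
    """Identity, role and the three mass components carried during exercise."""

    subject_id: str
    role: Role
    horse_mass_kg: float
    rider_mass_kg: float
    tack_mass_kg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        for name in ("horse_mass_kg", "rider_mass_kg", "tack_mass_kg"):
            value = float(getattr(self, name))
            if not math.isfinite(value) or value <= 0:
                raise DomainError(f"{name} must be a positive finite mass, got {value!r}")
            object.__setattr__(self, name, value)


class TelemetrySample(NamedTuple):
    """One second of recording."""

    t_s: int
    hr_bpm: float
    speed_mps: float
    cum_dist_m: float


#: Default rider mass per role (kg) for the study-means preset.
_STUDY_RIDER_MASS_KG = {Role.PH: 75.0, Role.HH: 72.5}
_STUDY_HORSE_MASS_KG = 428.0
_STUDY_TACK_MASS_KG = 10.0


def study_mean_metadata(subject_id: str, role: Role | str) -> SubjectMetadata:
    """Metadata preset using the cohort-mean masses (428 kg horse, 10 kg tack,
    75 kg rider for PH / 72.5 kg for HH); individual masses were not recorded.
    """
    role = Role(role)
    return SubjectMetadata(
        subject_id=subject_id,
        role=role,
        horse_mass_kg=_STUDY_HORSE_MASS_KG,
        rider_mass_kg=_STUDY_RIDER_MASS_KG[role],
        tack_mass_kg=_STUDY_TACK_MASS_KG,
    )


@dataclass(frozen=True)
class ExerciseSession:
    """One horse's validated 1 Hz telemetry stream plus its metadata.

    The four channels are stored as parallel numpy arrays; ``samples``
    iterates row-wise as :class:`TelemetrySample`.  Construction enforces all
    stream invariants (strictly increasing whole-second times, plausible HR
    and speed, non-decreasing cumulative distance, >= 2 samples) and warns on
    missing seconds.
    """

    metadata: SubjectMetadata
    t_s: np.ndarray = field(repr=False)
    hr_bpm: np.ndarray = field(repr=False)
    speed_mps: np.ndarray = field(repr=False)
    cum_dist_m: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t_raw = np.asarray(self.t_s, dtype=float)
        if t_raw.ndim != 1:
            raise SessionValidationError("t_s must be one-dimensional")
        if not np.all(np.isfinite(t_raw)):
            raise SessionValidationError("t_s contains non-finite values")
        if np.any(t_raw != np.floor(t_raw)):
            warnings.warn(
                "sub-second timestamps truncated to whole seconds", UserWarning, stacklevel=2
            )
        t = np.floor(t_raw).astype(np.int64)
        hr = np.ascontiguousarray(np.asarray(self.hr_bpm, dtype=float))
        v = np.ascontiguousarray(np.asarray(self.speed_mps, dtype=float))
        d = np.ascontiguousarray(np.asarray(self.cum_dist_m, dtype=float))
        n = t.size
        if not (hr.size == v.size == d.size == n):
            raise SessionValidationError("channel lengths differ")
        if n < 2:
            raise SessionValidationError(f"a session needs at least 2 samples, got {n}")

        increasing = np.diff(t) > 0
        if not np.all(increasing):
            idx = int(np.argmin(increasing)) + 1
            raise SessionValidationError(f"t_s not strictly increasing at row {idx}")
        _check_range("hr_bpm", hr, HR_RANGE_BPM)
        _check_range("speed_mps", v, SPEED_RANGE_MPS)
        non_decreasing = np.diff(d) >= 0
        if not np.all(non_decreasing):
            idx = int(np.argmin(non_decreasing)) + 1
            raise SessionValidationError(f"cum_dist_m decreases at row {idx}")
        gaps = np.flatnonzero(np.diff(t) > 1)
        if gaps.size:
            warnings.warn(
                f"session {self.metadata.subject_id!r} has {gaps.size} gap(s) > 1 s "
                f"(first after row {int(gaps[0])})",
                GapWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "hr_bpm", hr)
        object.__setattr__(self, "speed_mps", v)
        object.__setattr__(self, "cum_dist_m", d)

    # -- convenience views ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    @property
    def duration_s(self) -> int:
        """Elapsed seconds between first and last sample."""
        return int(self.t_s[-1] - self.t_s[0])

    @property
    def samples(self) -> Iterator[TelemetrySample]:
        for row in zip(self.t_s, self.hr_bpm, self.speed_mps, self.cum_dist_m):
            yield TelemetrySample(int(row[0]), float(row[1]), float(row[2]), float(row[3]))

    def distance_increments(self) -> np.ndarray:
        """Per-sample distance (m); first sample credits its cumulative value."""
        return np.diff(self.cum_dist_m, prepend=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "hr_bpm": self.hr_bpm,
                "speed_mps": self.speed_mps,
                "cum_dist_m": self.cum_dist_m,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExerciseSession):
            return NotImplemented
        return (
            self.metadata == other.metadata
            and np.array_equal(self.t_s, other.t_s)
            and np.array_equal(self.hr_bpm, other.hr_bpm)
            and np.array_equal(self.speed_mps, other.speed_mps)
            and np.array_equal(self.cum_dist_m, other.cum_dist_m)
        )


def _check_range(name: str, values: np.ndarray, bounds: tuple[float, float]) -> None:
    lo, hi = bounds
    ok = np.isfinite(values) & (values >= lo) & (values <= hi)
    if not np.all(ok):
        bad = np.flatnonzero(~ok)
        raise SessionValidationError(
            f"{name} outside [{lo}, {hi}] at row(s) {bad[:10].tolist()}"
            + (" ..." if bad.size > 10 else "")
        )


def read_session_csv(path: str | Path, metadata: SubjectMetadata) -> ExerciseSession:
    """Read one session from the canonical CSV dialect and validate it.

    Raises :class:`FormatError` for a missing column and
    :class:`SessionValidationError` (citing the first offending row) for
    invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    for column in SESSION_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"missing required column {column!r} in {path}")
    return ExerciseSession(
        metadata=metadata,
        t_s=frame["t_s"].to_numpy(),
        hr_bpm=frame["hr_bpm"].to_numpy(dtype=float),
        speed_mps=frame["speed_mps"].to_numpy(dtype=float),
        cum_dist_m=frame["cum_dist_m"].to_numpy(dtype=float),
    )


def write_session_csv(session: ExerciseSession, path: str | Path) -> None:
    """Write a session in the canonical dialect.

    Floats are serialized with their shortest exact representation, so
    ``read_session_csv(write_session_csv(s)) == s`` sample for sample.
    """
    session.to_frame().to_csv(path, index=False)


def total_carried_mass(metadata: SubjectMetadata) -> float:
    """Total moving mass (kg): horse + rider + tack."""
    return metadata.horse_mass_kg + metadata.rider_mass_kg + metadata.tack_mass_kg


_METADATA_FIELDS = ("subject_id", "role", "horse_mass_kg", "rider_mass_kg", "tack_mass_kg")


def write_metadata(metadata: SubjectMetadata, path: str | Path) -> None:
    """Write metadata as a ``key=value`` sidecar file."""
    lines = [
        f"subject_id={metadata.subject_id}",
        f"role={metadata.role.value}",
        f"horse_mass_kg={metadata.horse_mass_kg!r}",
        f"rider_mass_kg={metadata.rider_mass_kg!r}",
        f"tack_mass_kg={metadata.tack_mass_kg!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> SubjectMetadata:
    """Read a ``key=value`` metadata sidecar written by :func:`write_metadata`."""
    pairs: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}: line {lineno} is not key=value: {raw!r}")
        key, value = line.split("=", 1)
        pairs[key.strip()] = value.strip()
    missing = [name for name in _METADATA_FIELDS if name not in pairs]
    if missing:
        raise FormatError(f"{path}: missing metadata key(s) {missing}")
    return SubjectMetadata(
        subject_id=pairs["subject_id"],
        role=Role(pairs["role"]),
        horse_mass_kg=float(pairs["horse_mass_kg"]),
        rider_mass_kg=float(pairs["rider_mass_kg"]),
        tack_mass_kg=float(pairs["tack_mass_kg"]),
    )
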