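"""Speed-threshold gait labelling, bout extraction and race detection.

Gaits follow the published speed bands: walk < 1.67 m/s, trot in
[1.94, 4.17] m/s, gallop > 4.44 m/s.  Speeds inside the two unclassified
gaps ([1.67, 1.94) and (4.17, 4.44]) are labelled ``transition`` rather than
being forced into a neighbouring gait.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DomainError, ParameterError
from .telemetry_io import ExerciseSession

__all__ = [
    "Gait",
    "GaitBout",
    "RaceSegment",
    "WALK_MAX_MPS",
    "TROT_MIN_MPS",
    "TROT_MAX_MPS",
    "GALLOP_MIN_MPS",
    "classify_speed",
    "classify_speeds",
    "running_median",
    "label_session",
    "extract_bouts",
    "detect_races",
    "segments_to_bed",
]

WALK_MAX_MPS = 1.67   # walk: v < 1.67 (strict)
TROT_MIN_MPS = 1.94   # trot: 1.94 <= v <= 4.17 (inclusive)
TROT_MAX_MPS = 4.17
GALLOP_MIN_MPS = 4.44  # gallop: v > 4.44 (strict)

DEFAULT_SMOOTH_WINDOW = 3
DEFAULT_MIN_GALLOP_S = 5
DEFAULT_MIN_REST_S = 60


class Gait(str, enum.Enum):
    WALK = "walk"
    TROT = "trot"
    GALLOP = "gallop"
    TRANSITION = "transition"


def classify_speed(speed_mps: float) -> Gait:
    """Assign a gait to a single speed value.

    The three published bands partition [0, inf) together with the explicit
    ``transition`` label for the two gaps; boundary semantics follow the
    printed inequalities (1.67 -> transition, 1.94 and 4.17 -> trot,
    4.44 -> transition).
    """
    v = float(speed_mps)
    if not math.isfinite(v) or v < 0:
        raise DomainError(f"speed must be finite and >= 0, got {speed_mps!r}")
    if v < WALK_MAX_MPS:
        return Gait.WALK
    if TROT_MIN_MPS <= v <= TROT_MAX_MPS:
        return Gait.TROT
    if v > GALLOP_MIN_MPS:
        return Gait.GALLOP
    return Gait.TRANSITION


def classify_speeds(speeds_mps: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_speed`; returns an object array of Gait."""
    v = np.asarray(speeds_mps, dtype=float)
    if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
        raise DomainError("speeds must be finite and >= 0")
    # go through integer codes: numpy degrades str-enum scalars to plain
    # strings on masked assignment
    codes = np.full(v.shape, 3, dtype=np.int8)
    codes[v < WALK_MAX_MPS] = 0
    codes[(v >= TROT_MIN_MPS) & (v <= TROT_MAX_MPS)] = 1
    codes[v > GALLOP_MIN_MPS] = 2
    members = (Gait.WALK, Gait.TROT, Gait.GALLOP, Gait.TRANSITION)
    out = np.empty(v.shape, dtype=object)
    out[:] = [members[code] for code in codes]
    return out


def running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running median with a shrinking window at the edges.

    ``window`` must be odd; 1 returns the input unchanged.  Near the edges
    the window is truncated to the available samples, which keeps the filter
    deterministic and length-preserving without inventing padding values.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd and >= 1, got {window}")
    x = np.asarray(values, dtype=float)
    if window == 1 or x.size <= 1:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def label_session(
    session: ExerciseSession, smooth_window: int = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Per-sample gait labels from a running-median of speed.

    A window of 1 disables smoothing; the default window of 3 suppresses
    single-sample GPS jitter without moving bout edges by more than 1 s.
    """
    smoothed = running_median(session.speed_mps, smooth_window)
    return classify_speeds(smoothed)


@dataclass(frozen=True)
class GaitBout:
    """A maximal run of identically-labelled samples, half-open [start, end)."""

    label: Gait
    start_s: int
    end_s: int
    n_samples: int
    mean_hr_bpm: float
    mean_speed_mps: float
    distance_m: float

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class RaceSegment:
    """One race: a gallop-dominated span, half-open [start, end), 1-based index."""

    index: int
    start_s: int
    end_s: int
    distance_m: float

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j) of maximal equal-label runs."""
    n = len(labels)
    if n == 0:
        return []
    boundaries = [0]
    for i in range(1, n):
        if labels[i] != labels[i - 1]:
            boundaries.append(i)
    boundaries.append(n)
    return [(boundaries[k], boundaries[k + 1]) for k in range(len(boundaries) - 1)]


def extract_bouts(session: ExerciseSession, labels: Sequence[Gait]) -> list[GaitBout]:
    """Collapse per-sample labels into maximal gait bouts.

    Bouts tile the session: the union of [start, end) spans covers every
    sample exactly once, and per-bout sample counts, durations and distances
    sum to the session totals.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != session.n_samples:
        raise AlignmentError(
            f"labels ({labels.size}) not aligned to samples ({session.n_samples})"
        )
    t = session.t_s
    increments = session.distance_increments()
    bouts = []
    for i, j in _runs(labels):
        bouts.append(
            GaitBout(
                label=labels[i],
                start_s=int(t[i]),
                end_s=int(t[j - 1]) + 1,
                n_samples=j - i,
                mean_hr_bpm=float(np.mean(session.hr_bpm[i:j])),
                mean_speed_mps=float(np.mean(session.speed_mps[i:j])),
                distance_m=float(np.sum(increments[i:j])),
            )
        )
    return bouts


def detect_races(
    session: ExerciseSession,
    labels: Sequence[Gait],
    min_gallop_s: int = DEFAULT_MIN_GALLOP_S,
    min_rest_s: int = DEFAULT_MIN_REST_S,
) -> list[RaceSegment]:
    """Find the race structure: gallop spans separated by sufficient rest.

    A race is a maximal gallop-dominated span containing at least
    ``min_gallop_s`` consecutive gallop samples; gallop spans whose
    separating non-gallop gap is shorter than ``min_rest_s`` are merged into
    one race.  Returns races in time order with 1-based indices (empty list
    when nothing qualifies).
    """
    if min_gallop_s < 1 or min_rest_s < 1:
        raise ParameterError("min_gallop_s and min_rest_s must be >= 1")
    labels = np.asarray(labels, dtype=object)
    if labels.size != session.n_samples:
        raise AlignmentError(
            f"labels ({labels.size}) not aligned to samples ({session.n_samples})"
        )
    t = session.t_s
    gallop_runs = [(i, j) for i, j in _runs(labels) if labels[i] is Gait.GALLOP]
    if not gallop_runs:
        return []

    # merge runs separated by < min_rest_s of non-gallop time
    merged: list[list[tuple[int, int]]] = [[gallop_runs[0]]]
    for run in gallop_runs[1:]:
        prev_end_t = t[merged[-1][-1][1] - 1] + 1
        gap_s = int(t[run[0]]) - int(prev_end_t)
        if gap_s < min_rest_s:
            merged[-1].append(run)
        else:
            merged.append([run])

    increments = session.distance_increments()
    races = []
    for group in merged:
        longest = max(int(t[j - 1]) + 1 - int(t[i]) for i, j in group)
        if longest < min_gallop_s:
            continue
        i0 = group[0][0]
        j1 = group[-1][1]
        races.append(
            RaceSegment(
                index=len(races) + 1,
                start_s=int(t[i0]),
                end_s=int(t[j1 - 1]) + 1,
                distance_m=float(np.sum(increments[i0:j1])),
            )
        )
    return races


def segments_to_bed(
    session_id: str,
    segments: Sequence[GaitBout] | Sequence[RaceSegment],
    path: str | Path,
) -> None:
    """Export bouts or races as a BED-like TSV (session_id, start_s, end_s, label)."""
    lines = []
    for seg in segments:
        name = seg.label.value if isinstance(seg, GaitBout) else f"race{seg.index}"
        lines.append(f"{session_id}\t{seg.start_s}\t{seg.end_s}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
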