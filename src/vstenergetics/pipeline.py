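"""One-call orchestration: cohort in, report bundle out.

The bundle is a directory of tidy CSVs plus rendered text tables and a
manifest recording the configuration hash, so a rerun on the same inputs
reproduces every file byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from . import __version__
from .energetics import EnergeticsConfig, EnergeticsSummary, summarize_session
from .errors import AnalysisError, StageError, VSTError
from .gait_segmentation import (
    DEFAULT_MIN_GALLOP_S,
    DEFAULT_MIN_REST_S,
    DEFAULT_SMOOTH_WINDOW,
    detect_races,
    label_session,
)
from .group_stats import (
    DEFAULT_ALPHA,
    MeasurementPanel,
    compare_groups,
    summary_table,
)
from .lactate import (
    ANAEROBIC_THRESHOLD_MMOL_L,
    TIMEPOINTS,
    LactateCurve,
    curve_summary,
    read_lactate_csv,
    recovery_assessment,
    threshold_exceedance,
    write_lactate_csv,
)
from .synthetic_data import VSTGeneratorConfig, config_to_dict, generate_cohort, preset
from .telemetry_io import (
    ExerciseSession,
    Role,
    read_metadata,
    read_session_csv,
    write_metadata,
    write_session_csv,
)

__all__ = ["RunConfig", "RunResult", "run_vst_analysis", "write_cohort", "load_cohort"]

logger = logging.getLogger("vstenergetics")

_CELL_VARIABLES = (
    "mean_hr_bpm",
    "mean_speed_mps",
    "ee_J_per_kg_min",
    "cot_scaled",
    "pmet_scaled",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs; exactly one input mode is active."""

    mode: Literal["synthetic", "csv_dir"] = "synthetic"
    input_dir: str | None = None
    out_dir: str = "vst_out"
    generator: VSTGeneratorConfig = field(default_factory=preset)
    energetics: EnergeticsConfig = field(default_factory=EnergeticsConfig)
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    min_gallop_s: int = DEFAULT_MIN_GALLOP_S
    min_rest_s: int = DEFAULT_MIN_REST_S
    alpha: float = DEFAULT_ALPHA
    lactate_tolerance_mmol_l: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv_dir"):
            raise AnalysisError(f"unknown input mode {self.mode!r}")
        if self.mode == "csv_dir" and not self.input_dir:
            raise AnalysisError("csv_dir mode needs input_dir")


@dataclass(frozen=True)
class RunResult:
    out_dir: Path
    n_subjects: int
    n_races_per_subject: dict[str, int]
    files: tuple[str, ...]


def write_cohort(cohort, out_dir: str | Path, manifest: dict | None = None) -> None:
    """Write a cohort as canonical CSVs + metadata sidecars + lactate CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for session in cohort.sessions:
        sid = session.metadata.subject_id
        write_session_csv(session, out / f"{sid}.csv")
        write_metadata(session.metadata, out / f"{sid}.meta")
    write_lactate_csv(cohort.curves, out / "lactate.csv")
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_cohort(input_dir: str | Path) -> tuple[list[ExerciseSession], list[LactateCurve]]:
    """Load sessions (``<id>.csv`` + ``<id>.meta``) and optional ``lactate.csv``."""
    directory = Path(input_dir)
    if not directory.is_dir():
        raise AnalysisError(f"input directory not found: {directory}")
    meta_files = sorted(directory.glob("*.meta"))
    if not meta_files:
        raise AnalysisError(f"no subject metadata (*.meta) files in {directory}")
    sessions = []
    for meta_path in meta_files:
        metadata = read_metadata(meta_path)
        csv_path = meta_path.with_suffix(".csv")
        sessions.append(read_session_csv(csv_path, metadata))
    lactate_path = directory / "lactate.csv"
    curves = read_lactate_csv(lactate_path) if lactate_path.exists() else []
    return sessions, curves


def _config_digest(config: RunConfig) -> str:
    payload = {
        "mode": config.mode,
        "input_dir": config.input_dir,
        "generator": config_to_dict(config.generator),
        "energetics": vars(config.energetics).copy(),
        "smooth_window": config.smooth_window,
        "min_gallop_s": config.min_gallop_s,
        "min_rest_s": config.min_rest_s,
        "alpha": config.alpha,
        "lactate_tolerance_mmol_l": config.lactate_tolerance_mmol_l,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _cell_condition(race: int, gait: str) -> str:
    return f"race{race}_{gait}"


def _stats_rows(result, variable: str) -> list[dict]:
    rows = []
    for condition, outcomes in result.tukey.items():
        for outcome in outcomes:
            rows.append(
                {
                    "variable": variable,
                    "condition": condition,
                    "group_a": outcome.group_a,
                    "group_b": outcome.group_b,
                    "mean_a": result.means.at[outcome.group_a, condition],
                    "sd_a": result.sds.at[outcome.group_a, condition],
                    "mean_b": result.means.at[outcome.group_b, condition],
                    "sd_b": result.sds.at[outcome.group_b, condition],
                    "difference": outcome.difference,
                    "p_adj": outcome.p_adj,
                    "significant": outcome.significant,
                    "condition_F": result.f_statistic,
                    "condition_p": result.p_value,
                }
            )
    return rows


def run_vst_analysis(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the report bundle.

    Stages: input (generate or load) → segmentation → energetics →
    statistics → lactate → render.  Any stage failure propagates as
    :class:`StageError` naming the stage and subject; nothing is written
    until all per-subject computation has succeeded.
    """
    out = Path(config.out_dir)

    # -- stage: input ------------------------------------------------------
    if config.mode == "synthetic":
        cohort = generate_cohort(config.generator)
        sessions, curves = cohort.sessions, cohort.curves
    else:
        sessions, curves = load_cohort(config.input_dir)
    logger.info("loaded %d sessions, %d lactate curves", len(sessions), len(curves))

    # -- stages: segmentation + energetics (per subject) -------------------
    summaries: list[EnergeticsSummary] = []
    roles: dict[str, str] = {}
    race_counts: dict[str, int] = {}
    clamp_warnings = 0
    high_transition: list[str] = []
    for session in sessions:
        sid = session.metadata.subject_id
        roles[sid] = session.metadata.role.value
        try:
            labels = label_session(session, config.smooth_window)
            races = detect_races(session, labels, config.min_gallop_s, config.min_rest_s)
        except VSTError as exc:
            raise StageError("segmentation", sid, exc) from exc
        race_counts[sid] = len(races)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                summary = summarize_session(session, labels, races, config.energetics)
            clamp_warnings += sum("clamping" in str(w.message) for w in caught)
        except VSTError as exc:
            raise StageError("energetics", sid, exc) from exc
        if summary.transition_fraction > 0.10:
            high_transition.append(sid)
        summaries.append(summary)
        logger.info("subject %s: %d races, transition fraction %.3f",
                    sid, len(races), summary.transition_fraction)

    cells = pd.concat(
        [s.cells.assign(subject_id=s.subject_id, role=roles[s.subject_id]) for s in summaries],
        ignore_index=True,
    )
    metric_cols = [c for c in cells.columns if c not in ("subject_id", "role", "race", "gait")]
    cells = cells[["subject_id", "role", "race", "gait"] + metric_cols]
    totals = pd.DataFrame(
        [{"subject_id": s.subject_id, "role": roles[s.subject_id],
          "mass_kg": s.mass_kg, "cot_mode": s.cot_mode,
          "transition_fraction": s.transition_fraction, **s.totals.to_dict()}
         for s in summaries]
    )

    # -- stage: statistics --------------------------------------------------
    stats_rows: list[dict] = []
    rendered: list[str] = []
    role_series = pd.Series({s.subject_id: roles[s.subject_id] for s in summaries},
                            name="role").sort_index()
    can_compare = bool(
        role_series.value_counts().ge(2).reindex(["PH", "HH"]).fillna(False).all()
        and role_series.nunique() == 2
    )
    if can_compare:
        for variable in _CELL_VARIABLES:
            wide = cells.pivot_table(index="subject_id", columns=["race", "gait"],
                                     values=variable, aggfunc="first", observed=True)
            wide.columns = [_cell_condition(r, g) for r, g in wide.columns]
            wide = wide.dropna(axis=1).sort_index()
            if wide.empty or wide.shape[1] == 0:
                continue
            panel = MeasurementPanel(variable=variable, data=wide,
                                     groups=role_series.loc[wide.index])
            result = compare_groups(panel, alpha=config.alpha)
            stats_rows.extend(_stats_rows(result, variable))
            table = summary_table(panel, result)
            rendered.append(f"## {variable} (per race x gait)\n{table.to_string()}\n")
        # session totals: one condition per variable
        totals_wide = totals.set_index("subject_id").sort_index()
        for variable in _CELL_VARIABLES:
            panel = MeasurementPanel(
                variable=f"total_{variable}",
                data=totals_wide[[variable]].rename(columns={variable: "total"}),
                groups=role_series.loc[totals_wide.index],
            )
            result = compare_groups(panel, alpha=config.alpha)
            stats_rows.extend(_stats_rows(result, f"total_{variable}"))
            table = summary_table(panel, result)
            rendered.append(f"## total {variable}\n{table.to_string()}\n")
    else:
        logger.warning("fewer than 2 subjects per role; skipping group statistics")

    # -- stage: lactate ------------------------------------------------------
    lactate_rows: list[dict] = []
    lactate_rendered = ""
    for curve in curves:
        summary = curve_summary(curve)
        exceeds = threshold_exceedance(curve, ANAEROBIC_THRESHOLD_MMOL_L)
        recovered = recovery_assessment(curve, config.lactate_tolerance_mmol_l)
        lactate_rows.append(
            {
                "subject_id": curve.subject_id,
                "role": curve.role.value,
                "baseline_mmol_l": summary.baseline_mmol_l,
                "peak_mmol_l": summary.peak_mmol_l,
                "peak_timepoint": summary.peak_timepoint,
                "delta_mmol_l": summary.delta_mmol_l,
                "above_threshold": ";".join(sorted(exceeds)),
                "recovered_at": recovered or "",
            }
        )
    if curves and can_compare and all(set(TIMEPOINTS) <= set(c.labels) for c in curves):
        lac_wide = pd.DataFrame(
            {tp: {c.subject_id: c.values[tp] for c in curves} for tp in TIMEPOINTS}
        ).sort_index()
        lac_roles = pd.Series({c.subject_id: c.role.value for c in curves},
                              name="role").sort_index()
        if lac_roles.value_counts().ge(2).all() and lac_roles.nunique() == 2:
            panel = MeasurementPanel("lactate_mmol_l", lac_wide, lac_roles)
            result = compare_groups(panel, alpha=config.alpha)
            stats_rows.extend(_stats_rows(result, "lactate_mmol_l"))
            lactate_rendered = (
                f"## plasma lactate (mmol/L)\n{summary_table(panel, result, decimals=1).to_string()}\n"
                f"exercise effect: F={result.f_statistic:.2f}, p={result.p_value:.4g}\n"
            )

    # -- stage: render -------------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def _write_csv(frame: pd.DataFrame, name: str) -> None:
        frame.to_csv(out / name, index=False)
        files.append(name)

    _write_csv(cells, "energetics_cells.csv")
    _write_csv(totals, "energetics_totals.csv")
    if stats_rows:
        _write_csv(pd.DataFrame(stats_rows), "stats.csv")
    if lactate_rows:
        _write_csv(pd.DataFrame(lactate_rows), "lactate_summary.csv")
    if curves:
        write_lactate_csv(curves, out / "lactate_curves.csv")
        files.append("lactate_curves.csv")
    table_text = "\n".join(
        [f"# Energetics report (COT mode: {config.energetics.cot_mode}; "
         f"alpha = {config.alpha})", ""] + rendered + [lactate_rendered]
    )
    (out / "tables.txt").write_text(table_text)
    files.append("tables.txt")

    manifest = {
        "software": "vstenergetics",
        "version": __version__,
        "config_sha256": _config_digest(config),
        "mode": config.mode,
        "seed": config.generator.seed if config.mode == "synthetic" else None,
        "cot_mode": config.energetics.cot_mode,
        "alpha": config.alpha,
        "n_subjects": len(sessions),
        "race_counts": race_counts,
        "warnings": {
            "hr_clamped_segments": clamp_warnings,
            "high_transition_subjects": high_transition,
        },
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files.append("manifest.json")
    if clamp_warnings or high_transition:
        logger.warning("warnings: %d clamped segments, high-transition subjects: %s",
                       clamp_warnings, high_transition)
    return RunResult(
        out_dir=out,
        n_subjects=len(sessions),
        n_races_per_subject=race_counts,
        files=tuple(files),
    )
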