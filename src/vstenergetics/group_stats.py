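"""Normality screening, repeated-measures ANOVA, Tukey comparisons and
mean (±SD) report tables.

Two contrast structures are exposed explicitly, because the source analysis
reports a single p per table row without naming its contrast:

* :func:`rm_anova` — within-subject one-way ANOVA of a condition effect on a
  complete subjects x conditions matrix;
* :func:`tukey_pairwise` — between-group pairwise comparison (studentized
  range) at a fixed condition, used for the PH-vs-HH contrasts.

Significance defaults to alpha = 0.05 and no correction is applied across
variables or table rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_lowercase
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, DegenerateInputError, ParameterError

__all__ = [
    "MeasurementPanel",
    "TukeyOutcome",
    "GroupComparisonResult",
    "ks_normality",
    "rm_anova",
    "tukey_pairwise",
    "compare_groups",
    "summary_table",
    "format_mean_sd",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class MeasurementPanel:
    """One variable laid out as a subjects x conditions matrix with group labels.

    ``data``: DataFrame indexed by subject id, one column per condition
    (timepoint or race x gait cell).  ``groups``: Series mapping each subject
    id to its group label (e.g. "PH"/"HH").
    """

    variable: str
    data: pd.DataFrame = field(repr=False)
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.groups.index):
            raise AnalysisError(
                f"panel {self.variable!r}: group labels not aligned to subjects"
            )
        if self.data.shape[1] == 0 or self.data.isna().all(axis=0).any():
            bad = list(self.data.columns[self.data.isna().all(axis=0)])
            raise AnalysisError(
                f"panel {self.variable!r}: condition(s) entirely missing: {bad}"
            )

    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts()


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """One-sample Kolmogorov–Smirnov test against N(sample mean, sample SD).

    Parameters are estimated from the data (no Lilliefors correction), as is
    conventional in the applied literature this mirrors; the p value is
    therefore approximate (conservative).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ParameterError(f"need n >= 3 for a KS test, got n={x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateInputError("sample has zero variance; KS test undefined")
    result = stats.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(result.statistic), float(result.pvalue)


def rm_anova(data: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Within-subject one-way repeated-measures ANOVA for the condition effect.

    ``data`` is a complete subjects x conditions matrix.  Returns (F, p) with
    df = (k - 1, (n - 1)(k - 1)).  A matrix with no condition effect at all
    returns (0, 1).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise AnalysisError("need >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(x)):
        if isinstance(data, pd.DataFrame):
            bad = list(data.index[np.any(~np.isfinite(x), axis=1)])
            raise AnalysisError(f"missing cells for subject(s) {bad}")
        raise AnalysisError("matrix has missing cells")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    if ss_cond <= 0:
        return 0.0, 1.0
    if ss_err <= 0:
        return float("inf"), 0.0
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(stats.f.sf(f, df_cond, df_err))
    return float(f), p


class TukeyOutcome(NamedTuple):
    group_a: str
    group_b: str
    difference: float
    p_adj: float
    significant: bool


def tukey_pairwise(
    groups: Mapping[str, Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> list[TukeyOutcome]:
    """All pairwise mean differences with studentized-range adjusted p values.

    ``significant`` flags p_adj <= alpha.  Outcomes are symmetric in group
    order; ``difference`` is mean(group_a) - mean(group_b) in the mapping's
    iteration order.
    """
    names = list(groups)
    if len(names) < 2:
        raise AnalysisError("need >= 2 groups")
    arrays = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise AnalysisError(f"group {name!r} has n={arr.size} < 2")
        arrays.append(arr)
    result = stats.tukey_hsd(*arrays)
    outcomes = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(np.clip(result.pvalue[i, j], 0.0, 1.0))
            outcomes.append(
                TukeyOutcome(
                    group_a=names[i],
                    group_b=names[j],
                    difference=float(arrays[i].mean() - arrays[j].mean()),
                    p_adj=p_adj,
                    significant=p_adj <= alpha,
                )
            )
    return outcomes


@dataclass(frozen=True)
class GroupComparisonResult:
    """Full comparison for one variable: descriptive stats, condition-effect
    F/p, and per-condition pairwise Tukey outcomes."""

    variable: str
    alpha: float
    means: pd.DataFrame = field(repr=False)  # groups x conditions
    sds: pd.DataFrame = field(repr=False)
    f_statistic: float = float("nan")
    p_value: float = float("nan")
    tukey: dict[str, list[TukeyOutcome]] = field(default_factory=dict, repr=False)


def compare_groups(panel: MeasurementPanel, alpha: float = DEFAULT_ALPHA) -> GroupComparisonResult:
    """Run the full pipeline on a panel.

    The condition effect (F, p) comes from :func:`rm_anova` over all subjects
    pooled; the between-group contrast runs :func:`tukey_pairwise` per
    condition.  Requires >= 2 subjects per group.
    """
    sizes = panel.group_sizes()
    small = sizes[sizes < 2]
    if not small.empty:
        raise AnalysisError(
            f"panel {panel.variable!r}: group(s) with < 2 subjects: {list(small.index)}"
        )
    grouped = panel.data.groupby(panel.groups, observed=True)
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    if panel.data.shape[1] >= 2:
        f, p = rm_anova(panel.data)
    else:
        f, p = float("nan"), float("nan")
    tukey = {
        str(condition): tukey_pairwise(
            {str(g): sub[condition].to_numpy() for g, sub in panel.data.groupby(panel.groups, observed=True)},
            alpha=alpha,
        )
        for condition in panel.data.columns
    }
    return GroupComparisonResult(
        variable=panel.variable,
        alpha=alpha,
        means=means,
        sds=sds,
        f_statistic=f,
        p_value=p,
        tukey=tukey,
    )


def format_mean_sd(mean: float, sd: float, decimals: int = 2) -> str:
    return f"{mean:.{decimals}f} (±{sd:.{decimals}f})"


def _letter_display(
    group_means: pd.Series, outcomes: list[TukeyOutcome]
) -> dict[str, str]:
    """Greedy compact-letter display: groups sharing a letter do not differ.

    Returns an empty string for every group when nothing is significant.
    """
    if not any(o.significant for o in outcomes):
        return {str(g): "" for g in group_means.index}
    differs = {frozenset((o.group_a, o.group_b)) for o in outcomes if o.significant}
    ordered = [str(g) for g in group_means.sort_values(ascending=False).index]
    classes: list[list[str]] = []
    for g in ordered:
        placed = False
        for cls in classes:
            if all(frozenset((g, member)) not in differs for member in cls):
                cls.append(g)
                placed = True
        if not placed:
            classes.append([g])
    letters: dict[str, str] = {g: "" for g in ordered}
    for letter, cls in zip(ascii_lowercase, classes):
        for g in cls:
            letters[g] += letter
    return letters


def summary_table(
    panel: MeasurementPanel,
    result: GroupComparisonResult,
    decimals: int = 2,
) -> pd.DataFrame:
    """Wide "mean (±SD)" table, one row per condition, one column per group.

    Superscript-style letters mark Tukey-significant within-row differences
    (larger mean gets "a"); rows with no significant pair carry no letters.
    """
    rows = {}
    for condition in panel.data.columns:
        outcomes = result.tukey.get(str(condition), [])
        letters = _letter_display(result.means[condition], outcomes)
        row = {}
        for group in result.means.index:
            cell = format_mean_sd(
                result.means.at[group, condition], result.sds.at[group, condition], decimals
            )
            suffix = letters.get(str(group), "")
            row[str(group)] = f"{cell} {suffix}".rstrip()
        rows[str(condition)] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "condition"
    return table
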