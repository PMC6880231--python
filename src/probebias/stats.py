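"""Cohort-level statistics: contingency tables, Pearson chi-square, group summaries.

Participants are split by baseline bias classification (positive vs absent)
and compared on categorical demographics with the uncorrected Pearson
chi-square test, Σ(O−E)²/E with E from the margin products and
df = (R−1)(C−1).  No continuity correction is applied by default — the
journal-style results this pipeline reproduces were computed without one —
but the Yates-corrected variant is available behind a flag.  Expected
counts below 5 trigger a warning rather than an error: these cohorts are
small and sparse tables are the norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .records import BaselineClass, ChangeDirection, ParticipantTimeline
from .scoring import NoPostSessionError, overall_change


class SmallExpectedCountWarning(UserWarning):
    """Some expected cell count is below 5; the chi-square approximation is rough."""


@dataclass
class ContingencyTable:
    """Observed counts of a demographic factor crossed with baseline-bias group."""

    factor_name: str
    row_labels: list[str]
    column_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if (r, c) != (len(self.row_labels), len(self.column_labels)):
            raise ValueError("labels do not match counts shape")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("grand total must be positive")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected_counts: np.ndarray
    min_expected: float

    @property
    def small_expected(self) -> bool:
        return self.min_expected < 5.0


@dataclass
class GroupSummary:
    """Descriptives for one baseline-bias group."""

    label: str
    n: int
    numeric: dict[str, tuple[float, Optional[float]]] = field(default_factory=dict)
    categorical: dict[str, dict[str, int]] = field(default_factory=dict)


def chi_square_upper_tail(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution.

    Computed as the regularized upper incomplete gamma function
    Q(df/2, x/2); monotone decreasing in the statistic.
    """
    if statistic < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {statistic}")
    if df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(special.gammaincc(df / 2.0, statistic / 2.0))


def pearson_chi_square(
    table: ContingencyTable, correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence on an R×C table.

    ``correction=True`` applies the Yates continuity correction (2×2 tables
    only have a conventional use for it, but it is applied cell-wise as
    |O−E|−0.5 whenever requested).  Raises on all-zero rows or columns,
    where the degrees of freedom are undefined.
    """
    obs = table.counts
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if (row_tot == 0).any() or (col_tot == 0).any():
        raise ValueError(
            f"table {table.factor_name!r} has an all-zero row or column; "
            "chi-square is undefined"
        )
    grand = obs.sum()
    expected = np.outer(row_tot, col_tot) / grand
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    min_expected = float(expected.min())
    if min_expected < 5.0:
        warnings.warn(
            f"factor {table.factor_name!r}: minimum expected count "
            f"{min_expected:.2f} < 5; chi-square approximation may be poor",
            SmallExpectedCountWarning,
            stacklevel=2,
        )
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=chi_square_upper_tail(statistic, df),
        expected_counts=expected,
        min_expected=min_expected,
    )


def build_table(
    metadata: pd.DataFrame,
    classifications: Mapping[str, BaselineClass],
    factor_name: str,
    level_map: Optional[Mapping[str, str]] = None,
    levels: Optional[Sequence[str]] = None,
) -> ContingencyTable:
    """Cross-tabulate a demographic factor against baseline-bias group.

    ``level_map`` optionally collapses raw categories into reporting levels;
    an unmapped raw value raises with the offending value named.  ``levels``
    fixes the column order and retains zero-count levels (they are never
    dropped: a level that happens to be empty in one group still contributes
    to the table's shape and df).
    """
    rows = {BaselineClass.POSITIVE: "positive", BaselineClass.ABSENT: "absent"}
    mapped: dict[str, str] = {}
    for pid, raw in zip(
        metadata["participant_id"].astype(str), metadata[factor_name]
    ):
        raw = str(raw)
        if level_map is not None:
            if raw not in level_map:
                raise ValueError(
                    f"factor {factor_name!r}: unmapped level {raw!r} "
                    f"for participant {pid!r}"
                )
            mapped[pid] = level_map[raw]
        else:
            mapped[pid] = raw
    if levels is None:
        seen = []
        for v in mapped.values():
            if v not in seen:
                seen.append(v)
        levels = seen
    counts = np.zeros((2, len(levels)), dtype=float)
    col_index = {lvl: j for j, lvl in enumerate(levels)}
    for pid, cls in classifications.items():
        pid = str(pid)
        if pid not in mapped:
            raise ValueError(
                f"participant {pid!r} classified but absent from metadata"
            )
        lvl = mapped[pid]
        if lvl not in col_index:
            raise ValueError(f"factor {factor_name!r}: unmapped level {lvl!r}")
        i = 0 if cls is BaselineClass.POSITIVE else 1
        counts[i, col_index[lvl]] += 1
    return ContingencyTable(
        factor_name=factor_name,
        row_labels=[rows[BaselineClass.POSITIVE], rows[BaselineClass.ABSENT]],
        column_labels=list(levels),
        counts=counts,
    )


def classify_timelines(
    timelines: Iterable[ParticipantTimeline],
) -> dict[str, BaselineClass]:
    return {t.participant_id: t.baseline_class for t in timelines}


def summarize_groups(
    metadata: pd.DataFrame,
    classifications: Mapping[str, BaselineClass],
    numeric_fields: Sequence[str] = ("age_years", "sds_score"),
    categorical_fields: Sequence[str] = ("substance",),
) -> dict[str, GroupSummary]:
    """Per-group n, mean/SD of numeric fields and level counts of categoricals.

    SD uses the n−1 denominator and is reported as ``None`` (not 0) for a
    single-participant group, where it is undefined.
    """
    meta = metadata.set_index(metadata["participant_id"].astype(str))
    out: dict[str, GroupSummary] = {}
    for cls, label in ((BaselineClass.POSITIVE, "positive"), (BaselineClass.ABSENT, "absent")):
        pids = [p for p, c in classifications.items() if c is cls]
        sub = meta.loc[[str(p) for p in pids]]
        summary = GroupSummary(label=label, n=len(pids))
        for f in numeric_fields:
            if f not in sub.columns:
                continue
            vals = pd.to_numeric(sub[f], errors="coerce").dropna()
            mean = float(vals.mean()) if len(vals) else float("nan")
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else None
            summary.numeric[f] = (mean, sd)
        for f in categorical_fields:
            if f not in sub.columns:
                continue
            summary.categorical[f] = (
                sub[f].astype(str).value_counts().to_dict()
            )
        out[label] = summary
    return out


@dataclass(frozen=True)
class HeadlineProportions:
    """The cohort's headline fractions.

    ``fraction_absent``: share of scored participants with no baseline bias.
    ``fraction_no_reduction_among_positive``: among positive-baseline
    participants with a defined overall change, the share whose bias did not
    decrease (direction increased or unchanged).
    """

    fraction_absent: float
    fraction_no_reduction_among_positive: float
    n_scored: int
    n_absent: int
    n_positive: int
    n_positive_evaluable: int
    no_reduction_ids: tuple[str, ...]


def headline_proportions(
    timelines: Sequence[ParticipantTimeline],
) -> HeadlineProportions:
    if not timelines:
        raise ValueError("need at least one timeline")
    n = len(timelines)
    absent = [t for t in timelines if t.baseline_class is BaselineClass.ABSENT]
    positive = [t for t in timelines if t.baseline_class is BaselineClass.POSITIVE]
    no_reduction = []
    n_evaluable = 0
    for t in positive:
        try:
            change = overall_change(t)
        except NoPostSessionError:
            continue
        n_evaluable += 1
        if change.direction in (ChangeDirection.INCREASED, ChangeDirection.UNCHANGED):
            no_reduction.append(t.participant_id)
    return HeadlineProportions(
        fraction_absent=len(absent) / n,
        fraction_no_reduction_among_positive=(
            len(no_reduction) / n_evaluable if n_evaluable else float("nan")
        ),
        n_scored=n,
        n_absent=len(absent),
        n_positive=len(positive),
        n_positive_evaluable=n_evaluable,
        no_reduction_ids=tuple(sorted(no_reduction)),
    )


def chi_square_battery(
    tables: Iterable[ContingencyTable], correction: bool = False
) -> pd.DataFrame:
    """Run the Pearson test over several factors; one row per factor."""
    rows = []
    for table in tables:
        res = pearson_chi_square(table, correction=correction)
        rows.append(
            {
                "factor": table.factor_name,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "min_expected": res.min_expected,
                "small_expected_warning": res.small_expected,
            }
        )
    return pd.DataFrame(rows)
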