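"""Readers and writers for the pipeline's CSV/JSON dialects.

Trial-log CSV (header required, UTF-8, comma-delimited, "." decimal):

    participant_id,day_index,phase,trial_index,probe_condition,probe_side,rt_ms,correct

with ``phase`` in {baseline_assessment, post_assessment, intervention},
``probe_condition`` in {replaces_substance, replaces_neutral}, ``correct``
in {0, 1}.  Validation errors name the line number and offending field.

The timeline report mirrors the per-participant layout of a session table:
baseline and per-session bias scores (rounded to 1 decimal at this layer
only), the overall change with a direction flag, and missing-reason codes.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    MissingReason,
    ParticipantTimeline,
    Phase,
    ProbeCondition,
    ProbeSide,
    TrialRecord,
)
from .scoring import NoPostSessionError, overall_change

TRIAL_LOG_COLUMNS = [
    "participant_id",
    "day_index",
    "phase",
    "trial_index",
    "probe_condition",
    "probe_side",
    "rt_ms",
    "correct",
]


class TrialLogError(ValueError):
    """A trial-log file is malformed; message carries line number and field."""


def _parse_row(row: dict[str, str], line: int) -> TrialRecord:
    def fail(field: str, msg: str) -> TrialLogError:
        return TrialLogError(f"line {line}, field {field!r}: {msg}")

    pid = row["participant_id"].strip()
    if not pid:
        raise fail("participant_id", "empty")
    try:
        day = int(row["day_index"])
    except ValueError:
        raise fail("day_index", f"not an integer: {row['day_index']!r}") from None
    try:
        phase = Phase(row["phase"])
    except ValueError:
        raise fail("phase", f"unknown phase {row['phase']!r}") from None
    try:
        trial = int(row["trial_index"])
    except ValueError:
        raise fail("trial_index", f"not an integer: {row['trial_index']!r}") from None
    try:
        cond = ProbeCondition(row["probe_condition"])
    except ValueError:
        raise fail(
            "probe_condition", f"unknown condition {row['probe_condition']!r}"
        ) from None
    try:
        side = ProbeSide(row["probe_side"])
    except ValueError:
        raise fail("probe_side", f"unknown side {row['probe_side']!r}") from None
    try:
        rt = float(row["rt_ms"])
    except ValueError:
        raise fail("rt_ms", f"not a number: {row['rt_ms']!r}") from None
    if row["correct"] not in ("0", "1"):
        raise fail("correct", f"must be 0 or 1, got {row['correct']!r}")
    try:
        return TrialRecord(
            participant_id=pid,
            day_index=day,
            phase=phase,
            trial_index=trial,
            probe_condition=cond,
            probe_side=side,
            rt_ms=rt,
            correct=row["correct"] == "1",
        )
    except ValueError as e:
        raise TrialLogError(f"line {line}: {e}") from None


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trial-log CSV."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != TRIAL_LOG_COLUMNS:
            raise TrialLogError(
                f"{path}: bad header {reader.fieldnames}; expected {TRIAL_LOG_COLUMNS}"
            )
        records = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            if None in row or any(v is None for v in row.values()):
                raise TrialLogError(f"line {i}: wrong number of fields")
            records.append(_parse_row(row, i))
    return records


def write_trial_log(trials: Iterable[TrialRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_LOG_COLUMNS)
        for t in trials:
            writer.writerow(
                [
                    t.participant_id,
                    t.day_index,
                    t.phase.value,
                    t.trial_index,
                    t.probe_condition.value,
                    t.probe_side.value,
                    f"{t.rt_ms:.3f}",
                    int(t.correct),
                ]
            )


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False)
    if "participant_id" not in meta.columns:
        raise ValueError(f"{path}: metadata must have a participant_id column")
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index=False)


def timeline_report(
    timelines: Sequence[ParticipantTimeline], precision: int = 1
) -> pd.DataFrame:
    """Tabular report of a scored cohort, one row per participant.

    Scores are rounded here (default 1 decimal); everything upstream keeps
    full precision.  Participants without any observed post-session carry
    empty change columns rather than an error.
    """
    n_slots = max((len(t.post_sessions) for t in timelines), default=0)
    rows = []
    for t in timelines:
        row: dict = {
            "participant_id": t.participant_id,
            "baseline": round(t.baseline_bias_ms, precision),
            "baseline_class": t.baseline_class.value,
        }
        for i in range(n_slots):
            slot = t.post_sessions[i] if i < len(t.post_sessions) else None
            row[f"session_{i + 1}"] = (
                "" if slot is None or slot.missing else round(slot.bias_ms, precision)
            )
            row[f"reason_{i + 1}"] = (
                "" if slot is None or slot.reason is MissingReason.NONE
                else slot.reason.value
            )
        try:
            change = overall_change(t)
            row["overall_change"] = round(change.magnitude_ms, precision)
            row["direction"] = change.direction.value
        except NoPostSessionError:
            row["overall_change"] = ""
            row["direction"] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_timeline_report(
    timelines: Sequence[ParticipantTimeline],
    csv_path: str | Path,
    json_path: str | Path | None = None,
    precision: int = 1,
) -> pd.DataFrame:
    report = timeline_report(timelines, precision=precision)
    report.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(report.to_dict(orient="records"), indent=2) + "\n",
            encoding="utf-8",
        )
    return report


def read_timeline_report(path: str | Path) -> list[ParticipantTimeline]:
    """Rebuild timelines from a timeline-report CSV (scores at report precision)."""
    from .records import SessionSlot

    frame = pd.read_csv(path, dtype={"participant_id": str}, keep_default_na=False)
    session_cols = sorted(
        (c for c in frame.columns if c.startswith("session_")),
        key=lambda c: int(c.split("_")[1]),
    )
    out = []
    for _, row in frame.iterrows():
        slots = []
        for c in session_cols:
            i = c.split("_")[1]
            val = row[c]
            if val == "" or pd.isna(val):
                reason = row.get(f"reason_{i}", "")
                slots.append(
                    SessionSlot(
                        reason=MissingReason(reason) if reason else MissingReason.NONE
                    )
                )
            else:
                slots.append(SessionSlot(bias_ms=float(val)))
        out.append(
            ParticipantTimeline(
                participant_id=str(row["participant_id"]),
                baseline_bias_ms=float(row["baseline"]),
                post_sessions=slots,
            )
        )
    return out
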