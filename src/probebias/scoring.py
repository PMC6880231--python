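"""Scoring of dot-probe trial logs into bias indices and change trajectories.

The attentional-bias index for one assessment block is

    B = T1/n1 − T0/N0   (milliseconds)

where T1, n1 are the summed reaction time and trial count on probes that
replaced the neutral image and T0, N0 the same on probes that replaced the
substance image.  B is the difference of condition means: positive B means
faster responses when the probe replaced the substance image, i.e. attention
preferentially allocated to the substance cue.  Baseline bias is classified
present iff B is strictly positive.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import (
    AssessmentResult,
    BaselineClass,
    ChangeDirection,
    ChangeSummary,
    FilterConfig,
    MissingReason,
    ParticipantTimeline,
    Phase,
    ProbeCondition,
    SessionSlot,
    TrialRecord,
)


class DegenerateBlockError(ValueError):
    """An assessment block has no usable trials in one of the two conditions."""


class NoPostSessionError(ValueError):
    """A timeline has no observed post-session score, so change is undefined."""


def filter_trials(
    trials: Sequence[TrialRecord], cfg: FilterConfig
) -> list[TrialRecord]:
    """Apply RT-window and correctness exclusions; order is preserved.

    The number of removed trials is ``len(trials) - len(result)``.
    """
    return [
        t
        for t in trials
        if cfg.min_rt_ms <= t.rt_ms <= cfg.max_rt_ms
        and (t.correct or not cfg.drop_incorrect)
    ]


def compute_bias_index(
    trials: Iterable[TrialRecord], n_excluded: int = 0
) -> AssessmentResult:
    """Score one (already filtered) assessment block of a single participant.

    Raises :class:`DegenerateBlockError` if either condition has no trials,
    since the bias index is then undefined.
    """
    T1 = 0.0
    n1 = 0
    T0 = 0.0
    N0 = 0
    for t in trials:
        if t.probe_condition is ProbeCondition.REPLACES_NEUTRAL:
            T1 += t.rt_ms
            n1 += 1
        else:
            T0 += t.rt_ms
            N0 += 1
    if n1 == 0 or N0 == 0:
        raise DegenerateBlockError(
            f"bias index undefined: n1={n1} neutral-probe and N0={N0} "
            "substance-probe trials after filtering"
        )
    bias = T1 / n1 - T0 / N0
    return AssessmentResult(
        T1_ms=T1, n1=n1, T0_ms=T0, N0=N0, bias_ms=bias, n_excluded=n_excluded
    )


def score_assessment(
    trials: Sequence[TrialRecord], cfg: Optional[FilterConfig] = None
) -> AssessmentResult:
    """Filter then score one assessment block, recording the exclusion count."""
    cfg = cfg if cfg is not None else FilterConfig()
    kept = filter_trials(trials, cfg)
    return compute_bias_index(kept, n_excluded=len(trials) - len(kept))


def classify_baseline(bias_ms: float) -> BaselineClass:
    """Attentional bias is present iff the baseline score is strictly positive."""
    return BaselineClass.POSITIVE if bias_ms > 0 else BaselineClass.ABSENT


def overall_change(timeline: ParticipantTimeline) -> ChangeSummary:
    """Overall change in attentional bias for one participant.

    The change compares the *latest observed* post-session score with the
    baseline score (intermediate missing sessions are skipped, matching
    how participants with partial data are summarised).  Raises
    :class:`NoPostSessionError` when no post-session score exists.
    """
    observed = timeline.observed_sessions()
    if not observed:
        raise NoPostSessionError(
            f"participant {timeline.participant_id} has no observed "
            "post-session assessment; overall change undefined"
        )
    last = observed[-1][1]
    base = timeline.baseline_bias_ms
    delta = last - base
    if delta > 0:
        direction = ChangeDirection.INCREASED
    elif delta < 0:
        direction = ChangeDirection.DECREASED
    else:
        direction = ChangeDirection.UNCHANGED
    return ChangeSummary(
        magnitude_ms=abs(delta),
        direction=direction,
        last_value_ms=last,
        baseline_value_ms=base,
    )


def _slot_reason(
    slot_day: int,
    dropout_after_day: Optional[int],
    holiday_days: frozenset[int],
) -> MissingReason:
    if slot_day in holiday_days:
        return MissingReason.HOLIDAY
    if dropout_after_day is not None and slot_day > dropout_after_day:
        return MissingReason.DROPOUT
    return MissingReason.NONE


def score_cohort(
    trials: Sequence[TrialRecord],
    metadata: pd.DataFrame,
    cfg: Optional[FilterConfig] = None,
    n_planned_sessions: int = 5,
) -> list[ParticipantTimeline]:
    """Score a whole cohort's trial log into per-participant timelines.

    ``metadata`` must have one row per participant (indexable by
    ``participant_id``) and may carry ``dropout_after_day`` (empty/NaN if the
    participant completed) and ``holiday_days`` (semicolon-separated day
    indices) used to annotate missing slots.  Post-session slot *d* is filled
    by the post-assessment block of day *d*; day 1 runs
    assess → train → assess, so its second assessment is post session 1.

    Raises ``KeyError`` for a participant present in the log but not in the
    metadata, and ``ValueError`` for trials with inconsistent phases.
    """
    cfg = cfg if cfg is not None else FilterConfig()
    meta = metadata.set_index(metadata["participant_id"].astype(str))
    known = set(meta.index)

    by_participant: dict[str, list[TrialRecord]] = defaultdict(list)
    for t in trials:
        by_participant[t.participant_id].append(t)

    timelines: list[ParticipantTimeline] = []
    for pid in sorted(by_participant):
        if pid not in known:
            raise KeyError(
                f"participant {pid!r} appears in the trial log but not in the metadata"
            )
        row = meta.loc[pid]
        dropout = row.get("dropout_after_day")
        dropout = None if dropout is None or pd.isna(dropout) or dropout == "" else int(dropout)
        holidays = row.get("holiday_days", "")
        holiday_days = frozenset(
            int(x) for x in str(holidays).split(";") if x.strip()
        ) if holidays is not None and not pd.isna(holidays) else frozenset()

        blocks: dict[tuple[Phase, int], list[TrialRecord]] = defaultdict(list)
        for t in by_participant[pid]:
            if t.phase is not Phase.INTERVENTION:  # training trials are never scored
                blocks[(t.phase, t.day_index)].append(t)

        baseline_blocks = [
            k for k in blocks if k[0] is Phase.BASELINE_ASSESSMENT
        ]
        if not baseline_blocks:
            raise ValueError(f"participant {pid!r} has no baseline assessment trials")
        if len(baseline_blocks) > 1:
            raise ValueError(
                f"participant {pid!r} has baseline assessments on multiple days"
            )
        baseline_res = score_assessment(blocks[baseline_blocks[0]], cfg)

        slots: list[SessionSlot] = []
        for d in range(1, n_planned_sessions + 1):
            key = (Phase.POST_ASSESSMENT, d)
            if key in blocks:
                res = score_assessment(blocks[key], cfg)
                slots.append(SessionSlot(bias_ms=res.bias_ms, result=res))
            else:
                slots.append(
                    SessionSlot(reason=_slot_reason(d, dropout, holiday_days))
                )
        timelines.append(
            ParticipantTimeline(
                participant_id=pid,
                baseline_bias_ms=baseline_res.bias_ms,
                post_sessions=slots,
                baseline_result=baseline_res,
            )
        )
    return timelines
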