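"""Core domain types for dot-probe attention-bias analysis.

The dot-probe (visual probe) task presents a substance/neutral image pair
after a fixation cross; a probe then replaces one of the images and the
participant indicates its position as fast as possible.  Faster responses
when the probe replaces the substance image indicate attention captured by
the substance cue.  These records model single trials, scored assessment
blocks, and per-participant session timelines.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional


class Phase(str, enum.Enum):
    """Which block of the daily schedule a trial belongs to."""

    BASELINE_ASSESSMENT = "baseline_assessment"
    POST_ASSESSMENT = "post_assessment"
    INTERVENTION = "intervention"


class ProbeCondition(str, enum.Enum):
    """Which image the probe replaced on this trial."""

    REPLACES_SUBSTANCE = "replaces_substance"
    REPLACES_NEUTRAL = "replaces_neutral"


class ProbeSide(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class MissingReason(str, enum.Enum):
    """Why a planned post-session assessment slot has no score."""

    NONE = "none"
    DROPOUT = "dropout"
    HOLIDAY = "holiday"
    TECHNICAL = "technical"


class BaselineClass(str, enum.Enum):
    """Baseline attentional-bias classification: present iff strictly positive."""

    POSITIVE = "positive"
    ABSENT = "absent"


class ChangeDirection(str, enum.Enum):
    DECREASED = "decreased"
    INCREASED = "increased"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class TrialRecord:
    """One dot-probe trial.

    ``rt_ms`` is the reaction time to locate the probe, in milliseconds.
    Intervention (training) trials always have the probe replacing the
    neutral image — that is what retrains attention away from the cue —
    so a substance-probe intervention trial is rejected as malformed.
    """

    participant_id: str
    day_index: int
    phase: Phase
    trial_index: int
    probe_condition: ProbeCondition
    probe_side: ProbeSide
    rt_ms: float
    correct: bool

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if not (self.rt_ms > 0 and math.isfinite(self.rt_ms)):
            raise ValueError(f"rt_ms must be a positive finite number, got {self.rt_ms}")
        if (
            self.phase is Phase.INTERVENTION
            and self.probe_condition is not ProbeCondition.REPLACES_NEUTRAL
        ):
            raise ValueError(
                "intervention trials must have probe_condition=replaces_neutral"
            )


@dataclass(frozen=True)
class AssessmentResult:
    """Scored assessment block.

    Follows the T1/n1/T0/N0 decomposition of the bias index:
    ``T1_ms`` and ``n1`` are the summed RT and trial count for probes that
    replaced the *neutral* image; ``T0_ms`` and ``N0`` for probes that
    replaced the *substance* image.  ``bias_ms = T1_ms/n1 − T0_ms/N0``:
    positive means the participant was faster when the probe replaced the
    substance image, i.e. attention was already on the substance cue.
    """

    T1_ms: float
    n1: int
    T0_ms: float
    N0: int
    bias_ms: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.N0 < 0 or self.n_excluded < 0:
            raise ValueError("trial counts must be non-negative")

    @property
    def neutral_mean_ms(self) -> float:
        return self.T1_ms / self.n1

    @property
    def substance_mean_ms(self) -> float:
        return self.T0_ms / self.N0


@dataclass(frozen=True)
class FilterConfig:
    """Trial-level exclusion rules applied before scoring a block.

    Defaults follow common dot-probe practice (drop RTs outside
    200–2000 ms and error trials); they are fully configurable and
    :meth:`none` disables filtering entirely.
    """

    min_rt_ms: float = 200.0
    max_rt_ms: float = 2000.0
    drop_incorrect: bool = True

    def __post_init__(self) -> None:
        if not self.min_rt_ms < self.max_rt_ms:
            raise ValueError(
                f"min_rt_ms ({self.min_rt_ms}) must be < max_rt_ms ({self.max_rt_ms})"
            )

    @classmethod
    def none(cls) -> "FilterConfig":
        """A configuration that excludes nothing."""
        return cls(min_rt_ms=1e-12, max_rt_ms=math.inf, drop_incorrect=False)


@dataclass
class SessionSlot:
    """One planned post-session assessment slot: a score or a missing marker."""

    bias_ms: Optional[float] = None
    reason: MissingReason = MissingReason.NONE
    result: Optional[AssessmentResult] = None

    @property
    def missing(self) -> bool:
        return self.bias_ms is None


@dataclass
class ParticipantTimeline:
    """Ordered per-session bias scores for one participant.

    ``post_sessions`` has one slot per planned session; a missing slot
    carries a :class:`MissingReason`.  Scores are kept at full precision;
    rounding to one decimal happens only in the report layer.
    """

    participant_id: str
    baseline_bias_ms: float
    post_sessions: list[SessionSlot] = field(default_factory=list)
    baseline_result: Optional[AssessmentResult] = None

    @property
    def baseline_class(self) -> BaselineClass:
        from .scoring import classify_baseline

        return classify_baseline(self.baseline_bias_ms)

    def observed_sessions(self) -> list[tuple[int, float]]:
        """(1-based slot index, bias) pairs for non-missing slots, in order."""
        return [
            (i + 1, s.bias_ms)
            for i, s in enumerate(self.post_sessions)
            if not s.missing
        ]


@dataclass(frozen=True)
class ChangeSummary:
    """Overall change in attentional bias: last observed post-session vs baseline."""

    magnitude_ms: float
    direction: ChangeDirection
    last_value_ms: float
    baseline_value_ms: float

    def __post_init__(self) -> None:
        if self.magnitude_ms < 0:
            raise ValueError("magnitude_ms must be non-negative")
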