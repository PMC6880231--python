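"""Synthetic dot-probe cohort generator.

Generates trial-level reaction-time logs and participant metadata with the
statistical structure the scoring pipeline assumes, so the whole analysis is
testable without access to any real behavioural data.

Generative model
----------------
Reaction times are ex-Gaussian — the sum of a Gaussian (``rt_mu_ms``,
``rt_sigma_ms``) and an exponential (``rt_tau_ms``) component, the standard
family for response-time data (mean = mu + tau).  A participant's current
attentional bias ``b`` enters as a symmetric location shift: neutral-probe
trials are slowed by ``+b/2`` and substance-probe trials sped up by
``-b/2``, so the condition-mean difference equals ``b`` by construction and
the scored bias index is an unbiased estimate of the simulated truth.

The schedule mirrors an inpatient attention-bias-modification protocol:
day 1 runs assessment → intervention → assessment (the second assessment is
"post session 1"), each later day runs intervention → assessment.  After
every completed intervention block the current bias drops by a per-profile
``training_decrement_ms`` (linear decay, chosen for a closed-form
trajectory).  Dropout is a per-day hazard; holiday days emit no blocks.

A single seed drives everything; per-participant streams are spawned
hierarchically so adding participants never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import Phase, ProbeCondition, ProbeSide, TrialRecord

# Demographic marginals of the cohort being emulated: 30 inpatients in the
# rehabilitation phase of addiction treatment in Singapore (alcohol, opioid,
# cannabis or stimulant use disorder).  Counts are cohort totals per level.
DEFAULT_DEMOGRAPHIC_MARGINALS: dict[str, dict[str, int]] = {
    "substance": {"Alcohol": 6, "Opioids": 17, "Cannabis": 2, "Stimulants": 5},
    "nationality": {"Singaporean": 27, "Others": 3},
    "gender": {"Male": 26, "Female": 4},
    "race": {"Chinese": 7, "Malay": 13, "Indian": 9, "Others": 2},
    "education": {
        "Primary education": 7,
        "Secondary education": 16,
        "Junior college or polytechnic/technical studies": 5,
        "Undergraduate studies": 2,
    },
    "employment": {"Unemployed": 23, "Part-time employment": 3, "Full-time employment": 4},
    "housing": {
        "Homeless": 6,
        "1 room": 8,
        "2 rooms": 2,
        "3 rooms": 3,
        "4 rooms": 7,
        "5 rooms": 2,
        "Others": 2,
    },
    "psychiatric_disorder": {"Yes": 3, "No": 27},
    "physical_disorder": {"Yes": 11, "No": 19},
}


@dataclass(frozen=True)
class StudySchedule:
    """Planned block layout of the study.

    Five planned weekdays: day 1 contributes the baseline assessment and
    (after training) post session 1; days 2–5 contribute post sessions 2–5,
    giving the six assessment values a completed timeline carries.
    ``trials_per_assessment`` must be even so the probe replaces each image
    type equally often within an assessment block.
    """

    n_planned_days: int = 5
    trials_per_assessment: int = 40
    trials_per_intervention: int = 80
    holiday_days: frozenset[int] = frozenset()

    day1_blocks = (Phase.BASELINE_ASSESSMENT, Phase.INTERVENTION, Phase.POST_ASSESSMENT)
    later_day_blocks = (Phase.INTERVENTION, Phase.POST_ASSESSMENT)

    def __post_init__(self) -> None:
        if self.n_planned_days < 1:
            raise ValueError("n_planned_days must be >= 1")
        if self.trials_per_assessment % 2 != 0 or self.trials_per_assessment < 2:
            raise ValueError("trials_per_assessment must be a positive even integer")
        if self.trials_per_intervention < 1:
            raise ValueError("trials_per_intervention must be >= 1")
        object.__setattr__(self, "holiday_days", frozenset(self.holiday_days))


@dataclass
class ParticipantProfile:
    """Synthetic ground truth for one participant.

    ``true_bias_ms`` is the expected neutral-probe mean RT minus the
    substance-probe mean RT at baseline (0 for participants without any
    underlying bias).  ``training_decrement_ms`` is subtracted from the
    current bias after each completed intervention block.
    """

    participant_id: str
    true_bias_ms: float
    training_decrement_ms: float
    rt_mu_ms: float
    rt_sigma_ms: float
    rt_tau_ms: float
    lapse_rate: float
    dropout_after_day: Optional[int]
    demographics: dict[str, str]
    sds_score: int
    age_years: int

    def __post_init__(self) -> None:
        if self.rt_sigma_ms <= 0 or self.rt_tau_ms <= 0:
            raise ValueError("rt_sigma_ms and rt_tau_ms must be positive")
        if not (0 <= self.lapse_rate < 1):
            raise ValueError("lapse_rate must be in [0, 1)")


@dataclass
class ProfileDistribution:
    """How :func:`draw_profiles` samples participant ground truth.

    ``zero_bias_weight`` is the mixture weight of participants with no
    underlying bias (default 16/30, the fraction observed in the cohort
    being emulated); the rest draw a strictly positive baseline bias as
    ``|Normal(bias_mean_ms, bias_sd_ms)|``.  ``dropout_hazard`` is the
    per-day probability of leaving after a completed day, calibrated so
    roughly 11 of 30 participants fail to complete a five-day schedule.
    """

    zero_bias_weight: float = 16 / 30
    bias_mean_ms: float = 60.0
    bias_sd_ms: float = 70.0
    decrement_mean_ms: float = 25.0
    decrement_sd_ms: float = 10.0
    dropout_hazard: float = 0.108
    rt_mu_mean_ms: float = 450.0
    rt_mu_sd_ms: float = 50.0
    rt_sigma_mean_ms: float = 40.0
    rt_sigma_sd_ms: float = 10.0
    rt_tau_mean_ms: float = 60.0
    rt_tau_sd_ms: float = 15.0
    lapse_low: float = 0.01
    lapse_high: float = 0.08
    age_mean: float = 46.0
    age_sd: float = 11.6
    sds_mean: float = 10.6
    sds_sd: float = 3.3
    demographic_marginals: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_DEMOGRAPHIC_MARGINALS.items()
        }
    )

    def __post_init__(self) -> None:
        for name in ("zero_bias_weight", "dropout_hazard"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.lapse_low <= self.lapse_high < 1.0):
            raise ValueError("lapse rates must satisfy 0 <= low <= high < 1")
        for factor, levels in self.demographic_marginals.items():
            if not levels or any(c < 0 for c in levels.values()) or sum(levels.values()) == 0:
                raise ValueError(f"invalid marginal counts for factor {factor!r}")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort run."""

    n_participants: int = 30
    seed: int = 0
    schedule: StudySchedule = field(default_factory=StudySchedule)
    profiles: ProfileDistribution = field(default_factory=ProfileDistribution)
    bias_floor_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def draw_profiles(cfg: SimulationConfig) -> list[ParticipantProfile]:
    """Draw the cohort's ground-truth profiles, deterministically from the seed."""
    dist = cfg.profiles
    profiles = []
    for i in range(cfg.n_participants):
        # explicit spawn key: participant i's streams never depend on cohort size
        child = np.random.SeedSequence(cfg.seed, spawn_key=(i, 0))
        rng = np.random.Generator(np.random.PCG64(child))
        pid = f"{i + 1:03d}"
        zero_bias = rng.random() < dist.zero_bias_weight
        if zero_bias:
            bias = 0.0
        else:
            bias = abs(rng.normal(dist.bias_mean_ms, dist.bias_sd_ms))
            bias = max(bias, 1e-6)  # strictly positive by definition of the mixture
        decrement = rng.normal(dist.decrement_mean_ms, dist.decrement_sd_ms)
        mu = max(rng.normal(dist.rt_mu_mean_ms, dist.rt_mu_sd_ms), 200.0)
        sigma = max(rng.normal(dist.rt_sigma_mean_ms, dist.rt_sigma_sd_ms), 5.0)
        tau = max(rng.normal(dist.rt_tau_mean_ms, dist.rt_tau_sd_ms), 5.0)
        lapse = rng.uniform(dist.lapse_low, dist.lapse_high)

        dropout: Optional[int] = None
        for day in range(1, cfg.schedule.n_planned_days):
            if rng.random() < dist.dropout_hazard:
                dropout = day
                break

        demographics = {}
        for factor, levels in dist.demographic_marginals.items():
            names = list(levels)
            counts = np.array([levels[n] for n in names], dtype=float)
            demographics[factor] = str(rng.choice(names, p=counts / counts.sum()))

        age = int(np.clip(round(rng.normal(dist.age_mean, dist.age_sd)), 21, 65))
        sds = int(np.clip(round(rng.normal(dist.sds_mean, dist.sds_sd)), 0, 15))
        profiles.append(
            ParticipantProfile(
                participant_id=pid,
                true_bias_ms=bias,
                training_decrement_ms=decrement,
                rt_mu_ms=mu,
                rt_sigma_ms=sigma,
                rt_tau_ms=tau,
                lapse_rate=lapse,
                dropout_after_day=dropout,
                demographics=demographics,
                sds_score=sds,
                age_years=age,
            )
        )
    return profiles


def _ex_gaussian(profile: ParticipantProfile, rng: np.random.Generator, size=None):
    return rng.normal(profile.rt_mu_ms, profile.rt_sigma_ms, size) + rng.exponential(
        profile.rt_tau_ms, size
    )


def simulate_trial(
    profile: ParticipantProfile,
    current_bias_ms: float,
    condition: ProbeCondition,
    rng: np.random.Generator,
    *,
    day_index: int = 1,
    phase: Phase = Phase.BASELINE_ASSESSMENT,
    trial_index: int = 1,
) -> TrialRecord:
    """Draw one trial; the bias shifts the two conditions by ±bias/2."""
    if not math.isfinite(current_bias_ms):
        raise ValueError("current_bias_ms must be finite")
    shift = current_bias_ms / 2.0
    if condition is ProbeCondition.REPLACES_SUBSTANCE:
        shift = -shift
    rt = float(_ex_gaussian(profile, rng)) + shift
    return TrialRecord(
        participant_id=profile.participant_id,
        day_index=day_index,
        phase=phase,
        trial_index=trial_index,
        probe_condition=condition,
        probe_side=ProbeSide.LEFT if rng.random() < 0.5 else ProbeSide.RIGHT,
        rt_ms=max(rt, 0.5),
        correct=bool(rng.random() >= profile.lapse_rate),
    )


def _simulate_block(
    profile: ParticipantProfile,
    current_bias_ms: float,
    phase: Phase,
    day_index: int,
    n_trials: int,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Vectorised block draw; assessment blocks split conditions 50/50."""
    if phase is Phase.INTERVENTION:
        conditions = np.zeros(n_trials, dtype=bool)  # all replaces_neutral
    else:
        half = n_trials // 2
        conditions = rng.permutation(
            np.array([False] * half + [True] * (n_trials - half))
        )  # True = replaces_substance
    shift = np.where(conditions, -current_bias_ms / 2.0, current_bias_ms / 2.0)
    if phase is Phase.INTERVENTION:
        shift = np.zeros(n_trials)  # no bias read-out: probe never varies
    rts = np.maximum(_ex_gaussian(profile, rng, n_trials) + shift, 0.5)
    sides = rng.random(n_trials) < 0.5
    correct = rng.random(n_trials) >= profile.lapse_rate
    return [
        TrialRecord(
            participant_id=profile.participant_id,
            day_index=day_index,
            phase=phase,
            trial_index=i + 1,
            probe_condition=(
                ProbeCondition.REPLACES_SUBSTANCE
                if conditions[i]
                else ProbeCondition.REPLACES_NEUTRAL
            ),
            probe_side=ProbeSide.LEFT if sides[i] else ProbeSide.RIGHT,
            rt_ms=float(rts[i]),
            correct=bool(correct[i]),
        )
        for i in range(n_trials)
    ]


def simulate_participant(
    profile: ParticipantProfile,
    schedule: StudySchedule,
    rng: np.random.Generator,
    bias_floor_ms: Optional[float] = None,
) -> tuple[list[TrialRecord], dict, list[dict]]:
    """Simulate one participant's study: trials, a metadata row, craving ratings.

    The current bias starts at ``true_bias_ms`` and drops by the training
    decrement after every completed intervention block (optionally floored).
    No blocks are emitted on holiday days or after the dropout day.
    """
    trials: list[TrialRecord] = []
    bias = profile.true_bias_ms
    craving = float(rng.uniform(30, 85))
    craving_rows = []
    for day in range(1, schedule.n_planned_days + 1):
        if profile.dropout_after_day is not None and day > profile.dropout_after_day:
            break
        if day in schedule.holiday_days:
            continue
        blocks = schedule.day1_blocks if day == 1 else schedule.later_day_blocks
        vas_pre = float(np.clip(craving + rng.normal(0, 5), 0, 100))
        for phase in blocks:
            n = (
                schedule.trials_per_intervention
                if phase is Phase.INTERVENTION
                else schedule.trials_per_assessment
            )
            trials.extend(_simulate_block(profile, bias, phase, day, n, rng))
            if phase is Phase.INTERVENTION:
                bias -= profile.training_decrement_ms
                if bias_floor_ms is not None:
                    bias = max(bias, bias_floor_ms)
        craving = max(craving - rng.uniform(0, 4), 0.0)  # slow drift over admission
        vas_post = float(np.clip(craving + rng.normal(0, 5), 0, 100))
        craving_rows.append(
            {
                "participant_id": profile.participant_id,
                "day_index": day,
                "vas_pre": round(vas_pre, 1),
                "vas_post": round(vas_post, 1),
            }
        )

    meta = {
        "participant_id": profile.participant_id,
        **profile.demographics,
        "age_years": profile.age_years,
        "sds_score": profile.sds_score,
        "true_bias_ms": profile.true_bias_ms,
        "training_decrement_ms": profile.training_decrement_ms,
        "rt_mu_ms": profile.rt_mu_ms,
        "rt_sigma_ms": profile.rt_sigma_ms,
        "rt_tau_ms": profile.rt_tau_ms,
        "lapse_rate": profile.lapse_rate,
        "dropout_after_day": (
            "" if profile.dropout_after_day is None else profile.dropout_after_day
        ),
        "holiday_days": ";".join(str(d) for d in sorted(schedule.holiday_days)),
    }
    return trials, meta, craving_rows


@dataclass
class SimulatedCohort:
    """In-memory result of :func:`simulate_cohort`."""

    trials: list[TrialRecord]
    metadata: pd.DataFrame
    craving: pd.DataFrame
    profiles: list[ParticipantProfile]


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Simulate the whole cohort, reproducibly from ``cfg.seed``.

    Each participant gets an independent spawned random stream, so the data
    of participants 1..k are identical for any ``n_participants >= k``.
    """
    profiles = draw_profiles(cfg)
    all_trials: list[TrialRecord] = []
    meta_rows = []
    craving_rows = []
    for i, profile in enumerate(profiles):
        # per-participant trial-noise stream, independent of the profile stream
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(cfg.seed, spawn_key=(i, 1)))
        )
        trials, meta, craving = simulate_participant(
            profile, cfg.schedule, rng, cfg.bias_floor_ms
        )
        all_trials.extend(trials)
        meta_rows.append(meta)
        craving_rows.extend(craving)
    return SimulatedCohort(
        trials=all_trials,
        metadata=pd.DataFrame(meta_rows),
        craving=pd.DataFrame(craving_rows),
        profiles=profiles,
    )


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Plain-dict form of a config, suitable for YAML/JSON serialisation."""
    d = asdict(cfg)
    d["schedule"]["holiday_days"] = sorted(cfg.schedule.holiday_days)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    sched = dict(d.pop("schedule", {}))
    if "holiday_days" in sched:
        sched["holiday_days"] = frozenset(int(x) for x in sched["holiday_days"])
    prof = dict(d.pop("profiles", {}))
    return SimulationConfig(
        schedule=StudySchedule(**sched),
        profiles=ProfileDistribution(**prof),
        **d,
    )
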