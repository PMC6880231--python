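import numpy as np
import pytest
from hypothesis import settings

from probebias import (
    ParticipantProfile,
    Phase,
    ProbeCondition,
    ProbeSide,
    TrialRecord,
    load_fixtures,
)

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


def make_trial(
    rt_ms,
    condition=ProbeCondition.REPLACES_NEUTRAL,
    correct=True,
    participant_id="p01",
    day_index=1,
    phase=Phase.BASELINE_ASSESSMENT,
    trial_index=1,
    probe_side=ProbeSide.LEFT,
):
    return TrialRecord(
        participant_id=participant_id,
        day_index=day_index,
        phase=phase,
        trial_index=trial_index,
        probe_condition=condition,
        probe_side=probe_side,
        rt_ms=rt_ms,
        correct=correct,
    )


def make_block(neutral_rts, substance_rts, **kwargs):
    """An assessment block from two RT lists, one per probe condition."""
    trials = []
    for i, rt in enumerate(neutral_rts):
        trials.append(
            make_trial(rt, ProbeCondition.REPLACES_NEUTRAL, trial_index=i + 1, **kwargs)
        )
    for i, rt in enumerate(substance_rts):
        trials.append(
            make_trial(
                rt,
                ProbeCondition.REPLACES_SUBSTANCE,
                trial_index=len(neutral_rts) + i + 1,
                **kwargs,
            )
        )
    return trials


def make_profile(
    participant_id="p01",
    true_bias_ms=50.0,
    training_decrement_ms=0.0,
    rt_mu_ms=450.0,
    rt_sigma_ms=40.0,
    rt_tau_ms=60.0,
    lapse_rate=0.0,
    dropout_after_day=None,
):
    return ParticipantProfile(
        participant_id=participant_id,
        true_bias_ms=true_bias_ms,
        training_decrement_ms=training_decrement_ms,
        rt_mu_ms=rt_mu_ms,
        rt_sigma_ms=rt_sigma_ms,
        rt_tau_ms=rt_tau_ms,
        lapse_rate=lapse_rate,
        dropout_after_day=dropout_after_day,
        demographics={},
        sds_score=10,
        age_years=45,
    )


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def fixture_timelines(fixtures):
    return fixtures.timelines()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
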