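import numpy as np
import pandas as pd
import pytest

from ethofeed import (
    BehavioralEvent,
    ConditionLabel,
    FeedingStep,
    Observation,
    simulate_dataset,
)


def make_observation(obs_id="o1", subject="s1", steps=None, condition=None, window_s=120.0):
    """Build an observation from (step, onset, offset) triples; contact is implicit."""
    events = [BehavioralEvent(FeedingStep.CONTACT, 0.0, 0.0)]
    for step, onset, offset in steps or []:
        events.append(BehavioralEvent(step, onset, offset))
    return Observation(obs_id, subject, condition or ConditionLabel(), events, window_s)


def full_sequence_observation(obs_id="o1", subject="s1", condition=None):
    return make_observation(
        obs_id,
        subject,
        [
            (FeedingStep.PARALYZE, 4.0, None),
            (FeedingStep.TCR, 9.0, 11.5),
            (FeedingStep.BEND, 13.0, 16.0),
            (FeedingStep.INGEST, 20.0, 45.0),
        ],
        condition,
    )


@pytest.fixture
def event_table_df():
    """Minimal well-formed long-format table: one complete observation."""
    return pd.DataFrame(
        {
            "observation_id": ["a", "a"],
            "subject_id": ["s1", "s1"],
            "feeding_state": ["starved", "starved"],
            "preparation": ["intact", "intact"],
            "tentacle_use": ["na", "na"],
            "minutes_since_meal": [None, None],
            "step": ["contact", "paralyze"],
            "onset_s": [0.0, 3.0],
            "offset_s": [None, None],
        }
    )


@pytest.fixture(scope="session")
def starved_dataset():
    observations, truth = simulate_dataset("starved", seed=11)
    return observations, truth


@pytest.fixture(scope="session")
def fed_dataset():
    observations, truth = simulate_dataset("fed", seed=12)
    return observations, truth
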