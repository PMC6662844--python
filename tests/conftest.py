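import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from foragetails import (
    Event,
    Participant,
    SearchPath,
    Task,
    packaged_embeddings,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def toy_table():
    """Committed toy animal embedding fixture (60 tokens, 16-d, unit norm)."""
    return packaged_embeddings()


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated cohort shared across read-only tests."""
    return simulate_cohort(20, seed=424242)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_visual_path(coords, pid="p1"):
    return SearchPath(
        participant_id=pid,
        task=Task.VISUAL,
        events=[Event(index=i, x=float(x), y=float(y)) for i, (x, y) in enumerate(coords)],
    )


def make_semantic_path(tokens, pid="p1", times=None):
    times = times if times is not None else [None] * len(tokens)
    return SearchPath(
        participant_id=pid,
        task=Task.SEMANTIC,
        events=[Event(index=i, token=t, t=ts) for i, (t, ts) in enumerate(zip(tokens, times))],
    )


def make_cohort(scores, parents=None):
    parents = parents or [None] * len(scores)
    return [
        Participant(id=f"p{i}", teacher_score=s, parent_score=p)
        for i, (s, p) in enumerate(zip(scores, parents))
    ]
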