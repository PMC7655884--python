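import numpy as np
import pytest

from gviat import SimParams, load_task_spec, simulate_cohort
from gviat.session_io import Session, SessionSet, Trial


@pytest.fixture(scope="session")
def task():
    return load_task_spec()


@pytest.fixture(scope="session")
def small_cohort(task):
    """20 simulated participants with default generating parameters."""
    cohort, truth = simulate_cohort(SimParams(n_participants=20, seed=11), task)
    return cohort, truth


@pytest.fixture
def make_session():
    """Build a session from {block: [(latency, correct), ...]} mappings."""

    def _make(blocks: dict, participant_id: str = "P1", version: int = 1) -> Session:
        trials = []
        for block, entries in blocks.items():
            for i, entry in enumerate(entries, start=1):
                if isinstance(entry, tuple):
                    latency, correct = entry
                else:
                    latency, correct = entry, True
                trials.append(
                    Trial(
                        block=block,
                        trial_index=i,
                        stimulus="Respect",
                        latency_ms=float(latency),
                        first_correct=bool(correct),
                    )
                )
        return Session(participant_id=participant_id, version=version, trials=trials)

    return _make


@pytest.fixture
def make_cohort(task, make_session):
    """Wrap hand-built sessions into a SessionSet."""

    def _make(sessions) -> SessionSet:
        return SessionSet(task=task, sessions=list(sessions))

    return _make


def random_critical_session(
    rng: np.random.Generator, participant_id: str = "P1"
) -> Session:
    """A random critical-blocks-only session exercising every scoring rule.

    Latencies are lognormal with occasional fast guesses and lapses; errors
    occur at a random per-session rate; block sizes vary; version random.
    """
    version = int(rng.integers(1, 3))
    error_rate = float(rng.uniform(0.0, 0.2))
    trials = []
    for block in (3, 4, 6, 7):
        n = int(rng.integers(8, 30))
        lat = np.exp(rng.normal(6.7, 0.45, n)) + 120.0
        u = rng.random(n)
        lat = np.where(u < 0.03, rng.uniform(150, 299, n), lat)
        lat = np.where((u >= 0.03) & (u < 0.05), rng.uniform(10_001, 12_000, n), lat)
        errors = rng.random(n) < error_rate
        if errors.all():  # keep at least one correct trial per block
            errors[int(rng.integers(0, n))] = False
        for i in range(n):
            trials.append(
                Trial(
                    block=block,
                    trial_index=i + 1,
                    stimulus="Respect",
                    latency_ms=float(lat[i]),
                    first_correct=not bool(errors[i]),
                )
            )
    return Session(participant_id=participant_id, version=version, trials=trials)
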