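import pytest

from fearcircuit import schedule as S


@pytest.fixture(scope="session")
def fig3_schedule() -> S.TrialSchedule:
    """Conditioning + extinction + resting + retrieval, at default counts."""
    c = S.DEFAULT_COUNTS
    return S.concat(
        S.full_reinforcement(c["conditioning"], 1.0),
        S.extinction(c["extinction"]),
        S.resting(c["resting"]),
        S.retrieval(c["retrieval"]),
    )


@pytest.fixture(scope="session")
def partial_protocol() -> S.TrialSchedule:
    """Seeded p = 0.5 partial conditioning followed by extinction."""
    c = S.DEFAULT_COUNTS
    return S.concat(
        S.partial_reinforcement(c["conditioning"], 0.5, 1.0, seed=11),
        S.extinction(c["extinction"]),
    )
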