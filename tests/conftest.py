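import numpy as np
import pytest

from swsystolic import ScoringScheme, Sequence

DNA_LETTERS = list("ACGT")


@pytest.fixture
def demo_scheme():
    """Demonstration parameters: match 5, mismatch -5, linear gap 1."""
    return ScoringScheme(match_score=5, mismatch_score=-5, gap_penalty=1)


def random_scheme(rng: np.random.Generator) -> ScoringScheme:
    return ScoringScheme(
        match_score=int(rng.integers(1, 9)),
        mismatch_score=int(rng.integers(-8, 1)),
        gap_penalty=int(rng.integers(0, 4)),
    )


def random_pair(
    rng: np.random.Generator,
    min_len: int = 1,
    max_len: int = 32,
    database_at_least_query: bool = False,
) -> tuple[Sequence, Sequence]:
    n = int(rng.integers(min_len, max_len + 1))
    lo = n if database_at_least_query else min_len
    m = int(rng.integers(lo, max_len + 1))
    q = Sequence("".join(rng.choice(DNA_LETTERS, size=n)), name="q")
    s = Sequence("".join(rng.choice(DNA_LETTERS, size=m)), name="s")
    return q, s
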