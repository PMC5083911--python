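import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tespectrum.model import AlignedCopy, AlignmentSet

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_alignment(rows, populations=None, reference_id=None):
    """Build an AlignmentSet from bare sequence strings."""
    pops = populations or ["pop1"] * len(rows)
    copies = [
        AlignedCopy(copy_id=f"c{i+1:02d}", residues=seq, population=pops[i])
        for i, seq in enumerate(rows)
    ]
    return AlignmentSet(copies, reference_id=reference_id)


def random_messy_alignment(rng, max_copies=10, max_cols=50):
    """A random alignment with conserved columns, noise, gaps and Ns.

    Columns are i.i.d.: a majority character (base or gap) with ~10% of
    copies deviating to any other character, occasionally N — exercising
    fixed, substituted, indel and ambiguous columns alike.
    """
    n_copies = int(rng.integers(2, max_copies + 1))
    n_cols = int(rng.integers(1, max_cols + 1))
    chars = np.array(list("ACGT-"))
    major = rng.choice(chars, size=n_cols)
    M = np.tile(major, (n_copies, 1))
    noise = rng.random((n_copies, n_cols))
    for i in range(n_copies):
        for j in range(n_cols):
            if noise[i, j] < 0.10:
                M[i, j] = chars[rng.integers(5)]
            elif noise[i, j] < 0.12:
                M[i, j] = "N"
    rows = ["".join(row) for row in M]
    # every copy must contain at least one non-gap character overall;
    # regenerate degenerate all-gap rows as all-A
    rows = [r if set(r) != {"-"} else "A" * n_cols for r in rows]
    return make_alignment(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
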