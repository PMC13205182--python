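import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stagepath as sp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_truth() -> sp.GroundTruth:
    return sp.GroundTruth()


@pytest.fixture(scope="session")
def small_cohort(default_truth):
    """400-subject two-subtype cohort at the default noise level."""
    return sp.generate_mutations(default_truth, 400, seed=11)


@pytest.fixture
def tiny_matrix():
    """Two-event matrix holding the single profile x = (1, 0)."""
    return sp.BinaryMutationMatrix(
        pd.DataFrame([[1, 0]], index=["s1"], columns=["A", "B"])
    )


def brute_force_likelihood(x: np.ndarray, orderings, fractions, alpha, beta,
                           event_names) -> float:
    """Independent oracle: enumerate every (subtype, stage) pair."""
    col = {e: i for i, e in enumerate(event_names)}
    total = 0.0
    n_events = len(event_names)
    for f, ordering in zip(fractions, orderings):
        perm = [col[e] for e in ordering.events]
        subtype_p = 0.0
        for k in range(n_events + 1):
            p = 1.0
            for pos, j in enumerate(perm):
                if pos < k:  # event occurred
                    p *= (1 - beta) if x[j] else beta
                else:
                    p *= alpha if x[j] else (1 - alpha)
            subtype_p += p / (n_events + 1)
        total += f * subtype_p
    return total


@pytest.fixture(scope="session")
def brute_likelihood():
    return brute_force_likelihood
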