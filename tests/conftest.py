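import numpy as np
import pytest

from atnpipe.simulate import (
    DistributionalSpec,
    FixtureSpec,
    generate_distributional,
    generate_fixture,
)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The default exact-count 628-subject fixture cohort."""
    return generate_fixture(FixtureSpec(seed=20240101))


@pytest.fixture(scope="session")
def pet_subcohort():
    """A moderately sized two-group PET subcohort for derivation tests."""
    return generate_distributional(DistributionalSpec(seed=20240101, n=400))


def brute_force_auc(values, reference, direction):
    """Pairwise concordance count: the AUC oracle (ties count 0.5)."""
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=bool)
    scores = -values if direction == "lower_is_positive" else values
    pos = scores[reference]
    neg = scores[~reference]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_youden(values, reference, direction):
    """Plain-loop exhaustive Youden maximization over all candidate cutoffs.

    Same candidate set and tie-breaks as the implementation (midpoints of
    distinct values plus sentinels; higher sensitivity, then nearer the
    pooled median), but written as an independent scalar scan.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=bool)
    n1, n0 = reference.sum(), (~reference).sum()
    distinct = np.unique(values)
    candidates = [-np.inf, *((distinct[:-1] + distinct[1:]) / 2.0), np.inf]
    median = float(np.median(values))
    best_key, best = None, None
    for cut in candidates:
        called = values < cut if direction == "lower_is_positive" else values > cut
        sens = float((called & reference).sum()) / n1
        spec = float((~called & ~reference).sum()) / n0
        dist = abs(cut - median) if np.isfinite(cut) else np.inf
        key = (sens + spec - 1.0, sens, -dist)
        if best_key is None or key > best_key:
            best_key, best = key, (float(cut), sens, spec)
    return best
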