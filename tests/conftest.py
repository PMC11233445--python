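import numpy as np
import pytest

from ned_mcgurk import (
    CohortConfig,
    build_fusion_table,
    congruent_accuracy,
    filter_participants,
    make_stimulus_spec,
    predict_matrix,
    simulate_cohort,
)
from ned_mcgurk.scoring import FusionTable


@pytest.fixture(scope="session")
def spec_single():
    """Single-syllable voiced McGurk stimulus (auditory ba, visual ga)."""
    return make_stimulus_spec("s3", "ba", "ga", "voiced")


@pytest.fixture(scope="session")
def spec_double():
    """Double-syllable voiced McGurk stimulus (auditory baba, visual gaga)."""
    return make_stimulus_spec("s1", "baba", "gaga", "voiced")


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants x 6 stimuli x 10 reps, zero congruent lapse."""
    cfg = CohortConfig(
        n_participants=12, n_stimuli=6, n_reps=10,
        congruent_lapse_rate=0.0, seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    trials, truth, specs = small_cohort
    acc = congruent_accuracy(trials, specs)
    included, _ = filter_participants(acc)
    return build_fusion_table(trials, specs, included)


@pytest.fixture(scope="session")
def noiseless_table():
    """Exact model probabilities as observations (no binomial noise)."""
    rng = np.random.default_rng(5)
    D = rng.uniform(0.15, 0.85, 6)
    T = rng.uniform(0.1, 0.9, 10)
    sigma = rng.uniform(0.15, 0.45, 10)
    P = predict_matrix(D, T, sigma)
    table = FusionTable(
        [f"p{j:02d}" for j in range(10)],
        [f"s{i}" for i in range(6)],
        P,
        np.full((10, 6), 10),
    )
    return table, D, T, sigma
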