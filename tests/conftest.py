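import warnings

import numpy as np
import pytest

from bp_affect import features as feat
from bp_affect import scales, simulate

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def et_scale():
    return scales.build_et_scale()


@pytest.fixture(scope="session")
def ji_scale():
    return scales.build_ji_scale()


@pytest.fixture(scope="session")
def chords66_et(et_scale):
    """The 66 tritave-free patterns rooted on degree 0 above MIDI 52."""
    return [
        scales.realize_chord(et_scale, pat, 0, 52.0)
        for pat in scales.enumerate_patterns(include_tritave=False)
    ]


@pytest.fixture(scope="session")
def expectation_matrix():
    """Default 64-harmonic triad expectation matrix (shared; ~2 s to build)."""
    return feat.build_triad_expectation_matrix()


@pytest.fixture(scope="session")
def features66(chords66_et, expectation_matrix):
    return feat.feature_table(chords66_et, matrix=expectation_matrix)


@pytest.fixture(scope="session")
def ji_features(ji_scale):
    """Predictors for all 858 just-intonation realizations (patterns x roots)."""
    return simulate.stimulus_features(ji_scale, base_midi=52.0)


@pytest.fixture(scope="session")
def small_dataset(ji_features):
    """A compact simulated session used by several model tests."""
    cfg = simulate.SimulationConfig(n_participants=10, seed=42)
    return simulate.simulate_dataset(cfg, features=ji_features)
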