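import numpy as np
import pytest

from signfuse.lexicon import CompositeState, Lexicon, LexiconEntry, load_default_lexicon
from signfuse.synthgen import (
    SynthConfig,
    make_gesture_profiles,
    make_trajectory_templates,
)


@pytest.fixture(scope="session")
def lex120():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def profiles9():
    return make_gesture_profiles(9, seed=7)


@pytest.fixture(scope="session")
def templates9():
    return make_trajectory_templates(9, seed=3)


@pytest.fixture
def synth_cfg():
    return SynthConfig()


@pytest.fixture
def tiny_lexicon():
    """Six words spanning all three categories, states well apart."""
    entries = [
        LexiconEntry(1, "alpha", "SHGV", [CompositeState(1, 1)]),
        LexiconEntry(2, "beta", "SHGV", [CompositeState(3, 0)]),
        LexiconEntry(3, "gamma", "DHGV", [CompositeState(5, 4)]),
        LexiconEntry(4, "delta", "DHGV", [CompositeState(7, 6)]),
        LexiconEntry(5, "epsilon", "DGV", [CompositeState(2, 3), CompositeState(8, 3)]),
        LexiconEntry(6, "zeta", "DGV", [CompositeState(4, 8), CompositeState(9, 8)]),
    ]
    return Lexicon(entries=entries, n_gestures=9, n_movement_states=9)


def make_random_chmm(n1, n2, d1=2, d2=2, seed=0, mean_scale=3.0):
    """Random valid coupled HMM (dirichlet rows, separated means)."""
    from signfuse.chmm import CoupledHMM, EmissionModel

    rng = np.random.default_rng(seed)
    initial = [rng.dirichlet(np.ones(n1)), rng.dirichlet(np.ones(n2))]
    transitions = [
        rng.dirichlet(np.ones(n1), size=(n1, n2)),
        rng.dirichlet(np.ones(n2), size=(n1, n2)),
    ]
    means = [
        rng.normal(0, mean_scale, size=(n1, d1)),
        rng.normal(0, mean_scale, size=(n2, d2)),
    ]
    vars_ = [
        rng.uniform(0.5, 1.5, size=(n1, d1)),
        rng.uniform(0.5, 1.5, size=(n2, d2)),
    ]
    return CoupledHMM(
        n1=n1, n2=n2, initial=initial, transitions=transitions,
        emissions=EmissionModel(means=means, vars=vars_),
    )
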