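import numpy as np
import pytest

from reeftraits import traits
from reeftraits.reefscape import Arena


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ranges():
    return traits.TraitRanges()


@pytest.fixture
def species_set(rng, ranges):
    return traits.make_species_set(rng, ranges=ranges)


def make_two_species(ci_a=0.8, ci_b=0.2, growth=0.002):
    """Two minimal coral species with controlled CI for geometry tests."""
    alloc = traits.ResourceAllocation(40, 30, 30)
    a = traits.Species("a", "massive", alloc, growth, 0.1, ci_a, 1.0)
    b = traits.Species("b", "branching", alloc, growth, 0.1, ci_b, 3.0)
    return [a, b]


@pytest.fixture
def bare_arena():
    """Empty 10 m arena with two controllable species."""
    return Arena(make_two_species(), side=10.0)
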