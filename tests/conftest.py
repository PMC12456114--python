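import numpy as np
import pytest

from ancbreed.genome import GenomeMap, Panel, founder_labels


class ScriptedRNG:
    """Deterministic stand-in for a Generator with scripted draw streams."""

    def __init__(self, integers=(), exponentials=(), uniforms=(), poissons=()):
        self._integers = list(integers)
        self._exp = list(exponentials)
        self._unif = list(uniforms)
        self._pois = list(poissons)

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def exponential(self, *args, **kwargs):
        return self._exp.pop(0)

    def random(self, *args, **kwargs):
        return self._unif.pop(0)

    def poisson(self, *args, **kwargs):
        return self._pois.pop(0)


@pytest.fixture
def scripted_rng_factory():
    return ScriptedRNG


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_panel(rng, n=4, L=6, n_labels=6, t=1) -> Panel:
    """A small panel with arbitrary binary tracks and founder labels."""
    return Panel(
        t=t,
        G=rng.integers(0, 2, (n, 2, L)),
        A=rng.integers(0, 2, (n, 2, L)),
        F=rng.integers(1, n_labels + 1, (n, 2, L)),
    )


@pytest.fixture
def small_panel(rng):
    return random_panel(rng)


@pytest.fixture
def founder_panel(rng):
    """A generation-0 panel whose founder labels follow the 2i-I(a=1) rule."""
    n, L = 5, 8
    F = np.repeat(founder_labels(n)[:, :, None], L, axis=2)
    return Panel(
        t=0,
        G=rng.integers(0, 2, (n, 2, L)),
        A=np.ones((n, 2, L), dtype=np.uint8),
        F=F,
    )


@pytest.fixture
def genome_map():
    return GenomeMap(6, 1.0)
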