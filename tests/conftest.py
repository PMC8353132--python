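import numpy as np
import pytest
from hypothesis import settings

from iwlik import Ability, Item, TestForm

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

# domain classes that happen to match pytest's collection patterns
TestForm.__test__ = False


@pytest.fixture
def rasch_item():
    return Item("d1", "dichotomous", difficulty=0.0)


@pytest.fixture
def poly_uniform_item():
    # all cumulative steps zero -> uniform category probabilities at theta=0
    return Item("p1", "polytomous", steps=(0.0, 0.0, 0.0, 0.0))


@pytest.fixture
def poly_spread_item():
    return Item("p2", "polytomous", steps=(-1.5, -0.5, 0.5, 1.5))


def make_uni_form(n_dich=3, n_poly=2, b=None, steps=None):
    """Small unidimensional mixed form with fixed parameters."""
    b = b if b is not None else [-1.0, 0.0, 1.0, -0.5, 0.5, 1.5][:n_dich]
    steps = steps if steps is not None else (-1.2, -0.4, 0.4, 1.2)
    items = [
        Item(f"d{i}", "dichotomous", difficulty=float(b[i])) for i in range(n_dich)
    ]
    items += [
        Item(f"p{i}", "polytomous", steps=tuple(np.asarray(steps) + 0.1 * i))
        for i in range(n_poly)
    ]
    return TestForm(tuple(items), "unidimensional")


def make_long_form(n_dich=2, n_poly=1):
    """Small two-occasion mixed form with fixed parameters."""
    items = []
    for occ in ("pretest", "posttest"):
        items += [
            Item(f"{occ}_d{i}", "dichotomous", occ, difficulty=float(i - 0.5))
            for i in range(n_dich)
        ]
        items += [
            Item(f"{occ}_p{i}", "polytomous", occ, steps=(-1.0, -0.3, 0.3, 1.0))
            for i in range(n_poly)
        ]
    return TestForm(tuple(items), "longitudinal")


@pytest.fixture
def uni_form():
    return make_uni_form()


@pytest.fixture
def long_form():
    return make_long_form()
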