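"""Item response models for mixed-format tests.

This module implements the probability, information and response-simulation
machinery for tests that mix dichotomous (Rasch / two-parameter logistic)
items with polytomous partial-credit items, under two regimes:

``longitudinal``
    A two-occasion growth design.  Occasion-1 ("pretest") performance
    depends on the initial ability ``theta1`` alone; occasion-2
    ("posttest") performance depends on ``theta1 + theta2``, where
    ``theta2`` is the modifiability (growth) dimension added at the second
    measurement occasion.  Pretest and posttest item sets are disjoint.

``unidimensional``
    A single-occasion test scored on ``theta1`` only.  Dichotomous items
    may carry a discrimination parameter (two-parameter logistic model);
    with the default discrimination of 1 the Rasch case is recovered.

Partial-credit items use categories ``1..h`` with one step parameter per
category: the probability of category ``j`` at effective ability ``t`` is
proportional to ``exp(j*t - sum(steps[:j]))``.  Users accustomed to the
``0..m-1`` scoring convention of the partial credit model should note the
unit shift in the category scores; it only relabels the categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DICHOTOMOUS",
    "POLYTOMOUS",
    "PRETEST",
    "POSTTEST",
    "LONGITUDINAL",
    "UNIDIMENSIONAL",
    "RegimeError",
    "Item",
    "Ability",
    "TestForm",
    "effective_theta",
    "prob_dichotomous",
    "prob_polytomous",
    "item_information",
    "test_information",
    "simulate_response",
    "simulate_responses",
]

DICHOTOMOUS = "dichotomous"
POLYTOMOUS = "polytomous"
PRETEST = "pretest"
POSTTEST = "posttest"
LONGITUDINAL = "longitudinal"
UNIDIMENSIONAL = "unidimensional"


class RegimeError(ValueError):
    """An operation was requested that is invalid for the form's regime."""


@dataclass(frozen=True)
class Item:
    """One calibrated test item.

    Exactly one of ``difficulty`` (dichotomous) or ``steps`` (polytomous)
    is present, matching ``kind``.  ``discrimination`` applies to
    dichotomous items only; the default of 1 gives the Rasch model.
    ``occasion`` is meaningful in the longitudinal regime and ignored in
    the unidimensional one.
    """

    item_id: str
    kind: str
    occasion: str = PRETEST
    difficulty: Optional[float] = None
    discrimination: float = 1.0
    steps: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in (DICHOTOMOUS, POLYTOMOUS):
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.occasion not in (PRETEST, POSTTEST):
            raise ValueError(f"unknown occasion {self.occasion!r}")
        if self.kind == DICHOTOMOUS:
            if self.difficulty is None or self.steps is not None:
                raise ValueError(
                    f"item {self.item_id!r}: dichotomous items carry a "
                    "difficulty and no steps"
                )
            if not np.isfinite(self.difficulty):
                raise ValueError(f"item {self.item_id!r}: non-finite difficulty")
            if not self.discrimination > 0:
                raise ValueError(f"item {self.item_id!r}: discrimination must be > 0")
        else:
            if self.steps is None or self.difficulty is not None:
                raise ValueError(
                    f"item {self.item_id!r}: polytomous items carry steps "
                    "and no difficulty"
                )
            steps = tuple(float(s) for s in self.steps)
            if len(steps) < 2:
                raise ValueError(f"item {self.item_id!r}: need >= 2 categories")
            if not all(np.isfinite(steps)):
                raise ValueError(f"item {self.item_id!r}: non-finite step")
            object.__setattr__(self, "steps", steps)

    @property
    def n_categories(self) -> int:
        """Number of response categories (2 for dichotomous items)."""
        return 2 if self.kind == DICHOTOMOUS else len(self.steps)


@dataclass(frozen=True)
class Ability:
    """Latent trait state: ``theta1`` (initial ability) and, in the
    longitudinal regime, ``theta2`` (modifiability/growth)."""

    theta1: float
    theta2: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta1):
            raise ValueError("theta1 must be finite")
        if self.theta2 is not None and not np.isfinite(self.theta2):
            raise ValueError("theta2 must be finite")


def _group(item: Item, regime: str) -> int:
    if regime == LONGITUDINAL:
        return 2 * (item.occasion == POSTTEST) + (item.kind == POLYTOMOUS)
    return int(item.kind == POLYTOMOUS)


@dataclass(frozen=True)
class TestForm:
    """An ordered item collection with the canonical mixed-format layout.

    Longitudinal forms are ordered pretest-dichotomous (positions
    ``1..k``), pretest-polytomous (``k+1..n1``), posttest-dichotomous
    (``n1+1..m``), posttest-polytomous (``m+1..n``).  Unidimensional forms
    use only the dichotomous/polytomous split (``k``/``n1``) and ignore
    item occasions.
    """

    items: Tuple[Item, ...]
    regime: str = LONGITUDINAL

    def __post_init__(self) -> None:
        if self.regime not in (LONGITUDINAL, UNIDIMENSIONAL):
            raise RegimeError(f"unknown regime {self.regime!r}")
        items = tuple(self.items)
        if not items:
            raise ValueError("a test form must contain at least one item")
        object.__setattr__(self, "items", items)
        groups = [_group(it, self.regime) for it in items]
        if any(b < a for a, b in zip(groups, groups[1:])):
            raise ValueError(
                "items are not in canonical order "
                "(pretest dichotomous, pretest polytomous, "
                "posttest dichotomous, posttest polytomous)"
            )

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def k(self) -> int:
        """Number of pretest dichotomous items (dichotomous count for
        unidimensional forms)."""
        return sum(1 for it in self.items if _group(it, self.regime) == 0)

    @property
    def n1(self) -> int:
        """Index of the last pretest item (``n`` for unidimensional forms)."""
        if self.regime == UNIDIMENSIONAL:
            return self.n
        return sum(1 for it in self.items if _group(it, self.regime) <= 1)

    @property
    def m(self) -> int:
        """Index of the last posttest dichotomous item."""
        if self.regime == UNIDIMENSIONAL:
            return self.n
        return sum(1 for it in self.items if _group(it, self.regime) <= 2)

    def subform(self, keep: Sequence[bool]) -> "TestForm":
        """Form restricted to the items where ``keep`` is true (canonical
        order is preserved by subsetting)."""
        kept = tuple(it for it, k in zip(self.items, keep) if k)
        return TestForm(kept, self.regime)


def effective_theta(ability: Ability, occasion: str) -> float:
    """Ability entering an item's response function at the given occasion:
    ``theta1`` for the pretest, ``theta1 + theta2`` for the posttest."""
    if occasion == PRETEST:
        return ability.theta1
    if occasion == POSTTEST:
        if ability.theta2 is None:
            raise RegimeError("posttest requested but the ability has no theta2")
        return ability.theta1 + ability.theta2
    raise ValueError(f"unknown occasion {occasion!r}")


def _effective_for_item(form: TestForm, ability: Ability, item: Item) -> float:
    if form.regime == UNIDIMENSIONAL:
        return ability.theta1
    return effective_theta(ability, item.occasion)


def prob_dichotomous(theta_eff: float, item: Item) -> float:
    """Probability of a correct response: logistic in
    ``a * (theta_eff - b)``."""
    if item.kind != DICHOTOMOUS:
        raise ValueError("prob_dichotomous needs a dichotomous item")
    from scipy.special import expit

    return float(expit(item.discrimination * (theta_eff - item.difficulty)))


def prob_polytomous(theta_eff: float, item: Item) -> np.ndarray:
    """Category probabilities (length ``h``, categories ``1..h``) of a
    partial-credit item, computed with a max-shift for overflow safety."""
    if item.kind != POLYTOMOUS:
        raise ValueError("prob_polytomous needs a polytomous item")
    steps = np.asarray(item.steps, dtype=float)
    j = np.arange(1, steps.size + 1, dtype=float)
    logits = j * theta_eff - np.cumsum(steps)
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def item_information(item: Item, theta_eff: float) -> float:
    """Fisher information of one item at an effective ability.

    Dichotomous: ``a^2 * P * Q`` (``P * Q`` in the Rasch case).
    Polytomous: the variance of the category score,
    ``sum(j^2 P_j) - (sum(j P_j))^2``.
    """
    if item.kind == DICHOTOMOUS:
        p = prob_dichotomous(theta_eff, item)
        return item.discrimination**2 * p * (1.0 - p)
    p = prob_polytomous(theta_eff, item)
    j = np.arange(1, p.size + 1, dtype=float)
    m1 = float(j @ p)
    return float(j**2 @ p) - m1 * m1


def test_information(form: TestForm, ability: Ability) -> float:
    """Scalar test information: the sum of item informations, each item
    evaluated at its own occasion's effective ability."""
    return float(
        sum(
            item_information(it, _effective_for_item(form, ability, it))
            for it in form.items
        )
    )


def simulate_response(item: Item, ability: Ability, rng: np.random.Generator) -> int:
    """Draw one response: Bernoulli for dichotomous items (0/1),
    categorical over ``1..h`` for polytomous items."""
    occ = item.occasion if ability.theta2 is not None else PRETEST
    t = effective_theta(ability, occ)
    if item.kind == DICHOTOMOUS:
        return int(rng.random() < prob_dichotomous(t, item))
    p = prob_polytomous(t, item)
    return int(rng.choice(p.size, p=p)) + 1


def simulate_responses(
    form: TestForm,
    ability: Ability,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Simulate ``size`` independent response patterns for one examinee
    ability, returned as a ``(size, n_items)`` integer matrix in form
    order (0/1 for dichotomous items, ``1..h`` for polytomous items)."""
    out = np.empty((size, form.n), dtype=np.int64)
    for col, item in enumerate(form.items):
        t = _effective_for_item(form, ability, item)
        if item.kind == DICHOTOMOUS:
            p = prob_dichotomous(t, item)
            out[:, col] = rng.random(size) < p
        else:
            p = prob_polytomous(t, item)
            cum = np.cumsum(p)
            cum[-1] = 1.0
            out[:, col] = np.searchsorted(cum, rng.random(size), side="right") + 1
    return out
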