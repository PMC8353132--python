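"""Monte-Carlo studies of the ability estimators.

Two study layouts are provided.  Study 1 is longitudinal: at each of two
occasions an artificial mixed-format test is drawn (dichotomous
difficulties from N(0, 1); four-category step parameters from
N(-1.5, 0.2), N(-0.5, 0.2), N(0.5, 0.2), N(1.5, 0.2), read as mean/SD),
responses are simulated on a 17-point initial-ability grid from -4 to 4
in steps of 0.5 with the growth dimension tied to the initial level
(theta2 = 1.0 below -2, 0.8 between -2 and 2, 0.6 above 2), and every
requested estimator scores the identical response data.  Study 2 is the
unidimensional analogue combining the two-parameter logistic model
(discriminations drawn from Uniform(0.75, 4/3) by default, or fixed at 1)
with the partial credit model.

Test lengths 10/30/60 are crossed with dichotomous:polytomous mixes
lambda in {2, 1, 0.5} (e.g. a 30-item test has 20, 15 or 10 dichotomous
items), giving nine test designs; one item bank is drawn per condition
per master seed and reused across theta levels and replications.
All-extreme response patterns are excluded (and logged) before scoring.

Seeding is hierarchical: a master ``numpy.random.SeedSequence`` spawns one
child per condition, which spawns one stream for the item bank and one per
theta level, so every record is exactly reproducible from (master seed,
condition, level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import estimators as est
from . import metrics as met
from .models import (
    Ability,
    DICHOTOMOUS,
    Item,
    LONGITUDINAL,
    POLYTOMOUS,
    POSTTEST,
    PRETEST,
    TestForm,
    UNIDIMENSIONAL,
    simulate_responses,
)

__all__ = [
    "StudyDesign",
    "study1_design",
    "study2_design",
    "mixed_counts",
    "condition_label",
    "theta2_for",
    "draw_item_bank",
    "run_condition",
    "run_study1",
    "run_study2",
]

THETA1_GRID = tuple(float(x) for x in np.round(np.arange(-4.0, 4.01, 0.5), 1))


@dataclass(frozen=True)
class StudyDesign:
    """Full configuration of a simulation study."""

    regime: str = LONGITUDINAL
    test_lengths: Tuple[int, ...] = (10, 30, 60)
    mixes: Tuple[float, ...] = (2.0, 1.0, 0.5)
    theta1_grid: Tuple[float, ...] = THETA1_GRID
    theta2_levels: Tuple[float, float, float] = (1.0, 0.8, 0.6)  # low/mid/high
    n_replications: int = 1000
    seed: int = 0
    b_mean: float = 0.0
    b_sd: float = 1.0
    step_means: Tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)
    step_sd: float = 0.2
    discrimination: str = "unit"  # "unit" or "uniform" (2PL draws)
    disc_range: Tuple[float, float] = (0.75, 4.0 / 3.0)

    def __post_init__(self) -> None:
        if self.regime not in (LONGITUDINAL, UNIDIMENSIONAL):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.discrimination not in ("unit", "uniform"):
            raise ValueError("discrimination must be 'unit' or 'uniform'")

    @property
    def n_categories(self) -> int:
        return len(self.step_means)


def study1_design(**overrides) -> StudyDesign:
    """The longitudinal growth study with its standard settings."""
    return StudyDesign(**{"regime": LONGITUDINAL, **overrides})


def study2_design(**overrides) -> StudyDesign:
    """The unidimensional 2PL + partial-credit study."""
    return StudyDesign(
        **{"regime": UNIDIMENSIONAL, "discrimination": "uniform", **overrides}
    )


def mixed_counts(length: int, mix: float) -> Tuple[int, int]:
    """Dichotomous/polytomous item counts for a test length and mix ratio
    lambda = n_dichotomous : n_polytomous (e.g. 30 items at lambda=2 gives
    20 dichotomous + 10 polytomous)."""
    nd = int(round(length * mix / (1.0 + mix)))
    if nd <= 0 or nd >= length:
        raise ValueError(f"mix {mix} leaves no items of one type at length {length}")
    return nd, length - nd


def condition_label(length: int, mix: float) -> str:
    nd, npoly = mixed_counts(length, mix)
    return f"{nd}d+{npoly}p"


def theta2_for(design: StudyDesign, theta1: float) -> float:
    """Growth level attached to an initial ability: high gain for low
    starters (theta1 < -2), moderate in between, low gain above 2."""
    low, mid, high = design.theta2_levels
    if theta1 < -2.0:
        return low
    if theta1 > 2.0:
        return high
    return mid


def _draw_occasion(
    design: StudyDesign, occ: str, nd: int, npoly: int, rng: np.random.Generator
) -> List[Item]:
    if design.discrimination == "uniform":
        a = rng.uniform(*design.disc_range, size=nd)
    else:
        a = np.ones(nd)
    b = rng.normal(design.b_mean, design.b_sd, size=nd)
    items = [
        Item(f"{occ[:4]}_d{i + 1:02d}", DICHOTOMOUS, occ,
             difficulty=float(b[i]), discrimination=float(a[i]))
        for i in range(nd)
    ]
    means = np.asarray(design.step_means)
    steps = rng.normal(means[None, :], design.step_sd, size=(npoly, means.size))
    items += [
        Item(f"{occ[:4]}_p{i + 1:02d}", POLYTOMOUS, occ, steps=tuple(steps[i]))
        for i in range(npoly)
    ]
    return items


def draw_item_bank(
    design: StudyDesign, length: int, mix: float, rng: np.random.Generator
) -> TestForm:
    """Draw one calibrated item bank for a (length, mix) condition: the
    stated dichotomous/polytomous counts per occasion, difficulties and
    step parameters from the design's distributions."""
    if length not in design.test_lengths or mix not in design.mixes:
        raise ValueError(f"({length}, {mix}) is not a condition of this design")
    nd, npoly = mixed_counts(length, mix)
    if design.regime == LONGITUDINAL:
        items = _draw_occasion(design, PRETEST, nd, npoly, rng)
        items += _draw_occasion(design, POSTTEST, nd, npoly, rng)
    else:
        items = _draw_occasion(design, PRETEST, nd, npoly, rng)
    return TestForm(tuple(items), design.regime)


def run_condition(
    design: StudyDesign,
    length: int,
    mix: float,
    methods: Sequence[str] = ("mle", "map", "wle", "twle", "iwle"),
    seed_seq: Optional[np.random.SeedSequence] = None,
    config: Optional[est.OptimizerConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and score one (length, mix) condition.

    Returns ``(records, exclusions)``: long-format replication records
    (one row per non-degenerate replication per estimator) and the
    per-level exclusion log.  Estimator failures are carried as
    ``converged=False`` rows, never dropped.
    """
    if not methods:
        raise ValueError("need at least one estimator")
    ss = seed_seq if seed_seq is not None else np.random.SeedSequence(design.seed)
    streams = ss.spawn(1 + len(design.theta1_grid))
    form = draw_item_bank(design, length, mix, np.random.default_rng(streams[0]))
    label = condition_label(length, mix)
    nd, npoly = mixed_counts(length, mix)
    rec: Dict[str, list] = {
        k: []
        for k in (
            "condition", "length", "n_dich", "n_poly", "theta1", "theta2",
            "rep", "estimator", "theta1_hat", "theta2_hat", "converged", "n_iter",
        )
    }
    excl_rows = []
    longitudinal = design.regime == LONGITUDINAL
    for lvl, theta1 in enumerate(design.theta1_grid):
        theta2 = theta2_for(design, theta1) if longitudinal else np.nan
        ability = Ability(theta1, theta2 if longitudinal else None)
        rng = np.random.default_rng(streams[1 + lvl])
        R = simulate_responses(form, ability, rng, size=design.n_replications)
        fa = est._core.compile_form(form)
        Ud, Up = est._core.split_responses(fa, R)
        deg = est._core.degenerate_mask(fa, Ud, Up)
        keep = np.flatnonzero(~deg)
        excl_rows.append(
            {
                "condition": label,
                "theta1": theta1,
                "n_total": design.n_replications,
                "n_excluded": int(deg.sum()),
            }
        )
        if keep.size == 0:
            continue
        results = est.estimate_batch(form, R[keep], methods, config)
        for m in methods:
            r = results[m]
            n = keep.size
            rec["condition"] += [label] * n
            rec["length"] += [length] * n
            rec["n_dich"] += [nd] * n
            rec["n_poly"] += [npoly] * n
            rec["theta1"] += [theta1] * n
            rec["theta2"] += [theta2] * n
            rec["rep"] += list(keep)
            rec["estimator"] += [m] * n
            rec["theta1_hat"] += list(r.theta1)
            rec["theta2_hat"] += list(r.theta2)
            rec["converged"] += list(r.converged)
            rec["n_iter"] += list(r.n_iter)
    return pd.DataFrame(rec), pd.DataFrame(excl_rows)


def _run_study(
    design: StudyDesign,
    methods: Sequence[str],
    keep_records: bool,
    config: Optional[est.OptimizerConfig],
) -> met.SimulationSummary:
    master = np.random.SeedSequence(design.seed)
    conds = [(L, lam) for L in design.test_lengths for lam in design.mixes]
    children = master.spawn(len(conds))
    all_rec, all_exc = [], []
    for (length, mix), child in zip(conds, children):
        r, e = run_condition(design, length, mix, methods, child, config)
        all_rec.append(r)
        all_exc.append(e)
    records = pd.concat(all_rec, ignore_index=True)
    exclusions = pd.concat(all_exc, ignore_index=True)
    return met.summarize_records(
        records, exclusions, design=design.__dict__.copy(), keep_records=keep_records
    )


def run_study1(
    design: Optional[StudyDesign] = None,
    methods: Sequence[str] = ("mle", "map", "wle", "twle", "iwle"),
    keep_records: bool = True,
    config: Optional[est.OptimizerConfig] = None,
) -> met.SimulationSummary:
    """Run the longitudinal study over all (length, mix) conditions of the
    design and summarise per-condition metrics and pooled correlations."""
    design = design or study1_design()
    if design.regime != LONGITUDINAL:
        raise ValueError("run_study1 needs a longitudinal design")
    return _run_study(design, methods, keep_records, config)


def run_study2(
    design: Optional[StudyDesign] = None,
    methods: Sequence[str] = ("mle", "iwle"),
    keep_records: bool = True,
    config: Optional[est.OptimizerConfig] = None,
) -> met.SimulationSummary:
    """Run the unidimensional 2PL + partial-credit study (MLE vs IWLE by
    default)."""
    design = design or study2_design()
    if design.regime != UNIDIMENSIONAL:
        raise ValueError("run_study2 needs a unidimensional design")
    return _run_study(design, methods, keep_records, config)
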