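"""Ability estimators for mixed-format (and longitudinal) test forms.

Five estimators share one optimisation backbone (projected damped
Newton-Raphson with a coarse-grid multi-start fallback):

* ``mle`` -- maximiser of the log-likelihood ``log L(theta | U)``.
* ``map_estimate`` -- maximiser of the likelihood over the box
  ``[-4, 4]`` per dimension (a maximum a posteriori estimate under a
  non-informative uniform prior on that box); for extreme response
  patterns the maximiser sits on the boundary.
* ``wle`` -- Warm's weighted likelihood: maximiser of
  ``log L + 0.5 * log I(theta)`` where ``I`` is the scalar test
  information.
* ``twle`` -- type-weighted likelihood: the dichotomous and polytomous
  log-likelihood blocks are weighted by information-share ratios
  ``(I_d/I)^alpha`` and ``(I_p/I)^beta``, with ``alpha``/``beta`` tuned so
  that the dichotomous block weight ends below the polytomous one.
* ``iwle`` -- item-weighted likelihood: each item's log-likelihood term is
  weighted by its information share ``I_i(theta)/I(theta)``; the weights
  are computed once at the MLE and held fixed during maximisation.

All estimators search the box ``[-6, 6]`` per free dimension (matching the
grid used by the reference dense-grid cross-checks); a response pattern
whose likelihood increases monotonically toward infinity is therefore
returned at the box boundary rather than diverging.  All-extreme
("degenerate") patterns are detected up front and returned unestimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from . import _core
from .models import (
    Ability,
    LONGITUDINAL,
    RegimeError,
    TestForm,
)

__all__ = [
    "OptimizerConfig",
    "TwleTuning",
    "EstimationResult",
    "BatchResult",
    "log_likelihood",
    "detect_degenerate",
    "warm_weight",
    "item_weights",
    "estimate_batch",
    "mle",
    "map_estimate",
    "wle",
    "twle",
    "iwle",
    "ESTIMATORS",
]

ESTIMATORS = ("mle", "map", "wle", "twle", "iwle")


@dataclass(frozen=True)
class OptimizerConfig:
    """Newton-Raphson settings shared by all estimators.

    ``bounds`` is the search box per free dimension for the likelihood
    estimators; ``map_bounds`` is the uniform-prior support used by the
    MAP estimator.  ``damping`` is the step-halving factor, ``grid_step``
    the spacing of the multi-start fallback grid.
    """

    tolerance: float = 1e-6
    max_iter: int = 100
    init: Optional[Ability] = None
    bounds: Tuple[float, float] = (-6.0, 6.0)
    map_bounds: Tuple[float, float] = (-4.0, 4.0)
    damping: float = 0.5
    grid_step: float = 0.25

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class TwleTuning:
    """Tuning constants of the type-weighted estimator: the initial ratio
    exponent ``epsilon`` used when the dichotomous block is the more
    informative one, the ``increment`` by which ``alpha`` is raised until
    the dichotomous weight drops below the polytomous one, and the round
    cap."""

    epsilon: float = 0.35
    increment: float = 0.05
    max_rounds: int = 100


@dataclass(frozen=True)
class EstimationResult:
    """Point estimate with convergence diagnostics for one pattern."""

    estimator: str
    theta_hat: Optional[Ability]
    converged: bool
    n_iter: int
    final_gradient_norm: float
    degenerate: bool = False
    twle_alpha: Optional[float] = None
    twle_beta: Optional[float] = None
    weights_used: Optional[np.ndarray] = None


@dataclass
class BatchResult:
    """Array-valued results for a batch of patterns (NaN where a pattern
    was degenerate and therefore not estimated)."""

    estimator: str
    theta1: np.ndarray
    theta2: np.ndarray  # NaN in the unidimensional regime
    converged: np.ndarray
    n_iter: np.ndarray
    grad_norm: np.ndarray
    degenerate: np.ndarray
    alpha: Optional[np.ndarray] = None
    beta: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None


def _prepare(form: TestForm, responses) -> Tuple[_core.FormArrays, np.ndarray, np.ndarray]:
    fa = _core.compile_form(form)
    Ud, Up = _core.split_responses(fa, np.asarray(responses))
    return fa, Ud, Up


def log_likelihood(form: TestForm, responses, ability: Ability) -> float:
    """Joint log-likelihood of one response pattern: the sum over items of
    the log response probability, each item evaluated at its occasion's
    effective ability."""
    fa, Ud, Up = _prepare(form, responses)
    x = _ability_to_x(fa, ability)
    (f,) = _core.eval_objective(fa, "ml", x, Ud, Up, order=0)
    return float(f[0])


def detect_degenerate(form: TestForm, responses) -> bool:
    """True iff the pattern is all-extreme (all correct and top categories,
    or all incorrect and bottom categories); such patterns have no finite
    likelihood maximiser and are excluded from estimation."""
    fa, Ud, Up = _prepare(form, responses)
    return bool(_core.degenerate_mask(fa, Ud, Up)[0])


def warm_weight(form: TestForm, ability: Ability) -> float:
    """Warm's weight ``I(theta)^(1/2)``, with ``I`` the scalar test
    information."""
    from .models import test_information

    return float(np.sqrt(test_information(form, ability)))


def item_weights(form: TestForm, ability: Ability) -> np.ndarray:
    """Information-share weights ``w_i = I_i(theta) / I(theta)`` in form
    order; positive and summing to one."""
    fa = _core.compile_form(form)
    x = _ability_to_x(fa, ability)
    k2d, k2p = _core.information_parts(fa, x)
    total = float(k2d.sum() + k2p.sum())
    if not total > 0:
        raise ValueError("total test information is zero at this ability")
    w = np.empty(fa.n_items)
    w[fa.d_pos] = k2d[0] / total
    w[fa.p_pos] = k2p[0] / total
    return w


def _ability_to_x(fa: _core.FormArrays, ability: Ability) -> np.ndarray:
    x = np.zeros((1, 2))
    x[0, 0] = ability.theta1
    if fa.dim == 2:
        if ability.theta2 is None:
            raise RegimeError("longitudinal form needs an ability with theta2")
        x[0, 1] = ability.theta2
    return x


def _check_identifiable(fa: _core.FormArrays) -> None:
    if fa.dim == 2:
        n_pre = int((1.0 - fa.d_post).sum() + (1.0 - fa.p_post).sum())
        n_post = int(fa.d_post.sum() + fa.p_post.sum())
        if n_pre == 0 or n_post == 0:
            raise RegimeError(
                "longitudinal estimation needs items on both occasions"
            )


def _solve(
    fa: _core.FormArrays,
    kind: str,
    Ud: np.ndarray,
    Up: np.ndarray,
    cfg: OptimizerConfig,
    box: Tuple[float, float],
    x0: np.ndarray,
    **kw,
):
    """Run the batch maximiser for one objective, with a coarse-grid
    multi-start fallback (tie-break toward the smallest theta) for rows
    that fail to converge."""

    def objfun(x, order):
        return _core.eval_objective(fa, kind, x, Ud, Up, order=order, **kw)

    lo, hi = box
    x, f, pgn, n_iter, conv = _core.maximize_batch(
        objfun, x0, fa.dim, lo, hi, cfg.tolerance, cfg.max_iter
    )
    bad = np.flatnonzero(~conv)
    if bad.size:
        grid = _core.box_grid(lo, hi, fa.dim, cfg.grid_step)
        G = grid.shape[0]
        for i in bad:
            kw_i = {
                k: (np.repeat(v[i : i + 1], G, axis=0) if v is not None else None)
                for k, v in kw.items()
            }
            Ud_i = np.repeat(Ud[i : i + 1], G, axis=0)
            Up_i = np.repeat(Up[i : i + 1], G, axis=0)
            (fg,) = _core.eval_objective(fa, kind, grid, Ud_i, Up_i, order=0, **kw_i)
            start = grid[int(np.argmax(fg)) : int(np.argmax(fg)) + 1]
            kw_1 = {k: (v[i : i + 1] if v is not None else None) for k, v in kw.items()}

            def obj1(xx, order, _Ud=Ud[i : i + 1], _Up=Up[i : i + 1], _kw=kw_1):
                return _core.eval_objective(fa, kind, xx, _Ud, _Up, order=order, **_kw)

            xi, fi, pgi, ni, ci = _core.maximize_batch(
                obj1, start, fa.dim, lo, hi, cfg.tolerance, cfg.max_iter
            )
            if fi[0] >= f[i]:
                x[i], f[i], pgn[i] = xi[0], fi[0], pgi[0]
                n_iter[i] += ni[0]
                conv[i] = ci[0]
    return x, f, pgn, n_iter, conv


def _x0(fa: _core.FormArrays, N: int, cfg: OptimizerConfig) -> np.ndarray:
    x0 = np.zeros((N, 2))
    if cfg.init is not None:
        x0[:, 0] = cfg.init.theta1
        if fa.dim == 2 and cfg.init.theta2 is not None:
            x0[:, 1] = cfg.init.theta2
    return x0


def estimate_batch(
    form: TestForm,
    responses,
    methods: Sequence[str] = ("mle",),
    config: Optional[OptimizerConfig] = None,
    tuning: Optional[TwleTuning] = None,
    return_weights: bool = False,
    fixed_ratios: Optional[Tuple[float, float]] = None,
) -> Dict[str, BatchResult]:
    """Apply one or more estimators to a batch of response patterns.

    ``responses`` is an ``(N, n_items)`` integer matrix in form order.
    Degenerate (all-extreme) patterns are skipped by the likelihood
    estimators and returned as NaN; the MAP estimator, whose boxed
    maximiser exists for every pattern, estimates them at the prior
    boundary.  ``fixed_ratios`` bypasses the TWLE tuning loop with given
    ``(alpha, beta)`` exponents.
    """
    cfg = config or OptimizerConfig()
    tun = tuning or TwleTuning()
    fa = _core.compile_form(form)
    _check_identifiable(fa)
    for m in methods:
        if m not in ESTIMATORS:
            raise ValueError(f"unknown estimator {m!r}")
    Ud, Up = _core.split_responses(fa, np.asarray(responses))
    N = Ud.shape[0] if fa.nd else Up.shape[0]
    deg = _core.degenerate_mask(fa, Ud, Up)
    ok = ~deg
    Udo, Upo = Ud[ok], Up[ok]
    n_ok = int(ok.sum())

    out: Dict[str, BatchResult] = {}

    def pack(name, x, conv, n_iter, pgn, rows=ok, **extra):
        r = BatchResult(
            estimator=name,
            theta1=np.full(N, np.nan),
            theta2=np.full(N, np.nan),
            converged=np.zeros(N, dtype=bool),
            n_iter=np.zeros(N, dtype=np.int64),
            grad_norm=np.full(N, np.nan),
            degenerate=deg.copy(),
            **extra,
        )
        r.theta1[rows] = x[:, 0]
        if fa.dim == 2:
            r.theta2[rows] = x[:, 1]
        r.converged[rows] = conv
        r.n_iter[rows] = n_iter
        r.grad_norm[rows] = pgn
        return r

    need_mle = bool({"mle", "wle", "twle", "iwle"} & set(methods))
    x_mle = conv_mle = None
    if need_mle and n_ok:
        x_mle, f_mle, pg_mle, it_mle, conv_mle = _solve(
            fa, "ml", Udo, Upo, cfg, cfg.bounds, _x0(fa, n_ok, cfg)
        )
    elif need_mle:
        x_mle = np.zeros((0, 2))

    for m in methods:
        if m == "mle":
            if n_ok:
                out[m] = pack("mle", x_mle, conv_mle, it_mle, pg_mle)
            else:
                out[m] = pack("mle", np.zeros((0, 2)), *([np.zeros(0)] * 3))
        elif m == "map":
            lo, hi = cfg.map_bounds
            x, f, pgn, n_iter, conv = _solve(
                fa, "ml", Ud, Up, cfg, cfg.map_bounds, _x0(fa, N, cfg)
            )
            r = pack("map", x, conv, n_iter, pgn, rows=np.ones(N, dtype=bool))
            out[m] = r
        elif m == "wle":
            if n_ok:
                x, f, pgn, n_iter, conv = _solve(
                    fa, "wl", Udo, Upo, cfg, cfg.bounds, x_mle.copy()
                )
                out[m] = pack("wle", x, conv, n_iter, pgn)
            else:
                out[m] = pack("wle", np.zeros((0, 2)), *([np.zeros(0)] * 3))
        elif m == "iwle":
            if n_ok:
                k2d, k2p = _core.information_parts(fa, x_mle)
                total = k2d.sum(axis=1) + k2p.sum(axis=1)
                if not (total > 0).all():
                    raise ValueError("zero total information at an MLE anchor")
                w_d = k2d / total[:, None]
                w_p = k2p / total[:, None]
                x, f, pgn, n_iter, conv = _solve(
                    fa, "iwl", Udo, Upo, cfg, cfg.bounds, x_mle.copy(),
                    w_d=w_d, w_p=w_p,
                )
                extra = {}
                if return_weights:
                    W = np.full((N, fa.n_items), np.nan)
                    Wok = np.empty((n_ok, fa.n_items))
                    Wok[:, fa.d_pos] = w_d
                    Wok[:, fa.p_pos] = w_p
                    W[ok] = Wok
                    extra["weights"] = W
                out[m] = pack("iwle", x, conv, n_iter, pgn, **extra)
            else:
                out[m] = pack("iwle", np.zeros((0, 2)), *([np.zeros(0)] * 3))
        elif m == "twle":
            out[m] = _twle_batch(
                fa, Udo, Upo, cfg, tun, x_mle, pack, n_ok, fixed_ratios
            )
    return out


def _twle_batch(fa, Udo, Upo, cfg, tun, x_mle, pack, n_ok, fixed_ratios):
    if fa.nd == 0 or fa.npoly == 0:
        raise RegimeError("the type-weighted estimator needs both item types")
    if not n_ok:
        return pack(
            "twle", np.zeros((0, 2)), *([np.zeros(0)] * 3),
            alpha=np.zeros(0), beta=np.zeros(0),
        )
    k2d0, k2p0 = _core.information_parts(fa, x_mle)
    Id0 = k2d0.sum(axis=1)
    Ip0 = k2p0.sum(axis=1)
    I0 = Id0 + Ip0
    rd0 = Id0 / I0
    rp0 = Ip0 / I0
    if fixed_ratios is not None:
        alpha = np.full(n_ok, float(fixed_ratios[0]))
        beta = np.full(n_ok, float(fixed_ratios[1]))
        tuned = np.ones(n_ok, dtype=bool)
    else:
        alpha = np.ones(n_ok)
        beta = np.ones(n_ok)
        hard = Id0 >= Ip0  # dichotomous block at least as informative
        alpha[hard] = tun.epsilon
        beta[hard] = tun.epsilon
        for _ in range(tun.max_rounds):
            badw = rd0**alpha >= rp0**beta
            if not badw.any():
                break
            alpha[badw] += tun.increment
        tuned = rd0**alpha < rp0**beta
    x = x_mle.copy()
    conv = np.zeros(n_ok, dtype=bool)
    n_iter = np.zeros(n_ok, dtype=np.int64)
    pgn = np.full(n_ok, np.nan)
    todo = np.ones(n_ok, dtype=bool)
    for _ in range(tun.max_rounds):
        idx = np.flatnonzero(todo)
        if not idx.size:
            break
        xi, fi, pgi, ni, ci = _solve(
            fa, "twl", Udo[idx], Upo[idx], cfg, cfg.bounds, x[idx].copy(),
            alpha=alpha[idx], beta=beta[idx],
        )
        x[idx], pgn[idx], conv[idx] = xi, pgi, ci
        n_iter[idx] += ni
        if fixed_ratios is not None:
            todo[:] = False
            break
        k2d, k2p = _core.information_parts(fa, xi)
        Id = k2d.sum(axis=1)
        Ip = k2p.sum(axis=1)
        I = Id + Ip
        w1 = (Id / I) ** alpha[idx]
        w2 = (Ip / I) ** beta[idx]
        ok_now = w1 < w2
        todo[idx] = ~ok_now
        alpha[idx[~ok_now]] += tun.increment
    tuned &= ~todo
    conv &= tuned
    r = pack("twle", x, conv, n_iter, pgn, alpha=np.full(len(conv), np.nan),
             beta=np.full(len(conv), np.nan))
    # overwrite the placeholder alpha/beta arrays on the non-degenerate rows
    rows = ~r.degenerate
    a_full = np.full(r.theta1.size, np.nan)
    b_full = np.full(r.theta1.size, np.nan)
    a_full[rows] = alpha
    b_full[rows] = beta
    r.alpha = a_full
    r.beta = b_full
    return r


def _single(form, responses, method, config, tuning=None, fixed_ratios=None):
    R = np.asarray(responses)
    if R.ndim == 1:
        R = R[None, :]
    want_weights = method == "iwle"
    res = estimate_batch(
        form, R, (method,), config, tuning,
        return_weights=want_weights, fixed_ratios=fixed_ratios,
    )[method]
    if res.degenerate[0] and np.isnan(res.theta1[0]):
        return EstimationResult(
            estimator=method, theta_hat=None, converged=False, n_iter=0,
            final_gradient_norm=np.nan, degenerate=True,
        )
    fa = _core.compile_form(form)
    theta2 = float(res.theta2[0]) if fa.dim == 2 else None
    return EstimationResult(
        estimator=method,
        theta_hat=Ability(float(res.theta1[0]), theta2),
        converged=bool(res.converged[0]),
        n_iter=int(res.n_iter[0]),
        final_gradient_norm=float(res.grad_norm[0]),
        degenerate=bool(res.degenerate[0]),
        twle_alpha=(float(res.alpha[0]) if res.alpha is not None else None),
        twle_beta=(float(res.beta[0]) if res.beta is not None else None),
        weights_used=(res.weights[0] if res.weights is not None else None),
    )


def mle(form: TestForm, responses, config: Optional[OptimizerConfig] = None) -> EstimationResult:
    """Maximum likelihood estimate of the ability (2-D in the longitudinal
    regime); degenerate patterns are flagged and not estimated."""
    return _single(form, responses, "mle", config)


def map_estimate(form: TestForm, responses, config: Optional[OptimizerConfig] = None) -> EstimationResult:
    """Maximum a posteriori estimate under a uniform prior on the box
    ``[-4, 4]`` per dimension; equals the MLE whenever the MLE is interior
    to the box, and sits on the boundary for extreme patterns."""
    return _single(form, responses, "map", config)


def wle(form: TestForm, responses, config: Optional[OptimizerConfig] = None) -> EstimationResult:
    """Warm's weighted likelihood estimate: maximiser of
    ``log L(theta | U) + log w(theta)`` with ``w = I^(1/2)``."""
    return _single(form, responses, "wle", config)


def iwle(form: TestForm, responses, config: Optional[OptimizerConfig] = None) -> EstimationResult:
    """Item-weighted likelihood estimate: weights ``I_i/I`` fixed at the
    MLE, then the weighted log-likelihood is maximised.  With equal
    weights this reduces exactly to the MLE."""
    return _single(form, responses, "iwle", config)


def twle(
    form: TestForm,
    responses,
    config: Optional[OptimizerConfig] = None,
    tuning: Optional[TwleTuning] = None,
    fixed_ratios: Optional[Tuple[float, float]] = None,
) -> EstimationResult:
    """Type-weighted likelihood estimate with the three-step
    ``alpha``/``beta`` tuning loop (or fixed exponents via
    ``fixed_ratios``)."""
    return _single(form, responses, "twle", config, tuning, fixed_ratios)
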