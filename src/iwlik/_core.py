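"""Vectorised numerical kernels shared by the estimators and the simulator.

Everything here works on batches: ability parameters travel as ``(N, 2)``
arrays (the second column is carried but inert in the unidimensional
regime) and responses as ``(N, n_items)`` integer matrices in form order.

Per-item quantities are organised around the cumulants of the item-score
distributions.  For each item at effective ability ``t`` the response
model is a one-parameter exponential family in ``t``, so the derivatives
of the per-item log-likelihood and of the item information come for free:
the score is ``x - E[x]``, the curvature is ``-Var[x]``, and the first and
second derivatives of the information ``Var[x]`` are the third and fourth
cumulants of the item score.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.special import expit, log_expit

from .models import (
    DICHOTOMOUS,
    LONGITUDINAL,
    POSTTEST,
    TestForm,
)

_TINY = 1e-300


@dataclass(frozen=True, eq=False)
class FormArrays:
    """Array view of a :class:`~iwlik.models.TestForm`."""

    regime: str
    n_items: int
    dim: int  # 1 (unidimensional) or 2 (longitudinal)
    d_pos: np.ndarray  # form positions of dichotomous items
    p_pos: np.ndarray  # form positions of polytomous items
    a: np.ndarray  # (nd,) discriminations
    b: np.ndarray  # (nd,) difficulties
    d_post: np.ndarray  # (nd,) posttest indicator, float 0/1
    S: np.ndarray  # (np, hmax) cumulative step parameters
    h: np.ndarray  # (np,) categories per polytomous item
    cat_ok: np.ndarray  # (np, hmax) valid-category mask
    p_post: np.ndarray  # (np,) posttest indicator, float 0/1
    jgrid: np.ndarray  # (hmax,) category scores 1..hmax

    @property
    def nd(self) -> int:
        return self.a.size

    @property
    def npoly(self) -> int:
        return self.h.size


@lru_cache(maxsize=128)
def compile_form(form: TestForm) -> FormArrays:
    longitudinal = form.regime == LONGITUDINAL
    d_pos, p_pos = [], []
    a, b, d_post = [], [], []
    steps, p_post = [], []
    for pos, item in enumerate(form.items):
        post = float(longitudinal and item.occasion == POSTTEST)
        if item.kind == DICHOTOMOUS:
            d_pos.append(pos)
            a.append(item.discrimination)
            b.append(item.difficulty)
            d_post.append(post)
        else:
            p_pos.append(pos)
            steps.append(np.asarray(item.steps, dtype=float))
            p_post.append(post)
    hmax = max((s.size for s in steps), default=2)
    S = np.zeros((len(steps), hmax))
    cat_ok = np.zeros((len(steps), hmax), dtype=bool)
    h = np.zeros(len(steps), dtype=np.int64)
    for i, s in enumerate(steps):
        S[i, : s.size] = np.cumsum(s)
        cat_ok[i, : s.size] = True
        h[i] = s.size
    return FormArrays(
        regime=form.regime,
        n_items=form.n,
        dim=2 if longitudinal else 1,
        d_pos=np.asarray(d_pos, dtype=np.int64),
        p_pos=np.asarray(p_pos, dtype=np.int64),
        a=np.asarray(a, dtype=float),
        b=np.asarray(b, dtype=float),
        d_post=np.asarray(d_post, dtype=float),
        S=S,
        h=h,
        cat_ok=cat_ok,
        p_post=np.asarray(p_post, dtype=float),
        jgrid=np.arange(1, hmax + 1, dtype=float),
    )


def split_responses(fa: FormArrays, R: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split and validate a form-ordered response matrix into the
    dichotomous (0/1) and polytomous (1..h) blocks."""
    R = np.asarray(R)
    if R.ndim == 1:
        R = R[None, :]
    if R.shape[1] != fa.n_items:
        raise ValueError(
            f"response matrix has {R.shape[1]} columns, form has {fa.n_items} items"
        )
    Ud = R[:, fa.d_pos].astype(float)
    Up = R[:, fa.p_pos].astype(np.int64)
    if Ud.size and not np.isin(Ud, (0.0, 1.0)).all():
        raise ValueError("dichotomous responses must be 0 or 1")
    if Up.size and ((Up < 1) | (Up > fa.h[None, :])).any():
        raise ValueError("polytomous responses must lie in 1..h per item")
    return Ud, Up


def degenerate_mask(fa: FormArrays, Ud: np.ndarray, Up: np.ndarray) -> np.ndarray:
    """All-extreme patterns: every dichotomous response correct and every
    polytomous response in the top category, or every response at the
    bottom.  For these patterns the likelihood has no finite maximiser."""
    top = np.ones(max(len(Ud), len(Up)), dtype=bool)
    bot = top.copy()
    if fa.nd:
        top &= (Ud == 1.0).all(axis=1)
        bot &= (Ud == 0.0).all(axis=1)
    if fa.npoly:
        top &= (Up == fa.h[None, :]).all(axis=1)
        bot &= (Up == 1).all(axis=1)
    return top | bot


# ---------------------------------------------------------------------------
# per-item statistics


def _dich_stats(fa: FormArrays, t: np.ndarray, Ud: Optional[np.ndarray], order: int):
    """Per-dichotomous-item log-likelihood/score/cumulants at effective
    abilities ``t`` of shape (N, nd)."""
    z = fa.a * (t - fa.b)
    out = {}
    P = expit(z)
    pq = P * (1.0 - P)
    out["k2"] = fa.a**2 * pq
    if Ud is not None:
        out["ll"] = Ud * log_expit(z) + (1.0 - Ud) * log_expit(-z)
        out["sc"] = fa.a * (Ud - P)
    if order >= 1:
        out["k3"] = fa.a**3 * pq * (1.0 - 2.0 * P)
        out["k4"] = fa.a**4 * pq * (1.0 - 6.0 * pq)
    return out


def _poly_stats(fa: FormArrays, t: np.ndarray, Up: Optional[np.ndarray], order: int):
    """Per-polytomous-item statistics at effective abilities ``t`` of
    shape (N, np).  Category probabilities are evaluated with an exponent
    max-shift; padded categories carry zero mass."""
    logits = fa.jgrid[None, None, :] * t[..., None] - fa.S[None, :, :]
    logits = np.where(fa.cat_ok[None, :, :], logits, -np.inf)
    mx = logits.max(axis=-1, keepdims=True)
    w = np.exp(logits - mx)
    Z = w.sum(axis=-1)
    Pmat = w / Z[..., None]
    j = fa.jgrid
    m1 = Pmat @ j
    m2 = Pmat @ j**2
    k2 = m2 - m1**2
    out = {"k2": k2, "Pmat": Pmat}
    if Up is not None:
        S_x = fa.S[np.arange(fa.npoly)[None, :], Up - 1]
        logZ = mx[..., 0] + np.log(Z)
        out["ll"] = Up * t - S_x - logZ
        out["sc"] = Up - m1
    if order >= 1:
        m3 = Pmat @ j**3
        m4 = Pmat @ j**4
        k3 = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
        mu4 = m4 - 4.0 * m1 * m3 + 6.0 * m1**2 * m2 - 3.0 * m1**4
        out["k3"] = k3
        out["k4"] = mu4 - 3.0 * k2**2
    return out


def effective_t(fa: FormArrays, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Effective abilities per item: (N, nd) and (N, np) matrices."""
    t1 = x[:, 0]
    t2 = x[:, 1] if fa.dim == 2 else 0.0
    td = t1[:, None] + (t2[:, None] * fa.d_post if fa.dim == 2 else 0.0) + np.zeros(fa.nd)
    tp = t1[:, None] + (t2[:, None] * fa.p_post if fa.dim == 2 else 0.0) + np.zeros(fa.npoly)
    return td, tp


def information_parts(fa: FormArrays, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Item informations at abilities ``x``: (N, nd) and (N, np)."""
    td, tp = effective_t(fa, x)
    k2d = _dich_stats(fa, td, None, 0)["k2"]
    k2p = _poly_stats(fa, tp, None, 0)["k2"]
    return k2d, k2p


def _sum2(v: np.ndarray, post: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sum a per-item (N, n) array and its posttest-only restriction."""
    return v.sum(axis=1), v @ post


# ---------------------------------------------------------------------------
# objective assembly


def eval_objective(
    fa: FormArrays,
    kind: str,
    x: np.ndarray,
    Ud: np.ndarray,
    Up: np.ndarray,
    order: int = 2,
    w_d: Optional[np.ndarray] = None,
    w_p: Optional[np.ndarray] = None,
    alpha: Optional[np.ndarray] = None,
    beta: Optional[np.ndarray] = None,
):
    """Evaluate one of the estimation objectives on a batch.

    ``kind`` is ``"ml"`` (log-likelihood, also used by the flat-prior MAP),
    ``"wl"`` (log-likelihood plus ``0.5 * log I(theta)``), ``"iwl"``
    (information-share-weighted log-likelihood with fixed per-item weights
    ``w_d``/``w_p``) or ``"twl"`` (type-weighted log-likelihood with
    exponents ``alpha``/``beta``).

    With ``order=0`` only the objective values are returned; ``order=2``
    adds the gradient (N, 2) and a Hessian (N, 2, 2).  For ``"twl"`` the
    returned Hessian is the likelihood-curvature approximation
    ``w1 * Hd + w2 * Hp``; the gradient is exact.
    """
    N = x.shape[0]
    td, tp = effective_t(fa, x)
    dorder = 1 if (order >= 1 and kind in ("wl", "twl")) else 0
    d = _dich_stats(fa, td, Ud, dorder)
    p = _poly_stats(fa, tp, Up, dorder)

    if kind in ("ml", "wl"):
        f = d["ll"].sum(axis=1) + p["ll"].sum(axis=1)
    elif kind == "iwl":
        f = (w_d * d["ll"]).sum(axis=1) + (w_p * p["ll"]).sum(axis=1)
    elif kind == "twl":
        ld = d["ll"].sum(axis=1)
        lp = p["ll"].sum(axis=1)
        Id = d["k2"].sum(axis=1)
        Ip = p["k2"].sum(axis=1)
        I = Id + Ip
        w1 = (np.maximum(Id, _TINY) / np.maximum(I, _TINY)) ** alpha
        w2 = (np.maximum(Ip, _TINY) / np.maximum(I, _TINY)) ** beta
        f = w1 * ld + w2 * lp
    else:  # pragma: no cover - internal
        raise ValueError(f"unknown objective kind {kind!r}")

    if kind == "wl":
        I = d["k2"].sum(axis=1) + p["k2"].sum(axis=1)
        f = f + 0.5 * np.log(np.maximum(I, _TINY))
    if order == 0:
        return (f,)

    g = np.zeros((N, 2))
    H = np.zeros((N, 2, 2))

    def accumulate(scd, scp, cvd, cvp):
        g1d, g2d = _sum2(scd, fa.d_post)
        g1p, g2p = _sum2(scp, fa.p_post)
        g[:, 0] += g1d + g1p
        g[:, 1] += g2d + g2p
        h1d, h2d = _sum2(cvd, fa.d_post)
        h1p, h2p = _sum2(cvp, fa.p_post)
        H[:, 0, 0] += h1d + h1p
        off = h2d + h2p
        H[:, 0, 1] += off
        H[:, 1, 0] += off
        H[:, 1, 1] += off

    if kind in ("ml", "wl"):
        accumulate(d["sc"], p["sc"], -d["k2"], -p["k2"])
    elif kind == "iwl":
        accumulate(w_d * d["sc"], w_p * p["sc"], -w_d * d["k2"], -w_p * p["k2"])
    elif kind == "twl":
        # exact gradient: d/dtheta [w1 * ld + w2 * lp] with
        # grad w1 = alpha * w1 * (grad Id / Id - grad I / I), same for w2.
        gd = np.stack(_sum2(d["sc"], fa.d_post), axis=1)
        gp = np.stack(_sum2(p["sc"], fa.p_post), axis=1)
        gId = np.stack(_sum2(d["k3"], fa.d_post), axis=1)
        gIp = np.stack(_sum2(p["k3"], fa.p_post), axis=1)
        gI = gId + gIp
        Id_ = np.maximum(Id, _TINY)[:, None]
        Ip_ = np.maximum(Ip, _TINY)[:, None]
        I_ = np.maximum(I, _TINY)[:, None]
        gw1 = alpha[:, None] * w1[:, None] * (gId / Id_ - gI / I_)
        gw2 = beta[:, None] * w2[:, None] * (gIp / Ip_ - gI / I_)
        g[:] = w1[:, None] * gd + ld[:, None] * gw1
        g[:] += w2[:, None] * gp + lp[:, None] * gw2
        hd = np.stack(_sum2(-d["k2"], fa.d_post), axis=1)
        hp = np.stack(_sum2(-p["k2"], fa.p_post), axis=1)
        H[:, 0, 0] = w1 * hd[:, 0] + w2 * hp[:, 0]
        off = w1 * hd[:, 1] + w2 * hp[:, 1]
        H[:, 0, 1] = off
        H[:, 1, 0] = off
        H[:, 1, 1] = off

    if kind == "wl":
        # penalty 0.5 * log I: gradient 0.5 * grad I / I, Hessian
        # 0.5 * (hess I / I - outer(grad I) / I^2); grad and hess of the
        # scalar information are sums of third and fourth item cumulants.
        gI = np.zeros((N, 2))
        HI = np.zeros((N, 2, 2))
        g1d, g2d = _sum2(d["k3"], fa.d_post)
        g1p, g2p = _sum2(p["k3"], fa.p_post)
        gI[:, 0] = g1d + g1p
        gI[:, 1] = g2d + g2p
        h1d, h2d = _sum2(d["k4"], fa.d_post)
        h1p, h2p = _sum2(p["k4"], fa.p_post)
        HI[:, 0, 0] = h1d + h1p
        off = h2d + h2p
        HI[:, 0, 1] = off
        HI[:, 1, 0] = off
        HI[:, 1, 1] = off
        I_ = np.maximum(I, _TINY)
        g += 0.5 * gI / I_[:, None]
        H += 0.5 * (
            HI / I_[:, None, None]
            - gI[:, :, None] * gI[:, None, :] / (I_**2)[:, None, None]
        )

    if fa.dim == 1:
        g[:, 1] = 0.0
        H[:, 0, 1] = H[:, 1, 0] = 0.0
        H[:, 1, 1] = -1.0  # inert dimension, keep the 2x2 solve well posed
    return f, g, H


# ---------------------------------------------------------------------------
# batch maximiser


def _projected_gradient(
    x: np.ndarray, g: np.ndarray, lo: float, hi: float, dim: int
) -> np.ndarray:
    pg = g[:, :dim].copy()
    xa = x[:, :dim]
    pg[(xa <= lo + 1e-12) & (pg < 0)] = 0.0
    pg[(xa >= hi - 1e-12) & (pg > 0)] = 0.0
    return pg


def _newton_direction(
    x: np.ndarray, g: np.ndarray, H: np.ndarray, dim: int, lo: float, hi: float
) -> np.ndarray:
    """Per-row ascent direction: the Newton step (restricted to the
    coordinates not blocked at a box bound) when the reduced Hessian is
    safely negative definite, else the projected gradient (scaled)."""
    N = g.shape[0]
    # a coordinate is free unless it sits at a bound with the gradient
    # pointing outward (active-set reduction)
    free = np.ones((N, 2), dtype=bool)
    free[:, dim:] = False
    xa, ga = x[:, :dim], g[:, :dim]
    blocked = ((xa <= lo + 1e-12) & (ga < 0)) | ((xa >= hi - 1e-12) & (ga > 0))
    free[:, :dim] &= ~blocked
    gp = np.where(free, g, 0.0)
    step = np.zeros((N, 2))
    both = free[:, 0] & free[:, 1]
    if both.any():
        h11, h12, h22 = H[both, 0, 0], H[both, 0, 1], H[both, 1, 1]
        det = h11 * h22 - h12**2
        ok = (h11 < -1e-12) & (det > 1e-16)
        s = np.zeros((both.sum(), 2))
        s[ok, 0] = -(h22[ok] * gp[both][ok, 0] - h12[ok] * gp[both][ok, 1]) / det[ok]
        s[ok, 1] = -(h11[ok] * gp[both][ok, 1] - h12[ok] * gp[both][ok, 0]) / det[ok]
        step[both] = s
    for c in range(2):
        only = free[:, c] & ~free[:, 1 - c]
        if only.any():
            h = H[only, c, c]
            sc = np.where(h < -1e-12, -gp[only, c] / np.where(h < -1e-12, h, -1.0),
                          np.sign(gp[only, c]))
            step[only, c] = sc
    # guard against non-ascent or runaway directions
    dot = (step * gp).sum(axis=1)
    bad = (dot <= 0) & (np.abs(gp).max(axis=1) > 0)
    if bad.any():
        gn = np.maximum(np.abs(gp[bad]).max(axis=1), 1.0)
        step[bad] = gp[bad] / gn[:, None]
    nrm = np.abs(step).max(axis=1)
    big = nrm > 5.0
    if big.any():
        step[big] *= (5.0 / nrm[big])[:, None]
    return step


def maximize_batch(
    objfun: Callable,
    x0: np.ndarray,
    dim: int,
    lo: float,
    hi: float,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Projected damped-Newton ascent, vectorised over rows.

    ``objfun(x, order)`` returns ``(f,)`` or ``(f, g, H)``.  Rows stop when
    the infinity norm of the box-projected gradient drops below ``tol``
    (interior stationary point or boundary KKT point), when they stall, or
    at ``max_iter``.  Returns ``(x, f, pg_norm, n_iter, converged)``.
    """
    x = np.clip(np.array(x0, dtype=float), lo, hi)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("x0 must be (N, 2)")
    N = x.shape[0]
    f, g, H = objfun(x, 2)
    n_iter = np.zeros(N, dtype=np.int64)
    stalled = np.zeros(N, dtype=bool)
    for _ in range(max_iter):
        pg = _projected_gradient(x, g, lo, hi, dim)
        pgn = np.abs(pg).max(axis=1) if dim else np.zeros(N)
        active = (pgn > tol) & ~stalled
        if not active.any():
            break
        step = _newton_direction(x, g, H, dim, lo, hi)
        step[~active] = 0.0
        alpha = np.ones(N)
        moved = np.zeros(N, dtype=bool)
        xc = x.copy()
        fc = f.copy()
        for _half in range(40):
            trial = np.clip(x + alpha[:, None] * step, lo, hi)
            (ft,) = objfun(trial, 0)
            improve = active & ~moved & (ft > f) & np.isfinite(ft)
            xc[improve] = trial[improve]
            fc[improve] = ft[improve]
            moved |= improve
            todo = active & ~moved
            if not todo.any():
                break
            alpha[todo] *= 0.5
        stalled |= active & ~moved
        x, f = xc, fc
        n_iter[active & moved] += 1
        f, g, H = objfun(x, 2)
    pg = _projected_gradient(x, g, lo, hi, dim)
    pgn = np.abs(pg).max(axis=1)
    return x, f, pgn, n_iter, pgn <= tol


def box_grid(lo: float, hi: float, dim: int, step: float) -> np.ndarray:
    """Coarse search grid over the box, ordered by ascending theta1 then
    theta2 so that ``argmax`` tie-breaks toward the smallest coordinates."""
    t = np.arange(lo, hi + 0.5 * step, step)
    if dim == 1:
        pts = np.zeros((t.size, 2))
        pts[:, 0] = t
        return pts
    g1, g2 = np.meshgrid(t, t, indexing="ij")
    return np.column_stack([g1.ravel(), g2.ravel()])
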