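"""Nuisance-robust epidemic changepoint detection.

The series may contain, besides short signal segments (length <= l), long
"nuisance" background shifts (length > l) that affect the same parameter.
An outer optimal-partitioning recursion classifies each stretch as global
background, signal segment, or nuisance segment:

    F(s) = min( F(s-1) + C0(x_s; theta0),
                min_{1 <= s-t <= l}  F(t) + C_S(x[t+1:s]) + beta,
                min_{s-t > l}        F(t) + C'(x[t+1:s]) + beta' )

where all cost terms sit on the deviance scale (twice the negative
log-likelihood), ``C_S`` is the profiled segment cost and ``C'`` is itself the optimal
epidemic cost of the window with its own unknown local background -- an
inner Algorithm-1 problem, kept incrementally up to date per surviving
candidate start so each new point costs O(1) amortised work per candidate.

Signal segments nested in a nuisance window must lie strictly inside it,
so the inner solvers never place a segment on the first or last point of
their window.  Chosen nuisance windows are re-solved once in two-pass mode
at traceback for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from episeg.alg1 import OnlineSolver, Segment
from episeg.costs import (
    CostModel,
    Penalty,
    PrefixStats,
    _point_cost,
    _profiled_nll,
    beta as beta_value,
    fixed_cost,
    mle_param,
    segment_cost,
)

_BG, _SIG, _NUI = 0, 1, 2


@dataclass(frozen=True)
class SignalSegment:
    """Signal segment with its absolute level and local-background effect.

    ``effect`` is ``theta_hat`` minus the level of the enclosing nuisance
    segment, or minus the global background for a free-standing signal.
    """

    s: int
    e: int
    theta_hat: float
    effect: float


@dataclass(frozen=True)
class NuisanceSegment:
    """Long background shift, possibly with signal segments nested inside."""

    s: int
    e: int
    theta_hat: float
    inner_signals: tuple[SignalSegment, ...] = ()


@dataclass
class NuisanceSegmentation:
    """Fitted structure: all signals, nuisances, and recomputed cost.

    ``signals`` lists every signal segment (free-standing and nested).
    ``total_cost`` is the full penalised cost recomputed from the reported
    structure; ``objective`` is the raw outer dynamic-programming optimum.
    """

    signals: List[SignalSegment]
    nuisances: List[NuisanceSegment]
    theta0: float
    total_cost: float
    objective: float
    nll: float
    n: int
    beta: float
    beta_prime: float

    @property
    def k(self) -> int:
        return len(self.signals)

    @property
    def m(self) -> int:
        return len(self.nuisances)

    def signal_changepoints(self) -> tuple[list[int], list[int]]:
        return [g.s for g in self.signals], [g.e for g in self.signals]


@dataclass(frozen=True)
class Alg2Config:
    """Configuration: length bound, penalties, known global background."""

    model: CostModel = CostModel()
    theta0: float = 0.0
    l: int = 10
    penalty: Penalty = Penalty()
    beta: Optional[float] = None
    beta_prime: Optional[float] = None
    pruning: str = "global"  # "none" | "local" | "global"
    A_n: Optional[int] = None
    prune_margin: Optional[float] = None

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if self.pruning not in ("none", "local", "global"):
            raise ValueError(f"unknown pruning {self.pruning!r}")
        if self.pruning == "local":
            if self.A_n is None or self.A_n < self.l:
                raise ValueError("local pruning requires A_n >= l")

    def resolve(self, n: int) -> tuple[float, float, float]:
        b = self.beta if self.beta is not None else beta_value(n, self.penalty)
        bp = self.beta_prime if self.beta_prime is not None else b
        # default pruning margin: alpha*(ln n)^(1+delta) in log-likelihood
        # units, which is twice the deviance-scale segment penalty
        margin = self.prune_margin if self.prune_margin is not None else 2.0 * bp
        return b, bp, margin


def _inner_solver(model: CostModel, beta: float, l: int, capacity: int) -> OnlineSolver:
    return OnlineSolver(
        model,
        beta,
        l,
        capacity=capacity,
        min_seg_len=1,
        prune=True,
        forbid_first=True,
    )


def _resolve_window(
    xw: np.ndarray, model: CostModel, beta: float, l: int
) -> tuple[float, List[tuple[int, int]]]:
    """Two-pass inner fit of a chosen nuisance window.

    Returns the local background estimate and the nested signal segments
    (window-relative indices), with the first and last window points held
    in the local background class.
    """
    m = xw.size
    p1 = _inner_solver(model, beta, l, m)
    for i, v in enumerate(xw):
        p1.append(v, allow_segment=(i < m - 1))
    w = p1.w
    p2 = OnlineSolver(
        model, beta, l, capacity=m, min_seg_len=1, prune=True,
        forbid_first=True, theta0_fixed=w,
    )
    for i, v in enumerate(xw):
        p2.append(v, allow_segment=(i < m - 1))
    return w, p2.segments()


def fit(x: Sequence[float], cfg: Alg2Config) -> NuisanceSegmentation:
    """Fit the nuisance-robust detector to a series."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    n = x.size
    if cfg.l >= n:
        warnings.warn(
            f"l={cfg.l} >= n={n}: no nuisance segment is possible, the fit "
            "degrades to a fixed-background epidemic detector",
            stacklevel=2,
        )
    b, bp, margin = cfg.resolve(n) if n >= 2 else (
        cfg.beta or 1.0, cfg.beta_prime or cfg.beta or 1.0, cfg.prune_margin or 1.0
    )
    model = cfg.model
    theta0 = cfg.theta0
    l = cfg.l
    pre = PrefixStats(x)

    F = np.empty(n + 1)
    F[0] = 0.0
    ptype = np.empty(n + 1, dtype=np.int64)
    pt = np.empty(n + 1, dtype=np.int64)
    states: Dict[int, OnlineSolver] = {}

    for s in range(n):
        best = F[s] + 2.0 * _point_cost(x[s], model, theta0)
        btype, bt = _BG, -2

        # signal branch: t in [s-l, s-1]
        lo = max(-1, s - l)
        ts = np.arange(lo, s, dtype=np.int64)
        if ts.size:
            cnt = (s - ts).astype(float)
            s1 = pre.s1[s + 1] - pre.s1[ts + 1]
            s2 = pre.s2[s + 1] - pre.s2[ts + 1]
            tot = F[ts + 1] + 2.0 * _profiled_nll(cnt, s1, s2, model) + b
            j = tot.size - 1 - int(np.argmin(tot[::-1]))
            if tot[j] < best:
                best = float(tot[j])
                btype, bt = _SIG, int(ts[j])

        # nuisance branch: create the state whose window just reached l+1
        t0 = s - l - 1
        if t0 >= -1:
            st = _inner_solver(model, b, l, capacity=n - (t0 + 1))
            for v in x[t0 + 1: s]:
                st.append(v)
            states[t0] = st
        nui_vals: Dict[int, float] = {}
        for t, st in states.items():
            st.append(x[s])
            nui_vals[t] = float(F[t + 1]) + st.objective_bg_last
        if nui_vals:
            # largest-t tie-break
            vbest, tbest = None, None
            for t in sorted(nui_vals):
                v = nui_vals[t]
                if vbest is None or v <= vbest:
                    vbest, tbest = v, t
            if vbest + bp < best:
                best = vbest + bp
                btype, bt = _NUI, tbest

        F[s + 1] = best
        ptype[s + 1] = btype
        pt[s + 1] = bt

        # prune dominated nuisance candidates
        if cfg.pruning != "none" and len(nui_vals) > 1:
            if cfg.pruning == "local":
                window = {t for t in nui_vals if t + 1 > s - cfg.A_n}
            else:
                window = set(nui_vals)
            if len(window) > 1:
                vmin = min(nui_vals[t] for t in window)
                for t in window:
                    if nui_vals[t] >= vmin + margin:
                        del states[t]

    # traceback
    free_signals: List[tuple[int, int]] = []
    nuis_windows: List[tuple[int, int]] = []
    i = n
    while i > 0:
        kind = int(ptype[i])
        if kind == _BG:
            i -= 1
        elif kind == _SIG:
            t = int(pt[i])
            free_signals.append((t + 1, i - 1))
            i = t + 1
        else:
            t = int(pt[i])
            nuis_windows.append((t + 1, i - 1))
            i = t + 1
    free_signals.reverse()
    nuis_windows.reverse()

    # report: re-solve each nuisance window in two-pass mode
    signals: List[SignalSegment] = []
    nuisances: List[NuisanceSegment] = []
    nll = 0.0
    k_total = 0
    for a, e in free_signals:
        st = pre.window(a, e)
        th = mle_param(st, model)
        signals.append(SignalSegment(a, e, th, th - theta0))
        nll += segment_cost(st, model)
        k_total += 1
    for a, e in nuis_windows:
        wn, inner = _resolve_window(x[a: e + 1], model, b, l)
        inner_abs: List[SignalSegment] = []
        win_stats = pre.window(a, e)
        inner_stats_sum = win_stats.__class__()
        for ra, re_ in inner:
            st = pre.window(a + ra, a + re_)
            th = mle_param(st, model)
            inner_abs.append(SignalSegment(a + ra, a + re_, th, float(th - wn)))
            inner_stats_sum = inner_stats_sum.merge(st)
            nll += segment_cost(st, model)
            k_total += 1
        local_bg = win_stats.subtract(inner_stats_sum)
        if local_bg.count > 0:
            nll += fixed_cost(local_bg, model, wn)
        nuisances.append(NuisanceSegment(a, e, wn, tuple(inner_abs)))
        signals.extend(inner_abs)

    covered = sum(g.e - g.s + 1 for g in signals) + sum(
        nu.e - nu.s + 1 - sum(g.e - g.s + 1 for g in nu.inner_signals)
        for nu in nuisances
    )
    seg_stats = pre.window(0, n - 1).__class__()
    for g in signals:
        seg_stats = seg_stats.merge(pre.window(g.s, g.e))
    for nu in nuisances:
        inner_sum = seg_stats.__class__()
        for g in nu.inner_signals:
            inner_sum = inner_sum.merge(pre.window(g.s, g.e))
        seg_stats = seg_stats.merge(pre.window(nu.s, nu.e).subtract(inner_sum))
    global_bg = pre.window(0, n - 1).subtract(seg_stats)
    assert global_bg.count == n - covered
    if global_bg.count > 0:
        nll += fixed_cost(global_bg, model, theta0)

    signals.sort(key=lambda g: g.s)
    total_cost = 2.0 * nll + b * k_total + bp * len(nuisances)
    return NuisanceSegmentation(
        signals=signals,
        nuisances=nuisances,
        theta0=theta0,
        total_cost=total_cost,
        objective=float(F[n]),
        nll=nll,
        n=n,
        beta=b,
        beta_prime=bp,
    )


def nuisance_cost_state(
    x_start: float,
    model: CostModel,
    beta: float,
    l: int,
    capacity: int,
) -> OnlineSolver:
    """Incremental evaluator of the nuisance cost C' for a window.

    The returned solver is seeded with the first window point; append the
    remaining points with :meth:`OnlineSolver.append` and read
    ``objective_bg_last`` for the current C' (the inner epidemic optimum
    with the newest point in the local background, so that nested signals
    stay strictly interior).
    """
    st = _inner_solver(model, beta, l, capacity)
    st.append(x_start)
    return st
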