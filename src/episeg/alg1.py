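"""Epidemic changepoint detection with unknown background level.

The detector minimises the penalised epidemic cost

    F(n) = sum_i C(x[s_i:e_i]) + C0(background points; theta0) + beta * k

where the C terms are twice the negative log-likelihood (deviance scale:
the default penalty ``3 (ln n)^{1+0.1}`` is a strengthened SIC penalty and
SIC compares ``2 * NLL + p ln n``).  Minimisation is by optimal
partitioning, while the background parameter theta0 is replaced
by a running estimate ``w`` that is recalculated, in O(1) amortised work,
from the background points of the current optimal path every time a new
point is classified as background.  A refining second pass repeats the
segmentation with the final estimate held fixed.

:class:`OnlineSolver` is the incremental engine: it consumes one point at a
time and maintains the optimal objective for every prefix, which is what
lets :mod:`episeg.alg2` evaluate nuisance costs recursively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from episeg.costs import (
    VAR_FLOOR,
    CostModel,
    Family,
    Penalty,
    SufficientStats,
    _point_cost,
    _profiled_nll,
    beta as beta_value,
    fixed_cost,
    mle_param,
    segment_cost,
)

#: parent-pointer sentinel for "extend background"
_BG = -2


@dataclass(frozen=True)
class Segment:
    """One epidemic segment: inclusive 0-based indices and its ML level."""

    s: int
    e: int
    theta_hat: float


@dataclass
class Segmentation:
    """Result of the detector on one series.

    ``total_cost`` is the penalised epidemic cost recomputed from the
    reported segments and ``theta0_hat`` (so it satisfies the model
    definition exactly); ``objective`` is the raw dynamic-programming
    optimum, which differs from ``total_cost`` only in online mode where
    early background costs were evaluated at evolving estimates.
    """

    segments: List[Segment]
    theta0_hat: float
    total_cost: float
    objective: float
    nll: float
    w_trajectory: np.ndarray
    n: int
    beta: float

    @property
    def k(self) -> int:
        return len(self.segments)

    def changepoints(self) -> tuple[list[int], list[int]]:
        """(starts, ends) of all reported segments."""
        return [g.s for g in self.segments], [g.e for g in self.segments]


@dataclass(frozen=True)
class Alg1Config:
    """Configuration for the detector.

    ``l`` bounds the segment length (``None`` = unlimited).  ``beta``
    overrides the ``penalty``-derived value when given.  ``mode`` selects
    the online (single-pass) or two-pass variant.
    """

    model: CostModel = CostModel()
    l: Optional[int] = None
    penalty: Penalty = Penalty()
    beta: Optional[float] = None
    mode: str = "two_pass"  # "online" | "two_pass"
    prune: bool = True
    min_seg_len: int = 1
    theta0_init: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("online", "two_pass"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_seg_len < 1:
            raise ValueError("min_seg_len must be >= 1")
        if self.l is not None and self.l < self.min_seg_len:
            raise ValueError(f"l={self.l} < min_seg_len={self.min_seg_len}")

    def resolve_beta(self, n: int) -> float:
        return self.beta if self.beta is not None else beta_value(n, self.penalty)


def update_background(
    stats: SufficientStats, x_t: float, model: CostModel
) -> tuple[SufficientStats, float]:
    """Append one background point and return the updated estimator value.

    The estimator is the sample mean for a change in mean, or the mean
    squared deviation from the known mean for a change in variance; both
    update in O(1) from the running sums.
    """
    out = stats.append(x_t)
    return out, mle_param(out, model)


class OnlineSolver:
    """Incremental optimal-partitioning solver for the epidemic cost.

    Points are consumed left to right; after each :meth:`append` the solver
    holds the optimal penalised cost of the prefix seen so far
    (:attr:`objective`), the optimal cost with the newest point forced to
    the background class (:attr:`objective_bg_last`), and enough state to
    trace the optimal path back.

    ``forbid_first`` excludes segments that contain the first point of the
    window (used for nested sub-problems where segments must lie strictly
    inside).  ``append(x, allow_segment=False)`` likewise forbids a segment
    ending at that point.
    """

    def __init__(
        self,
        model: CostModel,
        beta: float,
        l: Optional[int],
        capacity: int,
        min_seg_len: int = 1,
        theta0_fixed: Optional[float] = None,
        theta0_init: Optional[float] = None,
        prune: bool = True,
        forbid_first: bool = False,
    ):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.model = model
        self.beta = float(beta)
        self.l = capacity if l is None else int(l)
        if self.l < min_seg_len:
            raise ValueError(f"l={self.l} < min_seg_len={min_seg_len}")
        self.min_seg_len = int(min_seg_len)
        self.theta0_fixed = theta0_fixed
        self.theta0_init = theta0_init
        self.prune = prune
        self.forbid_first = forbid_first

        n = capacity
        self.F = np.empty(n + 1)
        self.F[0] = 0.0
        self.parent = np.empty(n + 1, dtype=np.int64)
        self.P1 = np.zeros(n + 1)
        self.P2 = np.zeros(n + 1)
        self.bgc = np.zeros(n + 1, dtype=np.int64)
        self.bgs = np.zeros(n + 1)
        self.bgs2 = np.zeros(n + 1)
        self.w_traj = np.empty(n)
        self._cand = np.empty(n + 1, dtype=np.int64)
        self._ncand = 0
        self.m = 0
        self._first: Optional[float] = None
        self._last_bg_val = math.nan
        self.max_candidates = 0  # diagnostics for debug logging

    # -- background estimator ------------------------------------------------
    def _estimate(self, c: int, s1: float, s2: float) -> float:
        if self.model.family is Family.gauss_mean:
            return s1 / c
        mu = self.model.fixed_param
        return max((s2 - 2.0 * mu * s1 + c * mu * mu) / c, VAR_FLOOR)

    def _init_w(self) -> float:
        if self.theta0_init is not None:
            return self.theta0_init
        x0 = self._first if self._first is not None else 0.0
        if self.model.family is Family.gauss_mean:
            return x0
        d = x0 - self.model.fixed_param
        return max(d * d, VAR_FLOOR)

    @property
    def w(self) -> float:
        """Current background-parameter estimate."""
        if self.theta0_fixed is not None:
            return float(self.theta0_fixed)
        m = self.m
        if self.bgc[m] > 0:
            return float(self._estimate(self.bgc[m], self.bgs[m], self.bgs2[m]))
        return float(self._init_w())

    # -- main recursion ------------------------------------------------------
    def append(self, x: float, allow_segment: bool = True) -> None:
        m = self.m
        x = float(x)
        if m == 0:
            self._first = x
        self.P1[m + 1] = self.P1[m] + x
        self.P2[m + 1] = self.P2[m] + x * x

        # background branch, using the estimate from the incumbent path
        if self.theta0_fixed is not None:
            w = self.theta0_fixed
        elif self.bgc[m] > 0:
            w = self._estimate(self.bgc[m], self.bgs[m], self.bgs2[m])
        else:
            w = self._init_w()
        bg_val = self.F[m] + 2.0 * _point_cost(x, self.model, w)
        self._last_bg_val = bg_val
        best = bg_val
        choice = _BG

        # admit the candidate whose segment would end here at minimal length
        tn = m - self.min_seg_len
        if tn >= -1 and not (self.forbid_first and tn == -1):
            self._cand[self._ncand] = tn
            self._ncand += 1
        # expire candidates whose segment would exceed l
        if self._ncand:
            ts = self._cand[: self._ncand]
            keep = ts >= m - self.l
            if not keep.all():
                kept = ts[keep]
                self._ncand = kept.size
                self._cand[: self._ncand] = kept

        tot = None
        if allow_segment and self._ncand:
            ts = self._cand[: self._ncand]
            cnt = (m - ts).astype(float)
            s1 = self.P1[m + 1] - self.P1[ts + 1]
            s2 = self.P2[m + 1] - self.P2[ts + 1]
            seg = 2.0 * _profiled_nll(cnt, s1, s2, self.model)
            tot = self.F[ts + 1] + seg + self.beta
            # argmin with largest-t (shortest segment) tie-break
            j = tot.size - 1 - int(np.argmin(tot[::-1]))
            if tot[j] < best:
                best = float(tot[j])
                choice = int(ts[j])

        self.F[m + 1] = best
        self.parent[m + 1] = choice
        if choice == _BG:
            self.bgc[m + 1] = self.bgc[m] + 1
            self.bgs[m + 1] = self.bgs[m] + x
            self.bgs2[m + 1] = self.bgs2[m] + x * x
        else:
            j = choice + 1
            self.bgc[m + 1] = self.bgc[j]
            self.bgs[m + 1] = self.bgs[j]
            self.bgs2[m + 1] = self.bgs2[j]

        if self.theta0_fixed is not None:
            self.w_traj[m] = self.theta0_fixed
        elif self.bgc[m + 1] > 0:
            self.w_traj[m] = self._estimate(
                self.bgc[m + 1], self.bgs[m + 1], self.bgs2[m + 1]
            )
        else:
            self.w_traj[m] = self._init_w()

        self.max_candidates = max(self.max_candidates, self._ncand)
        # PELT prune: F(t) + C(x[t+1:m]) >= F(m) => t can never win again.
        # Only exact when every future window extension is itself an
        # admissible segment, which requires min_seg_len == 1.
        if self.prune and tot is not None and self.min_seg_len == 1:
            keep = (tot - self.beta) < best
            if not keep.all():
                kept = self._cand[: self._ncand][keep]
                self._ncand = kept.size
                self._cand[: self._ncand] = kept

        self.m = m + 1

    # -- results -------------------------------------------------------------
    @property
    def objective(self) -> float:
        return float(self.F[self.m])

    @property
    def objective_bg_last(self) -> float:
        """Optimal prefix cost with the newest point forced to background."""
        return self._last_bg_val

    def segments(self) -> List[tuple[int, int]]:
        """Traceback of the optimal path: inclusive (s, e) index pairs."""
        out: List[tuple[int, int]] = []
        i = self.m
        while i > 0:
            p = int(self.parent[i])
            if p == _BG:
                i -= 1
            else:
                out.append((p + 1, i - 1))
                i = p + 1
        out.reverse()
        return out

    def window_stats(self, a: int, b: int) -> SufficientStats:
        return SufficientStats(
            b - a + 1,
            float(self.P1[b + 1] - self.P1[a]),
            float(self.P2[b + 1] - self.P2[a]),
        )


def _build_segmentation(
    solver: OnlineSolver,
    theta0_hat: float,
    n: int,
    beta: float,
    model: CostModel,
) -> Segmentation:
    pairs = solver.segments()
    segs = [
        Segment(a, b, mle_param(solver.window_stats(a, b), model)) for a, b in pairs
    ]
    total_stats = solver.window_stats(0, n - 1)
    bg_stats = total_stats
    nll = 0.0
    for a, b in pairs:
        st = solver.window_stats(a, b)
        bg_stats = bg_stats.subtract(st)
        nll += segment_cost(st, model)
    if bg_stats.count > 0:
        nll += fixed_cost(bg_stats, model, theta0_hat)
    total_cost = 2.0 * nll + beta * len(segs)
    return Segmentation(
        segments=segs,
        theta0_hat=theta0_hat,
        total_cost=total_cost,
        objective=solver.objective,
        nll=nll,
        w_trajectory=solver.w_traj[:n].copy(),
        n=n,
        beta=beta,
    )


def fit_pass(
    x: Sequence[float],
    cfg: Alg1Config,
    theta0_fixed: Optional[float] = None,
) -> Segmentation:
    """One forward pass of the detector.

    With ``theta0_fixed`` the online update is disabled and the pass is an
    exact optimal partitioning of the epidemic cost at that background
    value; otherwise the background estimate evolves online.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    n = x.size
    b = cfg.resolve_beta(n)
    solver = OnlineSolver(
        cfg.model,
        b,
        cfg.l,
        capacity=n,
        min_seg_len=cfg.min_seg_len,
        theta0_fixed=theta0_fixed,
        theta0_init=cfg.theta0_init,
        prune=cfg.prune,
    )
    for v in x:
        solver.append(v)
    theta0_hat = theta0_fixed if theta0_fixed is not None else solver.w
    return _build_segmentation(solver, theta0_hat, n, b, cfg.model)


def fit(x: Sequence[float], cfg: Alg1Config = Alg1Config()) -> Segmentation:
    """Run the detector in the configured mode.

    ``two_pass`` reruns the segmentation with the final online background
    estimate held fixed, refining changepoints near the start of the data;
    the reported ``theta0_hat`` and ``w_trajectory`` stay those of pass 1.
    """
    if cfg.mode == "online":
        return fit_pass(x, cfg)
    pass1 = fit_pass(x, cfg)
    pass2 = fit_pass(x, cfg, theta0_fixed=pass1.theta0_hat)
    return replace(pass2, w_trajectory=pass1.w_trajectory)
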