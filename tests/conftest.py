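"""Shared fixtures and independent reference implementations.

The reference code here is deliberately naive: exhaustive enumeration and
plain-python recursions, written without any of the package's dynamic
programming, pruning or incremental machinery, so that it provides a
genuinely independent route to the same quantities.

Objectives live on the deviance scale (2 x negative log-likelihood plus
penalties), matching the SIC-style penalty calibration of the detectors.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from episeg.costs import CostModel, Family, VAR_FLOOR

LOG_2PI = math.log(2.0 * math.pi)


def point_nll(x: float, model: CostModel, theta: float) -> float:
    """Pointwise -log density, written directly from the formulas."""
    if model.family is Family.gauss_mean:
        v = model.fixed_param
        return 0.5 * (LOG_2PI + math.log(v)) + (x - theta) ** 2 / (2.0 * v)
    var = max(theta, VAR_FLOOR)
    return 0.5 * (LOG_2PI + math.log(var)) + (x - model.fixed_param) ** 2 / (2.0 * var)


def window_mle(xs, model: CostModel) -> float:
    xs = np.asarray(xs, dtype=float)
    if model.family is Family.gauss_mean:
        return float(xs.mean())
    return max(float(np.mean((xs - model.fixed_param) ** 2)), VAR_FLOOR)


def window_segment_cost(xs, model: CostModel) -> float:
    """Profiled window NLL via pointwise summation at the window MLE."""
    th = window_mle(xs, model)
    return sum(point_nll(v, model, th) for v in xs)


def brute_force_alg1(x, model, theta0, beta, l, min_len=1):
    """Exhaustive minimum of the epidemic cost at fixed background theta0.

    Enumerates every admissible placement of disjoint segments (lengths in
    [min_len, l]) over the series; O(2^n), for tiny n only.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    pc = [2.0 * point_nll(v, model, theta0) for v in x]
    best = [math.inf]

    def rec(i: int, acc: float) -> None:
        if i == n:
            best[0] = min(best[0], acc)
            return
        rec(i + 1, acc + pc[i])  # x[i] background
        for j in range(i + min_len - 1, min(n, i + l)):
            rec(j + 1, acc + 2.0 * window_segment_cost(x[i: j + 1], model) + beta)

    rec(0, 0.0)
    return best[0]


def naive_online_alg1(x, model, beta, l, theta0_init=None, forbid_first=False,
                      force_bg_last=False):
    """Plain-loop mirror of the online detector's forward recursion.

    At every step the background points of the incumbent optimal path are
    re-derived from scratch by walking the parent pointers, and the running
    estimate is recomputed from those raw points -- no shared incremental
    state with the package implementation.  Returns the final optimum.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    F = [0.0]
    parent = [None]  # None = root; -2 = background; t = segment start-1

    def bg_points(upto: int):
        pts = []
        i = upto
        while i > 0:
            p = parent[i]
            if p == -2:
                pts.append(x[i - 1])
                i -= 1
            else:
                i = p + 1
        return pts[::-1]

    def estimate(upto: int) -> float:
        pts = bg_points(upto)
        if pts:
            return window_mle(pts, model)
        if theta0_init is not None:
            return theta0_init
        if model.family is Family.gauss_mean:
            return float(x[0])
        return max((float(x[0]) - model.fixed_param) ** 2, VAR_FLOOR)

    for s in range(n):
        w = estimate(s)
        best = F[s] + 2.0 * point_nll(x[s], model, w)
        choice = -2
        if not (force_bg_last and s == n - 1):
            lo = max(-1, s - l)
            if forbid_first:
                lo = max(lo, 0)
            for t in range(s - 1, lo - 1, -1):  # largest t first: shortest segment
                cand = F[t + 1] + 2.0 * window_segment_cost(x[t + 1: s + 1], model) + beta
                if cand < best:
                    best = cand
                    choice = t
        F.append(best)
        parent.append(choice)
    segs = []
    i = n
    while i > 0:
        p = parent[i]
        if p == -2:
            i -= 1
        else:
            segs.append((p + 1, i - 1))
            i = p + 1
    return F[n], segs[::-1], estimate(n)


def brute_force_alg2(x, model, theta0, beta, beta_prime, l):
    """Exhaustive minimum of the nuisance-robust cost.

    Top-level blocks are background points, signal segments (length <= l)
    and nuisance windows (length > l); each nuisance window is priced by
    the naive online epidemic solver with nested segments held strictly
    interior (first and last window points in the local background).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    pc = [2.0 * point_nll(v, model, theta0) for v in x]
    best = [math.inf]

    def nuisance_cost(a: int, b: int) -> float:
        val, _, _ = naive_online_alg1(
            x[a: b + 1], model, beta, l, forbid_first=True, force_bg_last=True
        )
        return val

    def rec(i: int, acc: float) -> None:
        if i == n:
            best[0] = min(best[0], acc)
            return
        rec(i + 1, acc + pc[i])
        for j in range(i, min(n, i + l)):  # signal: length 1..l
            rec(j + 1, acc + 2.0 * window_segment_cost(x[i: j + 1], model) + beta)
        for j in range(i + l, n):  # nuisance: length > l
            rec(j + 1, acc + nuisance_cost(i, j) + beta_prime)

    rec(0, 0.0)
    return best[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gauss_model():
    return CostModel(Family.gauss_mean, 1.0)


@pytest.fixture
def var_model():
    return CostModel(Family.gauss_var, 0.0)
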