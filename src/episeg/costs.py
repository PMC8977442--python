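"""Gaussian segment costs, penalties and sufficient statistics.

All costs are full negative log-likelihoods (``-log f``), *including* the
normalising constants: background and segment terms are compared directly,
so the constants must be carried consistently (they do not cancel for
variance changes).  Natural logarithms throughout.

Two one-parameter families are supported:

* ``gauss_mean`` -- change in mean of a Gaussian with known variance
  (``fixed_param`` is sigma^2);
* ``gauss_var`` -- change in variance with known mean
  (``fixed_param`` is mu; the free parameter theta is the variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Union

import numpy as np

_LOG_2PI = math.log(2.0 * math.pi)

#: floor applied to variance ML estimates so costs stay finite on
#: (near-)constant windows
VAR_FLOOR = 1e-12


class Family(str, Enum):
    """Distribution family with one changing parameter."""

    gauss_mean = "gauss_mean"
    gauss_var = "gauss_var"


@dataclass(frozen=True)
class CostModel:
    """Family plus its known, fixed parameter.

    For ``gauss_mean`` the fixed parameter is the (positive) variance; for
    ``gauss_var`` it is the known mean.
    """

    family: Family = Family.gauss_mean
    fixed_param: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.family is Family.gauss_mean and not self.fixed_param > 0:
            raise ValueError(
                f"gauss_mean requires a positive known variance, got {self.fixed_param}"
            )


@dataclass(frozen=True)
class SufficientStats:
    """Running (count, sum, sum of squares) of a window of observations."""

    count: int = 0
    sum: float = 0.0
    sum_sq: float = 0.0

    def append(self, x: float) -> "SufficientStats":
        return SufficientStats(self.count + 1, self.sum + x, self.sum_sq + x * x)

    def merge(self, other: "SufficientStats") -> "SufficientStats":
        return SufficientStats(
            self.count + other.count,
            self.sum + other.sum,
            self.sum_sq + other.sum_sq,
        )

    def subtract(self, other: "SufficientStats") -> "SufficientStats":
        """Stats of a window minus a disjoint sub-window contained in it."""
        return SufficientStats(
            self.count - other.count,
            self.sum - other.sum,
            self.sum_sq - other.sum_sq,
        )


def stats_of(window: Iterable[float]) -> SufficientStats:
    """Exact sufficient statistics of a (possibly empty) window."""
    arr = np.asarray(list(window) if not isinstance(window, np.ndarray) else window,
                     dtype=float)
    if arr.size == 0:
        return SufficientStats()
    return SufficientStats(int(arr.size), float(arr.sum()), float((arr * arr).sum()))


class PrefixStats:
    """Prefix sums of a series for O(1) window statistics."""

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        self.n = x.size
        self.s1 = np.concatenate(([0.0], np.cumsum(x)))
        self.s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def window(self, a: int, b: int) -> SufficientStats:
        """Stats of ``x[a:b+1]`` (inclusive 0-based indices)."""
        if b < a:
            return SufficientStats()
        return SufficientStats(
            b - a + 1,
            float(self.s1[b + 1] - self.s1[a]),
            float(self.s2[b + 1] - self.s2[a]),
        )


def _rss(count, s1, s2, center):
    """Sum of squared deviations from ``center`` given raw sums."""
    return s2 - 2.0 * center * s1 + count * center * center


def _fixed_nll(count, s1, s2, model: CostModel, theta):
    if model.family is Family.gauss_mean:
        v = model.fixed_param
        return 0.5 * count * (_LOG_2PI + math.log(v)) + _rss(count, s1, s2, theta) / (2.0 * v)
    # gauss_var: theta is the variance, mean is known
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("variance parameter must be positive")
    mu = model.fixed_param
    return 0.5 * count * (_LOG_2PI + np.log(theta)) + _rss(count, s1, s2, mu) / (2.0 * theta)


def _mle(count, s1, s2, model: CostModel):
    if model.family is Family.gauss_mean:
        return s1 / count
    mu = model.fixed_param
    return np.maximum(_rss(count, s1, s2, mu) / count, VAR_FLOOR)


def _profiled_nll(count, s1, s2, model: CostModel):
    """Segment cost: negative log-likelihood at the ML parameter."""
    if model.family is Family.gauss_mean:
        v = model.fixed_param
        rss = s2 - s1 * s1 / count
        # guard tiny negative round-off
        rss = np.maximum(rss, 0.0)
        return 0.5 * count * (_LOG_2PI + math.log(v)) + rss / (2.0 * v)
    mu = model.fixed_param
    rss = np.maximum(_rss(count, s1, s2, mu), 0.0)
    vhat = np.maximum(rss / count, VAR_FLOOR)
    return 0.5 * count * (_LOG_2PI + np.log(vhat)) + rss / (2.0 * vhat)


def _point_cost(x: float, model: CostModel, theta: float) -> float:
    """Negative log density of a single observation at parameter ``theta``."""
    if model.family is Family.gauss_mean:
        v = model.fixed_param
        d = x - theta
        return 0.5 * (_LOG_2PI + math.log(v)) + d * d / (2.0 * v)
    var = max(theta, VAR_FLOOR)
    d = x - model.fixed_param
    return 0.5 * (_LOG_2PI + math.log(var)) + d * d / (2.0 * var)


def fixed_cost(stats: SufficientStats, model: CostModel, theta: float) -> float:
    """Full Gaussian NLL of a window at a given parameter value."""
    if stats.count == 0:
        return 0.0
    if model.family is Family.gauss_var and theta <= 0:
        raise ValueError(f"variance parameter must be positive, got {theta}")
    return float(_fixed_nll(stats.count, stats.sum, stats.sum_sq, model, theta))


def mle_param(stats: SufficientStats, model: CostModel) -> float:
    """ML parameter of a window: sample mean, or mean squared deviation
    from the known mean (biased/ML form, divisor = count)."""
    if stats.count < 1:
        raise ValueError("mle_param requires a non-empty window")
    return float(_mle(stats.count, stats.sum, stats.sum_sq, model))


def segment_cost(stats: SufficientStats, model: CostModel) -> float:
    """Window NLL profiled at the ML parameter.

    Superadditive under concatenation, which justifies PELT pruning.
    """
    if stats.count < 1:
        raise ValueError("segment_cost requires a non-empty window")
    return float(_profiled_nll(stats.count, stats.sum, stats.sum_sq, model))


@dataclass(frozen=True)
class Penalty:
    """Strengthened-SIC penalty beta(n) = alpha * (ln n)^(1+delta)."""

    alpha: float = 3.0
    delta: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.delta <= 0:
            raise ValueError("penalty requires alpha > 0 and delta > 0")


def beta(n: int, penalty: Penalty = Penalty()) -> float:
    """Per-segment penalty ``alpha * (ln n)^(1+delta)`` (natural log)."""
    if n < 2:
        raise ValueError(f"penalty defined for n >= 2, got n={n}")
    return penalty.alpha * math.log(n) ** (1.0 + penalty.delta)


def delta_strength(mu0: float, sigma0: float, mu_i: float, sigma_i: float) -> float:
    """Signal-strength measure of a segment relative to the background.

    ``d~ = ln(((mu0-mu_i)^2 + 2(sigma0^2 + sigma_i^2)) / (4 sigma0 sigma_i))``
    and the returned strength is ``min(d~, d~^2)``.  Zero iff the segment
    distribution equals the background.  Used by design helpers to check
    the detectability bound ``(e_i - s_i) * strength > (ln n)^(1+delta)``.
    """
    if sigma0 <= 0 or sigma_i <= 0:
        raise ValueError("scales must be positive")
    arg = ((mu0 - mu_i) ** 2 + 2.0 * (sigma0 ** 2 + sigma_i ** 2)) / (4.0 * sigma0 * sigma_i)
    d = math.log(arg)
    return min(d, d * d)


ModelLike = Union[CostModel, str]
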