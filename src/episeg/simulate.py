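"""Synthetic scenario generator and Monte-Carlo study driver.

Six named scenarios cover the evaluation settings: three single-process
designs (``one_segment``, ``multiple``, ``heavy_tail``) for the plain
epidemic detector, and three signal/nuisance designs (``overlap1``,
``overlap2``, ``many_weak``) for the nuisance-robust detector.

Index convention: time is 1-based t = 1..n and a half-open interval
``(a*n, b*n]`` of the unit design maps to integer times
``floor(a*n)+1 .. floor(b*n)``, i.e. 0-based indices
``floor(a*n) .. floor(b*n)-1`` inclusive.  The same convention is used for
ground truth and scoring, so the 0.05n localisation windows are consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from episeg import alg1, alg2, evaluate
from episeg.costs import CostModel, Family

SCENARIOS = (
    "one_segment",
    "multiple",
    "heavy_tail",
    "overlap1",
    "overlap2",
    "many_weak",
)

#: default signal-length bound, as a fraction of n, for each scenario
DEFAULT_L_FRAC: Dict[str, float] = {
    "one_segment": 0.5,
    "multiple": 0.5,
    "heavy_tail": 0.5,
    "overlap1": 0.33,
    "overlap2": 0.15,
    "many_weak": 0.2,
}

#: known noise variance used by the detector cost in each scenario
NOISE_VARIANCE: Dict[str, float] = {
    "one_segment": 1.0,
    "multiple": 1.0,
    "heavy_tail": 3.0,  # variance of a t(3) variate
    "overlap1": 1.0,
    "overlap2": 1.0,
    "many_weak": 1.0,
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Named scenario at a given size and seed."""

    name: str
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class GroundTruth:
    """True structure behind a generated series.

    Segment entries are ``(s, e, level)`` with inclusive 0-based indices.
    """

    n: int
    signal_segments: List[Tuple[int, int, float]]
    nuisance_segments: List[Tuple[int, int, float]] = field(default_factory=list)
    noise: str = "gauss"

    def signal_changepoints(self) -> tuple[list[int], list[int]]:
        return (
            [s for s, _, _ in self.signal_segments],
            [e for _, e, _ in self.signal_segments],
        )


def interval_indices(a: float, b: float, n: int) -> Tuple[int, int]:
    """0-based inclusive index range of design interval ``(a*n, b*n]``."""
    s = math.floor(a * n + 1e-9)
    e = math.floor(b * n + 1e-9) - 1
    return s, e


def _scenario_truth(name: str, n: int, rng: np.random.Generator) -> GroundTruth:
    iv = interval_indices
    if name == "one_segment":
        s, e = iv(0.3, 0.5, n)
        return GroundTruth(n, [(s, e, 3.0)])
    if name == "multiple":
        return GroundTruth(
            n,
            [
                (*iv(0.2, 0.3, n), -1.0),
                (*iv(0.5, 0.6, n), 1.0),
                (*iv(0.7, 0.8, n), -1.0),
            ],
        )
    if name == "heavy_tail":
        s, e = iv(0.2, 0.6, n)
        return GroundTruth(n, [(s, e, 2.0)], noise="t3")
    if name == "overlap1":
        return GroundTruth(
            n,
            [(*iv(0.3, 0.5, n), 2.0)],
            nuisance_segments=[(*iv(0.2, 0.7, n), 2.0)],
        )
    if name == "overlap2":
        return GroundTruth(
            n,
            [(*iv(0.5, 0.6, n), 3.0), (*iv(0.7, 0.8, n), -3.0)],
            nuisance_segments=[(*iv(0.2, 0.4, n), 1.5)],
        )
    if name == "many_weak":
        levels = rng.uniform(-4.0, 4.0, size=9)
        segs = []
        for j in range(1, 10):
            s, e = iv(0.1 * j, 0.1 * j + 0.05, n)
            segs.append((s, e, float(levels[j - 1])))
        return GroundTruth(n, segs)
    raise ValueError(f"unknown scenario {name!r}")


def mean_vector(truth: GroundTruth) -> np.ndarray:
    """Piecewise mean of the series: additive signal + nuisance levels."""
    mu = np.zeros(truth.n)
    for s, e, level in truth.signal_segments + truth.nuisance_segments:
        mu[s: e + 1] += level
    return mu


def generate(spec: ScenarioSpec) -> Tuple[np.ndarray, GroundTruth]:
    """Generate one replicate series and its ground truth.

    Random segment levels (``many_weak``) are drawn before the noise, from
    the same seeded stream, so a replicate is fully determined by the seed.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _scenario_truth(spec.name, spec.n, rng)
    mu = mean_vector(truth)
    if truth.noise == "t3":
        noise = rng.standard_t(3, size=spec.n)
    else:
        noise = rng.standard_normal(spec.n)
    return mu + noise, truth


def _default_detector_cfg(scenario: str, n: int, detector: str, overrides: dict):
    l_frac = overrides.pop("l_frac", DEFAULT_L_FRAC[scenario])
    l = overrides.pop("l", None)
    if l is None:
        l = int(round(l_frac * n))
    sigma2 = overrides.pop("sigma2", NOISE_VARIANCE[scenario])
    model = overrides.pop("model", CostModel(Family.gauss_mean, sigma2))
    if detector == "alg1":
        return alg1.Alg1Config(model=model, l=l, **overrides)
    if detector == "alg2":
        overrides.setdefault("theta0", 0.0)
        return alg2.Alg2Config(model=model, l=l, **overrides)
    raise ValueError(f"unknown detector {detector!r}")


def run_cell(
    scenario: str,
    n: int,
    reps: int,
    base_seed: int,
    detector: str = "alg1",
    **detector_kwargs,
):
    """Run one (scenario, n) study cell: ``reps`` generate+fit replicates.

    Each replicate uses the independent substream ``base_seed + rep``.
    Returns the list of fitted results and the matching ground truths.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = _default_detector_cfg(scenario, n, detector, dict(detector_kwargs))
    fits, truths = [], []
    for rep in range(reps):
        x, truth = generate(ScenarioSpec(scenario, n, base_seed + rep))
        if detector == "alg1":
            fits.append(alg1.fit(x, cfg))
        else:
            fits.append(alg2.fit(x, cfg))
        truths.append(truth)
    return fits, truths


def summarize_cell(fits, truths, n: int) -> Dict[str, float]:
    """Standard metrics for one study cell."""
    out: Dict[str, float] = {
        "mean_segments": evaluate.mean_segments(fits, kind="signal"),
        "tpr": evaluate.tpr(fits, truths, n),
        "ppv": evaluate.ppv(fits, truths, n),
    }
    if isinstance(fits[0], alg2.NuisanceSegmentation):
        out["mean_nuisance_segments"] = evaluate.mean_segments(fits, kind="nuisance")
    if all(len(t.signal_segments) == 1 for t in truths):
        out["theta_s"] = evaluate.theta_s_estimate(fits, truths)
    return out


def study(
    scenario: str,
    n_grid: Sequence[int],
    reps: int,
    base_seed: int,
    detector: str = "alg1",
    **detector_kwargs,
) -> pd.DataFrame:
    """Monte-Carlo study over a grid of sample sizes.

    Returns a long-format table with columns
    ``(scenario, n, reps, metric, value)``.
    """
    rows = []
    for n in n_grid:
        fits, truths = run_cell(
            scenario, n, reps, base_seed, detector=detector, **detector_kwargs
        )
        for metric, value in summarize_cell(fits, truths, n).items():
            rows.append(
                {"scenario": scenario, "n": n, "reps": reps,
                 "metric": metric, "value": value}
            )
    return pd.DataFrame(rows)
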