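"""Detection scoring: TPR, PPV, segment-count summaries, effects, SIC.

A reported changepoint is "correct" when it lies strictly within 0.05n
index units of a true signal changepoint; for the nuisance-robust detector
the type must match too (starts against true starts, ends against true
ends).  Nuisance segments are model structure, not detections, so their
boundaries enter neither the TPR nor the PPV counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from episeg.alg1 import Segmentation
from episeg.alg2 import NuisanceSegmentation

#: localisation tolerance as a fraction of n (strict inequality)
TOL_FRAC = 0.05

Result = Union[Segmentation, NuisanceSegmentation]


@dataclass
class DetectionScore:
    """Summary of one study cell."""

    tpr: float
    ppv: float
    mean_segments: float
    mean_loc_error: float
    bias: float


@dataclass(frozen=True)
class BiasResult:
    """Segment-count bias; absolute excess (flagged) when the true count is 0."""

    value: float
    relative: bool


def _is_typed(result: Result) -> bool:
    return isinstance(result, NuisanceSegmentation)


def _reported_cps(result: Result) -> tuple[list[int], list[int]]:
    if isinstance(result, NuisanceSegmentation):
        return result.signal_changepoints()
    return result.changepoints()


def _true_cps(truth) -> tuple[list[int], list[int]]:
    return truth.signal_changepoints()


def _covered(target: int, reported: Sequence[int], tol: float) -> bool:
    return any(abs(r - target) < tol for r in reported)


def tpr(results: Sequence[Result], truths: Sequence, n: int) -> float:
    """Fraction of replicates in which every true changepoint is detected.

    A replicate succeeds iff each true signal changepoint has at least one
    reported changepoint strictly within 0.05n.  For the nuisance-robust
    detector the match must be of the correct type (start/end).
    """
    tol = TOL_FRAC * n
    ok = 0
    for res, truth in zip(results, truths, strict=True):
        ts, te = _true_cps(truth)
        if not ts:
            raise ValueError("tpr requires a non-empty ground truth")
        rs, re_ = _reported_cps(res)
        if _is_typed(res):
            success = all(_covered(t, rs, tol) for t in ts) and all(
                _covered(t, re_, tol) for t in te
            )
        else:
            pooled = rs + re_
            success = all(_covered(t, pooled, tol) for t in ts + te)
        ok += success
    return ok / len(results)


def ppv(results: Sequence[Result], truths: Sequence, n: int) -> float:
    """Pooled positive predictive value of the reported changepoints.

    Correct reported changepoints (within 0.05n of a true signal
    changepoint, of the correct type for typed detectors) divided by the
    total number of reported changepoints, pooled over replicates.
    Returns NaN when nothing was reported.
    """
    tol = TOL_FRAC * n
    num = den = 0
    for res, truth in zip(results, truths, strict=True):
        ts, te = _true_cps(truth)
        rs, re_ = _reported_cps(res)
        if _is_typed(res):
            num += sum(_covered(r, ts, tol) for r in rs)
            num += sum(_covered(r, te, tol) for r in re_)
        else:
            pooled_truth = ts + te
            num += sum(_covered(r, pooled_truth, tol) for r in rs + re_)
        den += len(rs) + len(re_)
    return num / den if den else math.nan


def mean_segments(results: Sequence[Result], kind: str = "signal") -> float:
    """Arithmetic mean of reported segment counts.

    ``kind`` selects signal or nuisance counts for the nuisance-robust
    detector; plain segmentations always count their segments.
    """
    counts = []
    for res in results:
        if isinstance(res, NuisanceSegmentation):
            if kind == "signal":
                counts.append(len(res.signals))
            elif kind == "nuisance":
                counts.append(len(res.nuisances))
            else:
                counts.append(len(res.signals) + len(res.nuisances))
        else:
            counts.append(len(res.segments))
    return float(np.mean(counts))


def bias(results: Sequence[Result], truths: Sequence, kind: str = "signal") -> BiasResult:
    """Relative bias in segment counts: (mean reported - true)/true.

    When the true count is zero the relative form is undefined; the mean
    absolute excess is returned instead, flagged via ``relative=False``.
    """
    mean_rep = mean_segments(results, kind=kind)
    if kind == "nuisance":
        true_counts = [len(t.nuisance_segments) for t in truths]
    else:
        true_counts = [len(t.signal_segments) for t in truths]
    true_mean = float(np.mean(true_counts))
    if true_mean == 0:
        return BiasResult(mean_rep, relative=False)
    return BiasResult((mean_rep - true_mean) / true_mean, relative=True)


def mean_loc_error(results: Sequence[Result], truths: Sequence, n: int) -> float:
    """Mean |reported - true| over true changepoints, nearest correct-type
    detection; replicates reporting nothing are skipped.  (A reconstruction
    of an unspecified summary; not used for acceptance checks.)"""
    errs = []
    for res, truth in zip(results, truths, strict=True):
        ts, te = _true_cps(truth)
        rs, re_ = _reported_cps(res)
        if _is_typed(res):
            pairs = [(ts, rs), (te, re_)]
        else:
            pairs = [(ts + te, rs + re_)]
        for targets, reported in pairs:
            if not reported:
                continue
            for t in targets:
                errs.append(min(abs(r - t) for r in reported))
    return float(np.mean(errs)) if errs else math.nan


def _signals_with_effect(res: Result):
    if isinstance(res, NuisanceSegmentation):
        return res.signals
    return [
        type("E", (), {"s": g.s, "e": g.e, "effect": g.theta_hat - res.theta0_hat})()
        for g in res.segments
    ]


def theta_s_estimate(results: Sequence[Result], truths: Sequence) -> float:
    """Mean signal-specific effect of the detection closest to the truth.

    Requires exactly one true signal segment per replicate; replicates with
    no detections are excluded from the average.
    """
    effects = []
    for res, truth in zip(results, truths, strict=True):
        if len(truth.signal_segments) != 1:
            raise ValueError("theta_s_estimate requires exactly one true signal segment")
        s_true, e_true, _ = truth.signal_segments[0]
        sigs = _signals_with_effect(res)
        if not sigs:
            continue
        closest = min(sigs, key=lambda g: abs(g.s - s_true) + abs(g.e - e_true))
        effects.append(closest.effect)
    return float(np.mean(effects)) if effects else math.nan


def sic(result: Result) -> float:
    """Schwarz information criterion of a fitted model.

    ``2 * NLL + p * ln n`` where p counts the free parameters: 3 per signal
    segment (s, e, theta), 3 per nuisance segment (plus 3 per nested
    signal, already counted in the signal list), and 1 per estimated
    background parameter (the global estimate of the plain detector; the
    nuisance-robust detector takes its global background as known).
    """
    n = result.n
    if isinstance(result, NuisanceSegmentation):
        p = 3 * len(result.signals) + 3 * len(result.nuisances)
    else:
        p = 3 * len(result.segments) + 1
    return 2.0 * result.nll + p * math.log(n)
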