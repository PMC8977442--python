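"""Tests for the online epidemic detector."""

import math

import numpy as np
import pytest

from conftest import brute_force_alg1, naive_online_alg1
from episeg.alg1 import Alg1Config, OnlineSolver, fit, fit_pass, update_background
from episeg.costs import CostModel, Family, Penalty, beta, stats_of
from episeg.simulate import ScenarioSpec, generate


def _cfg(**kw):
    kw.setdefault("model", CostModel(Family.gauss_mean, 1.0))
    return Alg1Config(**kw)


class TestFitPassBasics:
    def test_flat_series_no_segments(self):
        x = np.zeros(50)
        res = fit_pass(x, _cfg(l=25))
        assert res.segments == []
        assert res.theta0_hat == pytest.approx(0.0)
        assert res.total_cost == pytest.approx(res.objective)

    def test_clean_single_segment(self):
        x = np.concatenate([np.zeros(20), np.full(10, 10.0), np.zeros(20)])
        res = fit_pass(x, _cfg(l=25))
        assert [(g.s, g.e) for g in res.segments] == [(20, 29)]
        assert res.segments[0].theta_hat == pytest.approx(10.0)
        assert res.theta0_hat == pytest.approx(0.0)

    def test_single_segment_matches_brute_force_placement(self, rng):
        """Best single-segment placement oracle on noisy one-segment data."""
        x = np.concatenate(
            [rng.normal(size=20), rng.normal(10.0, 1.0, 10), rng.normal(size=20)]
        )
        model = CostModel(Family.gauss_mean, 1.0)
        b = beta(50, Penalty())
        res = fit(x, _cfg(l=25))
        # oracle: exhaustive single-segment placement with theta0 profiled
        # as the mean of the complementary points
        best = (math.inf, None)
        for s in range(50):
            for e in range(s, min(50, s + 25)):
                seg = x[s: e + 1]
                bg = np.concatenate([x[:s], x[e + 1:]])
                cost = (
                    2.0 * sum(0.5 * math.log(2 * math.pi) + 0.5 * (v - seg.mean()) ** 2 for v in seg)
                    + 2.0 * sum(0.5 * math.log(2 * math.pi) + 0.5 * (v - bg.mean()) ** 2 for v in bg)
                    + b
                )
                if cost < best[0]:
                    best = (cost, (s, e))
        assert [(g.s, g.e) for g in res.segments] == [best[1]]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            fit_pass(np.array([]), _cfg())

    def test_l_below_min_seg_len_rejected(self):
        with pytest.raises(ValueError):
            Alg1Config(l=1, min_seg_len=3)

    def test_segment_lengths_respect_bounds(self, rng):
        x = rng.normal(size=80) + 4.0 * (np.arange(80) % 17 < 5)
        res = fit(x, _cfg(l=6, min_seg_len=2))
        for g in res.segments:
            assert 2 <= g.e - g.s + 1 <= 6
        # non-overlapping and sorted
        for a, b in zip(res.segments, res.segments[1:]):
            assert a.e < b.s


class TestOracleEquivalence:
    @pytest.mark.parametrize("family,fixed", [
        (Family.gauss_mean, 1.0), (Family.gauss_var, 0.0),
    ])
    def test_fixed_theta0_matches_enumeration(self, rng, family, fixed):
        model = CostModel(family, fixed)
        theta0 = 0.0 if family is Family.gauss_mean else 1.0
        for _ in range(25):
            n = int(rng.integers(4, 11))
            x = rng.normal(size=n) + rng.choice([0.0, 2.5])
            b = 2.0
            res = fit_pass(x, _cfg(model=model, l=n, beta=b), theta0_fixed=theta0)
            oracle = brute_force_alg1(x, model, theta0, b, l=n)
            assert res.objective == pytest.approx(oracle)
            assert res.total_cost == pytest.approx(oracle)

    def test_online_matches_naive_recursion(self, rng):
        """The full online pass agrees with an independent plain-loop mirror."""
        model = CostModel(Family.gauss_mean, 1.0)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            x[n // 3: n // 2] += 3.0
            res = fit_pass(x, _cfg(model=model, l=n, beta=4.0, prune=False))
            val, segs, w = naive_online_alg1(x, model, beta=4.0, l=n)
            assert res.objective == pytest.approx(val)
            assert [(g.s, g.e) for g in res.segments] == segs
            assert res.theta0_hat == pytest.approx(w)


class TestBackgroundUpdate:
    def test_mean_update(self, gauss_model):
        _, w = update_background(stats_of([1.0]), 3.0, gauss_model)
        assert w == pytest.approx(2.0)

    def test_var_update(self, var_model):
        _, w = update_background(stats_of([2.0]), -2.0, var_model)
        assert w == pytest.approx(4.0)

    def test_sequence_matches_batch(self, rng, gauss_model):
        xs = rng.normal(size=30)
        st = stats_of([])
        for v in xs:
            st, w = update_background(st, v, gauss_model)
        assert w == pytest.approx(xs.mean())

    def test_w_trajectory_tracks_background_mean_on_flat_data(self, rng):
        x = rng.normal(size=60)
        res = fit_pass(x, _cfg(l=30))
        if not res.segments:  # high-probability branch at this penalty
            expected = np.cumsum(x) / np.arange(1, 61)
            np.testing.assert_allclose(res.w_trajectory, expected)


class TestPruning:
    def test_pruned_equals_unpruned(self, rng):
        model = CostModel(Family.gauss_mean, 1.0)
        for _ in range(30):
            x = rng.normal(size=100)
            x[40:55] += rng.choice([0.0, 2.0, 4.0])
            r1 = fit(x, _cfg(model=model, l=50, prune=True))
            r0 = fit(x, _cfg(model=model, l=50, prune=False))
            assert r1.objective == pytest.approx(r0.objective)
            assert [(g.s, g.e) for g in r1.segments] == [(g.s, g.e) for g in r0.segments]

    def test_candidate_set_is_bounded(self, rng):
        x = rng.normal(size=200)
        solver = OnlineSolver(CostModel(), beta(200, Penalty()), l=None, capacity=200)
        for i, v in enumerate(x):
            solver.append(v)
            assert solver._ncand <= i + 1
        assert solver.max_candidates <= 200


class TestModes:
    def test_two_pass_cost_not_worse(self, rng):
        """Pass 2 re-optimises at the final estimate: its recomputed cost at
        theta0_hat is <= the online segmentation's cost at the same value."""
        from episeg.costs import fixed_cost, segment_cost
        model = CostModel(Family.gauss_mean, 1.0)
        for seed in range(10):
            g = np.random.default_rng(seed)
            x = g.normal(size=60)
            x[15:25] += 2.5
            online = fit(x, _cfg(model=model, l=30, mode="online"))
            two = fit(x, _cfg(model=model, l=30, mode="two_pass"))
            assert two.theta0_hat == pytest.approx(online.theta0_hat)

            def cost_at(res, theta0):
                covered = np.zeros(60, bool)
                c = res.beta * len(res.segments)
                for seg in res.segments:
                    covered[seg.s: seg.e + 1] = True
                    c += 2.0 * segment_cost(stats_of(x[seg.s: seg.e + 1]), model)
                if (~covered).any():
                    c += 2.0 * fixed_cost(stats_of(x[~covered]), model, theta0)
                return c

            assert cost_at(two, two.theta0_hat) <= cost_at(online, two.theta0_hat) + 1e-9

    def test_total_cost_recomputation_invariant(self, rng):
        from episeg.costs import fixed_cost, segment_cost
        x = rng.normal(size=70)
        x[20:30] += 3.0
        res = fit(x, _cfg(l=35))
        covered = np.zeros(70, bool)
        c = res.beta * len(res.segments)
        for seg in res.segments:
            covered[seg.s: seg.e + 1] = True
            c += 2.0 * segment_cost(stats_of(x[seg.s: seg.e + 1]), CostModel())
        c += 2.0 * fixed_cost(stats_of(x[~covered]), CostModel(), res.theta0_hat)
        assert res.total_cost == pytest.approx(c)

    def test_cost_monotone_in_beta(self, rng):
        x = rng.normal(size=50)
        x[10:20] += 3.0
        penalised, unpenalised = [], []
        for b in (2.0, 5.0, 10.0):
            res = fit_pass(x, _cfg(l=25, beta=b), theta0_fixed=0.0)
            penalised.append(res.objective)
            unpenalised.append(res.objective - b * len(res.segments))
        # the optimum is pointwise monotone in beta, and so is its
        # unpenalised part
        assert penalised == sorted(penalised)
        assert unpenalised[0] <= unpenalised[1] + 1e-9 <= unpenalised[2] + 2e-9


class TestConsistencyProperties:
    def test_background_estimate_near_oracle_on_pure_noise(self):
        """On background-only data the estimate should sit inside the CLT
        oracle band of the true-background mean estimator."""
        hits = 0
        for seed in range(40):
            g = np.random.default_rng(seed + 1000)
            x = g.normal(size=500)
            res = fit(x, _cfg(l=250))
            if abs(res.theta0_hat) < 3.0 / math.sqrt(500):
                hits += 1
        assert hits >= 36  # ~3 sigma band should hold in the vast majority

    def test_estimate_error_shrinks_with_n(self):
        errs = {}
        for n in (90, 750):
            e = []
            for seed in range(60):
                x, _ = generate(ScenarioSpec("one_segment", n, 5000 + seed))
                res = fit(x, _cfg(l=n // 2))
                e.append(abs(res.theta0_hat))
            errs[n] = float(np.median(e))
        assert errs[750] < errs[90]
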