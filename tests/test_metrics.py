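"""Assignment optimality, P/R/F1 arithmetic, normalized RMSE, percentile sweep."""

import itertools

import numpy as np
import pytest

from tomopick import CentroidSet, ParticleSet, match, normalized_rmse, prf, threshold_sweep
from tomopick.metrics import SWEEP_PERCENTILES


def brute_force_min_cost(gt: np.ndarray, pred: np.ndarray) -> float:
    """Minimal total Euclidean cost over all one-to-one assignments, by
    exhaustive permutation enumeration (feasible for <= 7 points per side)."""
    n, m = len(gt), len(pred)
    best = np.inf
    if n <= m:
        for perm in itertools.permutations(range(m), n):
            cost = sum(np.linalg.norm(gt[i] - pred[j]) for i, j in enumerate(perm))
            best = min(best, cost)
    else:
        for perm in itertools.permutations(range(n), m):
            cost = sum(np.linalg.norm(gt[i] - pred[j]) for j, i in enumerate(perm))
            best = min(best, cost)
    return best


class TestMatch:
    def test_identical_sets_all_tp(self):
        pts = np.array([[1.0, 2.0, 3.0], [10.0, 10.0, 10.0]])
        result = match(pts, pts, dist_threshold=2.0)
        assert (result.tp, result.fp, result.fn) == (2, 0, 0)
        assert all(d == 0 for _, _, d in result.pairs)

    def test_optimal_pairing_beats_naive(self):
        """gt {(0,0,0),(0,0,4)} vs pred {(0,0,3),(0,0,-1)}: the optimal
        crossing assignment costs 2, the naive in-order pairing 8."""
        gt = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]])
        pred = np.array([[0.0, 0.0, 3.0], [0.0, 0.0, -1.0]])
        result = match(gt, pred, dist_threshold=2.0)
        total = sum(d for _, _, d in result.pairs)
        assert total == pytest.approx(2.0)
        pairing = {(g, p) for g, p, _ in result.pairs}
        assert pairing == {(0, 1), (1, 0)}

    def test_surplus_counts(self):
        gt = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        pred = gt[:2] + 0.5
        result = match(gt, pred, dist_threshold=2.0)
        assert (result.tp, result.fp, result.fn) == (2, 0, 1)

    def test_count_identities(self, rng):
        for _ in range(10):
            gt = rng.uniform(0, 20, size=(rng.integers(0, 6), 3))
            pred = rng.uniform(0, 20, size=(rng.integers(0, 6), 3))
            result = match(gt, pred, dist_threshold=3.0)
            assert result.tp + result.fp == len(pred)
            assert result.tp + result.fn == len(gt)

    def test_total_cost_matches_permutation_brute_force(self, rng):
        """Optimal-assignment total cost equals the exhaustive permutation
        minimum on many random instances with <= 7 points per side."""
        for trial in range(60):
            n = rng.integers(1, 8)
            m = rng.integers(1, 8)
            gt = rng.uniform(0, 10, size=(n, 3))
            pred = rng.uniform(0, 10, size=(m, 3))
            result = match(gt, pred, dist_threshold=1.0)
            total = sum(d for _, _, d in result.pairs)
            assert total == pytest.approx(brute_force_min_cost(gt, pred), abs=1e-9)

    def test_empty_sets(self):
        result = match(np.zeros((0, 3)), np.ones((3, 3)), dist_threshold=1.0)
        assert (result.tp, result.fp, result.fn) == (0, 3, 0)
        result = match(np.ones((2, 3)), np.zeros((0, 3)), dist_threshold=1.0)
        assert (result.tp, result.fp, result.fn) == (0, 0, 2)

    def test_default_threshold_is_half_diameter(self):
        gt = ParticleSet(np.array([[0.0, 0.0, 0.0]]), diameter=100.0, voxel_size=10.0)
        pred = CentroidSet(np.array([[4.0, 0.0, 0.0]]), np.array([1.0]))
        result = match(gt, pred)  # threshold = 5 px
        assert result.tp == 1
        pred_far = CentroidSet(np.array([[6.0, 0.0, 0.0]]), np.array([1.0]))
        assert match(gt, pred_far).tp == 0


class TestPrf:
    def test_worked_example(self):
        from tomopick.metrics import MatchResult

        result = MatchResult([], tp=2, fp=0, fn=1, dist_threshold=1.0)
        p, r, f1 = prf(result)
        assert p == pytest.approx(1.0)
        assert r == pytest.approx(2 / 3)
        assert f1 == pytest.approx(0.8)

    def test_perfect_prediction(self):
        from tomopick.metrics import MatchResult

        p, r, f1 = prf(MatchResult([], tp=5, fp=0, fn=0, dist_threshold=1.0))
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_zero_prediction_conventions(self):
        from tomopick.metrics import MatchResult

        p, r, f1 = prf(MatchResult([], tp=0, fp=0, fn=3, dist_threshold=1.0))
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_symmetry_swapping_sides(self, rng):
        """Swapping gt and pred swaps precision and recall, F1 unchanged."""
        gt = rng.uniform(0, 10, size=(5, 3))
        pred = rng.uniform(0, 10, size=(3, 3))
        p1, r1, f1a = prf(match(gt, pred, dist_threshold=4.0))
        p2, r2, f1b = prf(match(pred, gt, dist_threshold=4.0))
        assert p1 == pytest.approx(r2)
        assert r1 == pytest.approx(p2)
        assert f1a == pytest.approx(f1b)

    def test_f1_bounded_by_min_side(self, rng):
        gt = rng.uniform(0, 5, size=(6, 3))
        pred = rng.uniform(0, 5, size=(2, 3))
        _, _, f1 = prf(match(gt, pred, dist_threshold=100.0))
        assert f1 <= 2 * 2 / (6 + 2) + 1e-12


class TestNormalizedRmse:
    def test_single_offset(self):
        gt = np.array([[0.0, 0.0, 0.0]])
        pred = np.array([[3.0, 0.0, 0.0]])
        result = match(gt, pred, dist_threshold=5.0)
        assert normalized_rmse(result, diameter=10.0) == pytest.approx(0.3)

    def test_perfect_match_is_zero(self):
        pts = np.array([[1.0, 1.0, 1.0]])
        assert normalized_rmse(match(pts, pts, dist_threshold=1.0), 10.0) == 0.0

    def test_two_tp_rms(self):
        gt = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        pred = np.array([[3.0, 0.0, 0.0], [24.0, 0.0, 0.0]])
        result = match(gt, pred, dist_threshold=5.0)
        assert normalized_rmse(result, 10.0) == pytest.approx(np.sqrt(12.5) / 10)

    def test_no_tp_reported_missing(self):
        result = match(np.zeros((1, 3)), np.full((1, 3), 50.0), dist_threshold=1.0)
        assert normalized_rmse(result, 10.0) is None

    def test_min_side_denominator_variant(self):
        """With min(|gt|, |pred|) in the denominator, unmatched points dilute
        the per-point error instead of being ignored."""
        gt = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        pred = np.array([[3.0, 0.0, 0.0], [100.0, 0.0, 0.0]])  # one TP, one FP
        result = match(gt, pred, dist_threshold=5.0)
        assert normalized_rmse(result, 10.0) == pytest.approx(0.3)  # TP-only
        assert normalized_rmse(result, 10.0, denominator="min_side") == pytest.approx(
            np.sqrt(9.0 / 2) / 10
        )


class TestThresholdSweep:
    def _gt(self, n=10):
        rng = np.random.default_rng(0)
        coords = rng.uniform(5, 60, size=(n, 3))
        return ParticleSet(coords, diameter=100.0, voxel_size=10.0)

    def test_thirteen_rows(self):
        gt = self._gt()
        pred = CentroidSet(gt.coordinates, np.linspace(0.3, 1.0, len(gt)))
        sweep = threshold_sweep(gt, pred)
        assert len(sweep.table) == 13
        assert list(sweep.table["percentile"]) == list(SWEEP_PERCENTILES)

    def test_perfect_uniform_scores_flags_lowest_percentile(self):
        gt = self._gt()
        pred = CentroidSet(gt.coordinates, np.ones(len(gt)))
        sweep = threshold_sweep(gt, pred)
        assert np.allclose(sweep.table["f1"], 1.0)
        assert sweep.best["percentile"] == 2

    def test_confidence_separated_fps_peak_at_separating_percentile(self):
        """When all FPs score below all TPs, F1 rises then falls and F1_max
        occurs once the FPs are thresholded away."""
        gt = self._gt(8)
        fp = np.random.default_rng(1).uniform(70, 90, size=(8, 3))
        points = np.vstack([gt.coordinates, fp])
        scores = np.concatenate([np.linspace(0.8, 1.0, 8), np.linspace(0.1, 0.3, 8)])
        sweep = threshold_sweep(gt, CentroidSet(points, scores))
        assert sweep.f1_max == pytest.approx(1.0)
        # half the predictions are FPs; with data-valued cutoffs the first
        # percentile whose cutoff clears the FP band is 58 (index 8 of 16)
        assert sweep.best["percentile"] == 58
        f1 = sweep.table["f1"].to_numpy()
        peak = int(np.argmax(f1))
        assert np.all(np.diff(f1[: peak + 1]) >= -1e-12)
        assert np.all(np.diff(f1[peak:]) <= 1e-12)

    def test_flagged_row_attains_max(self):
        gt = self._gt()
        rng = np.random.default_rng(2)
        pred = CentroidSet(rng.uniform(0, 70, size=(20, 3)), rng.uniform(size=20))
        sweep = threshold_sweep(gt, pred)
        assert sweep.best["f1"] == sweep.table["f1"].max()
        assert sweep.table.loc[sweep.best_index, "is_best"]

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(self._gt(), CentroidSet(np.zeros((0, 3)), np.zeros(0)))
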