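"""Detection matching, localization scoring and goodness-of-fit metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropcell import metrics
from dropcell.metrics import (
    circle_iou,
    counting_mre,
    localization_score,
    match_detections,
    poisson_chi2,
    poisson_fit_rss,
    prf1,
)


def rasterized_iou(c1, c2, res=0.2):
    """Brute-force oracle: rasterize both disks on a fine grid."""
    x0 = min(c1[0] - c1[2], c2[0] - c2[2]) - 1
    x1 = max(c1[0] + c1[2], c2[0] + c2[2]) + 1
    y0 = min(c1[1] - c1[2], c2[1] - c2[2]) - 1
    y1 = max(c1[1] + c1[2], c2[1] + c2[2]) + 1
    xs = np.arange(x0, x1, res)
    ys = np.arange(y0, y1, res)
    xx, yy = np.meshgrid(xs, ys)
    in1 = (xx - c1[0]) ** 2 + (yy - c1[1]) ** 2 <= c1[2] ** 2
    in2 = (xx - c2[0]) ** 2 + (yy - c2[1]) ** 2 <= c2[2] ** 2
    return (in1 & in2).sum() / (in1 | in2).sum()


class TestCircleIou:
    def test_identical(self):
        assert circle_iou((3, 4, 5), (3, 4, 5)) == pytest.approx(1.0)

    def test_disjoint(self):
        assert circle_iou((0, 0, 2), (10, 0, 2)) == 0.0
        assert circle_iou((0, 0, 2), (4, 0, 2)) == 0.0  # tangent

    def test_concentric_double_radius(self):
        # area ratio pi r^2 / pi (2r)^2 = 1/4 exactly
        assert circle_iou((5, 5, 3), (5, 5, 6)) == pytest.approx(0.25, abs=1e-12)

    @given(
        st.tuples(
            st.floats(-20, 20), st.floats(-20, 20), st.floats(0.5, 10),
            st.floats(-20, 20), st.floats(-20, 20), st.floats(0.5, 10),
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, t):
        c1, c2 = (t[0], t[1], t[2]), (t[3], t[4], t[5])
        v = circle_iou(c1, c2)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(circle_iou(c2, c1), abs=1e-12)

    def test_against_rasterization_oracle(self, rng):
        for _ in range(10):
            c1 = (rng.uniform(0, 10), rng.uniform(0, 10), rng.uniform(2, 8))
            c2 = (rng.uniform(0, 10), rng.uniform(0, 10), rng.uniform(2, 8))
            assert circle_iou(c1, c2) == pytest.approx(
                rasterized_iou(c1, c2), abs=0.02
            )


def optimal_match_count(truth, preds, theta):
    """Exhaustive oracle: max number of one-to-one pairs with IoU >= theta."""
    best = 0
    idx = range(len(preds))
    for k in range(min(len(truth), len(preds)), 0, -1):
        for tsub in itertools.combinations(range(len(truth)), k):
            for psub in itertools.permutations(idx, k):
                if all(
                    circle_iou(truth[t], preds[p]) >= theta
                    for t, p in zip(tsub, psub)
                ):
                    return k
    return best


class TestMatchDetections:
    def test_perfect_predictions(self):
        truth = [(10, 10, 5), (30, 10, 6), (20, 30, 4)]
        m = match_detections(truth, list(truth), 0.5)
        assert m.tp == 3 and m.fp == 0 and m.fn == 0

    def test_empty_predictions(self):
        truth = [(10, 10, 5), (30, 10, 6)]
        m = match_detections(truth, [], 0.5)
        assert m.tp == 0 and m.fn == 2 and m.fp == 0

    def test_near_duplicates_on_one_truth(self):
        truth = [(10, 10, 5), (40, 10, 5), (70, 10, 5)]
        preds = [(10, 10, 5), (10.5, 10, 5)]  # both cover truth 0 only
        m = match_detections(truth, preds, 0.5)
        assert m.tp == 1 and m.fp == 1 and m.fn == 2

    def test_permutation_invariance(self, rng):
        truth = [(rng.uniform(0, 50), rng.uniform(0, 50), rng.uniform(3, 6))
                 for _ in range(5)]
        preds = [(x + rng.normal(0, 1), y + rng.normal(0, 1), r)
                 for x, y, r in truth]
        m1 = match_detections(truth, preds, 0.5)
        perm = list(rng.permutation(len(preds)))
        m2 = match_detections(truth, [preds[i] for i in perm], 0.5)
        assert m1.tp == m2.tp and m1.fp == m2.fp and m1.fn == m2.fn

    def test_one_to_one_and_threshold_respected(self, rng):
        truth = [(rng.uniform(0, 40), rng.uniform(0, 40), rng.uniform(3, 6))
                 for _ in range(4)]
        preds = [(rng.uniform(0, 40), rng.uniform(0, 40), rng.uniform(3, 6))
                 for _ in range(5)]
        m = match_detections(truth, preds, 0.3)
        assert len({i for i, _, _ in m.pairs}) == len(m.pairs)
        assert len({j for _, j, _ in m.pairs}) == len(m.pairs)
        assert all(iou >= 0.3 for _, _, iou in m.pairs)

    def test_matches_exhaustive_oracle_on_small_instances(self, rng):
        # on well-separated instances greedy matching attains the optimum
        for _ in range(5):
            truth = [(rng.uniform(0, 60), rng.uniform(0, 60), rng.uniform(3, 5))
                     for _ in range(3)]
            preds = [(x + rng.normal(0, 2), y + rng.normal(0, 2), r)
                     for x, y, r in truth[:2]]
            m = match_detections(truth, preds, 0.4)
            assert m.tp == optimal_match_count(truth, preds, 0.4)


class TestPrf1:
    def test_perfect(self):
        assert prf1(10, 0, 0) == (1.0, 1.0, 1.0)

    def test_formula(self):
        p, r, f1 = prf1(6, 2, 5)
        assert f1 == pytest.approx(2 * p * r / (p + r))
        # worked example: P=0.8, R=0.6 -> F1 = 0.6857...
        p, r, f1 = prf1(24, 6, 16)
        assert (p, r) == (0.8, 0.6)
        assert f1 == pytest.approx(0.685714, abs=1e-6)

    def test_degenerate(self):
        assert prf1(0, 0, 0) == (0.0, 0.0, 0.0)
        assert prf1(0, 3, 4)[2] == 0.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f1_bounded_by_min_based_bound(self, tp, fp, fn):
        p, r, f1 = prf1(tp, fp, fn)
        lo = min(p, r)
        assert f1 <= 2 * lo / (1 + lo) + 1e-12


class TestLocalizationScore:
    def test_exact_hit(self):
        s = localization_score([(5, 5)], [(5, 5)], 1.0)
        assert s.tp == 1 and s.fp == 0 and s.fn == 0

    def test_outside_valid_area(self):
        s = localization_score([(5, 5)], [(16, 5)], 10.0)
        assert s.tp == 0 and s.fp == 1 and s.fn == 1

    def test_two_predictions_one_centroid(self):
        s = localization_score([(5, 5)], [(5, 6), (6, 5)], 4.0)
        assert s.tp == 1 and s.fp == 1 and s.fn == 0
        assert s.precision == 0.5 and s.recall == 1.0

    def test_nearest_prediction_wins(self):
        s = localization_score([(0, 0), (10, 0)], [(1, 0), (9, 0)], 5.0)
        assert s.tp == 2
        assert s.distances == [1.0, 1.0]


class TestCountingMre:
    def test_perfect(self):
        assert counting_mre([1, 2, 3], [1, 2, 3])[0] == 0.0

    def test_single_droplet_half_error(self):
        assert counting_mre([2], [3])[0] == 0.5

    def test_mixed_set_equals_hand_computation(self):
        true = [1, 2, 4, 5]
        pred = [1, 3, 3, 6]
        expect = np.mean([0, 0.5, 0.25, 0.2])
        assert counting_mre(true, pred)[0] == pytest.approx(expect)

    def test_zero_true_counts_excluded(self):
        mre, excluded = counting_mre([0, 1, 2], [1, 1, 2])
        assert excluded == 1
        assert mre == 0.0


class TestPoissonFit:
    def test_rss_zero_on_curve(self):
        from dropcell.poisson import PoissonModel, rates

        obs = [(lam, rates(PoissonModel(lam)).single) for lam in (0.1, 0.5, 1.0)]
        assert poisson_fit_rss(obs, "single") == pytest.approx(0.0, abs=1e-15)

    def test_rss_single_offset(self):
        from dropcell.poisson import PoissonModel, rates

        lam = 0.5
        obs = [(lam, rates(PoissonModel(lam)).multicell + 0.1)]
        assert poisson_fit_rss(obs, "multicell") == pytest.approx(0.01, abs=1e-12)

    def test_chi2_accepts_true_model(self, rng):
        counts = rng.poisson(0.6, size=5000)
        stat, p, dof = poisson_chi2(counts, 0.6)
        assert p > 0.01

    def test_chi2_rejects_wrong_model(self, rng):
        counts = rng.poisson(1.5, size=5000)
        _, p, _ = poisson_chi2(counts, 0.5)
        assert p < 1e-6


class TestCategoryF1:
    def test_category_mismatch_counted_both_ways(self):
        truth = [(10, 10, 5), (30, 10, 5)]
        res = metrics.category_prf1(truth, [0, 1], list(truth), [0, 2], 0.5)
        # droplet 1: true category 1 (fn), predicted 2 (fp)
        assert res[0] == (1.0, 1.0, 1.0)
        assert res[1][1] == 0.0  # recall of true category
        assert res[2][0] == 0.0  # precision of predicted category

    def test_f1_decreases_with_stricter_matching(self, rng):
        # jittered predictions: raising the IoU threshold can only drop F1
        truth = [(rng.uniform(20, 200), rng.uniform(20, 140), rng.uniform(8, 12))
                 for _ in range(40)]
        preds = [(x + rng.normal(0, 1.5), y + rng.normal(0, 1.5),
                  r * rng.uniform(0.9, 1.1)) for x, y, r in truth]
        f1s = []
        for theta in (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85):
            m = match_detections(truth, preds, theta)
            f1s.append(prf1(m.tp, m.fp, m.fn)[2])
        assert all(a >= b for a, b in zip(f1s, f1s[1:]))
        assert f1s[0] > f1s[-1]
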