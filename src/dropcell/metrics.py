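"""Evaluation of droplet detections and cell localization.

Droplet proposals are compared with ground-truth bounding circles by circle
IoU (analytic lens intersection over union), matched one-to-one greedily in
descending IoU, and scored with precision / recall / F1.  Predicted cell
locations are scored against annotated centroids using a circular "valid
area" of radius x pixels.  Poisson goodness-of-fit of observed encapsulation
rates is reported as a residual sum of squares against the theoretical
curves, with an optional chi-squared test on count histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .poisson import PoissonModel, rates

__all__ = [
    "Circle",
    "MatchResult",
    "LocalizationScore",
    "circle_iou",
    "match_detections",
    "prf1",
    "localization_score",
    "counting_mre",
    "poisson_fit_rss",
    "poisson_chi2",
    "category_prf1",
]

#: a circle is (center_x, center_y, radius) in pixels
Circle = tuple[float, float, float]


@dataclass
class MatchResult:
    """One-to-one matching of predicted circles to truth at IoU >= theta."""

    pairs: list[tuple[int, int, float]]  # (truth_idx, pred_idx, iou)
    unmatched_truth: list[int]
    unmatched_pred: list[int]
    theta: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_truth)


@dataclass
class LocalizationScore:
    radius_x: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    distances: list[float] = field(default_factory=list)


def _lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two disks with radii r1, r2 and center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    # circular segment angles (law of cosines), numerically clipped
    cos1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1)
    cos2 = (d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2)
    a1 = math.acos(max(-1.0, min(1.0, cos1)))
    a2 = math.acos(max(-1.0, min(1.0, cos2)))
    return (
        r1 * r1 * (a1 - math.sin(2 * a1) / 2.0)
        + r2 * r2 * (a2 - math.sin(2 * a2) / 2.0)
    )


def circle_iou(c1: Circle, c2: Circle) -> float:
    """Intersection over union of two disks; symmetric, in [0, 1]."""
    x1, y1, r1 = c1
    x2, y2, r2 = c2
    if r1 <= 0 or r2 <= 0:
        raise ValueError("circle radii must be positive")
    d = math.hypot(x2 - x1, y2 - y1)
    inter = _lens_area(r1, r2, d)
    union = math.pi * (r1 * r1 + r2 * r2) - inter
    return inter / union


def match_detections(truth: list[Circle], preds: list[Circle], theta: float) -> MatchResult:
    """Greedy one-to-one matching of predictions to truth circles.

    Candidate (truth, pred) pairs with IoU >= theta are consumed in
    descending IoU; each circle participates in at most one pair.  The
    result is invariant to the ordering of ``preds``.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    cand: list[tuple[float, int, int]] = []
    for i, t in enumerate(truth):
        for j, p in enumerate(preds):
            iou = circle_iou(t, p)
            if iou >= theta:
                cand.append((iou, i, j))
    # sort by IoU desc; break ties by (truth, pred) index for determinism
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for iou, i, j in cand:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        pairs.append((i, j, iou))
    return MatchResult(
        pairs=pairs,
        unmatched_truth=[i for i in range(len(truth)) if i not in used_t],
        unmatched_pred=[j for j in range(len(preds)) if j not in used_p],
        theta=theta,
    )


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 = 2PR/(P+R); zero when degenerate."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def localization_score(
    true_centroids, predicted_locations, radius_x: float
) -> LocalizationScore:
    """Score predicted cell locations against annotated centroids.

    A disk of radius ``radius_x`` around each centroid is its valid area.
    Predictions are matched to centroids greedily by ascending distance,
    one-to-one; a matched prediction within the valid area is a true
    positive.
    """
    if radius_x <= 0:
        raise ValueError("valid-area radius must be positive")
    truths = [tuple(map(float, t)) for t in true_centroids]
    preds = [tuple(map(float, p)) for p in predicted_locations]
    cand: list[tuple[float, int, int]] = []
    for i, t in enumerate(truths):
        for j, p in enumerate(preds):
            d = math.hypot(p[0] - t[0], p[1] - t[1])
            if d <= radius_x:
                cand.append((d, i, j))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    dists: list[float] = []
    for d, i, j in cand:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        dists.append(d)
    tp = len(dists)
    fp = len(preds) - tp
    fn = len(truths) - tp
    precision = tp / len(preds) if preds else 0.0
    recall = tp / len(truths) if truths else 0.0
    return LocalizationScore(
        radius_x=radius_x,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        distances=dists,
    )


def counting_mre(true_counts, predicted_counts) -> tuple[float, int]:
    """Mean relative error of predicted vs true per-droplet cell counts.

    Droplets with a true count of zero carry no relative error and are
    excluded; the second return value reports how many were excluded.
    """
    t = np.asarray(true_counts, dtype=float)
    p = np.asarray(predicted_counts, dtype=float)
    if t.shape != p.shape:
        raise ValueError("count arrays must be paired")
    mask = t >= 1
    excluded = int(np.count_nonzero(~mask))
    if not np.any(mask):
        raise ValueError("no droplets with true count >= 1")
    mre = float(np.mean(np.abs(p[mask] - t[mask]) / t[mask]))
    return mre, excluded


_CURVES = {
    "empty": lambda r: r.empty,
    "single": lambda r: r.single,
    "multicell": lambda r: r.multicell,
    "single_cell_rate": lambda r: r.single_cell_rate,
}


def poisson_fit_rss(observed_rates_by_lambda, curve: str) -> float:
    """RSS of observed (lambda, rate) pairs against the Poisson curve.

    ``curve`` selects which theoretical rate to compare against: "empty",
    "single", "multicell" or "single_cell_rate".
    """
    if curve not in _CURVES:
        raise ValueError(f"unknown curve {curve!r}; choose from {sorted(_CURVES)}")
    f = _CURVES[curve]
    rss = 0.0
    for lam, rate in observed_rates_by_lambda:
        theo = f(rates(PoissonModel(float(lam))))
        if theo is None:
            raise ValueError("single_cell_rate is undefined at lambda = 0")
        rss += (float(rate) - theo) ** 2
    return rss


def poisson_chi2(counts, lam: float, min_expected: float = 5.0):
    """Chi-squared test of per-droplet cell counts against Poisson(lam).

    Bins k = 0, 1, 2, ... are pooled from the right until every expected
    count is at least ``min_expected``.  Returns (statistic, p_value, dof).
    """
    counts = np.asarray(counts, dtype=int)
    n = counts.size
    kmax = int(counts.max())
    observed = np.bincount(counts, minlength=kmax + 2).astype(float)
    expected = stats.poisson.pmf(np.arange(kmax + 2), lam) * n
    expected[-1] = n - expected[:-1].sum()  # right tail
    # pool sparse right-hand bins
    while len(expected) > 2 and expected[-1] < min_expected:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected = expected[:-1]
        observed = observed[:-1]
    stat = float(np.sum((observed - expected) ** 2 / expected))
    dof = len(expected) - 1
    p = float(stats.chi2.sf(stat, dof))
    return stat, p, dof


def category_prf1(
    truth: list[Circle],
    truth_categories: list[int],
    preds: list[Circle],
    pred_categories: list[int],
    theta: float,
) -> dict[int, tuple[float, float, float]]:
    """Per-category precision/recall/F1 with category-aware accounting.

    Circles are matched geometrically at IoU >= theta; a matched pair with
    disagreeing categories counts as a false positive for the predicted
    category and a false negative for the true one.  Unmatched truth and
    predictions are false negatives / false positives of their own
    categories.  Returns {category: (precision, recall, f1)}.
    """
    match = match_detections(truth, preds, theta)
    cats = sorted(set(truth_categories) | set(pred_categories))
    tp = {c: 0 for c in cats}
    fp = {c: 0 for c in cats}
    fn = {c: 0 for c in cats}
    for i, j, _ in match.pairs:
        ct, cp = truth_categories[i], pred_categories[j]
        if ct == cp:
            tp[ct] += 1
        else:
            fn[ct] += 1
            fp[cp] += 1
    for i in match.unmatched_truth:
        fn[truth_categories[i]] += 1
    for j in match.unmatched_pred:
        fp[pred_categories[j]] += 1
    return {c: prf1(tp[c], fp[c], fn[c]) for c in cats}
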