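"""Adaptive scale template matching (ASTM) for droplet proposal generation.

Adherent droplets merge into one connected blob in the binary foreground, so
connected-component analysis cannot separate them.  ASTM instead slides a
binary circular template over the foreground: the response at a pixel is the
fraction of the template covered by foreground, so a template matching a
droplet's diameter responds ~1 at its center.  Searching greedily from a
large initial scale, accepting every response plateau above a threshold
sigma, erasing accepted droplets and shrinking the template adaptively
(next diameter = max response x current diameter) finds droplets of all
diameters down to a minimum scale.  Non-maximum suppression on bounding
circles removes residual redundant proposals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes, label
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

from .metrics import circle_iou

__all__ = [
    "AstmConfig",
    "CircleProposal",
    "binarize_foreground",
    "circular_template",
    "match_response",
    "response_map",
    "greedy_propose",
    "nms_circles",
    "detect_droplets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AstmConfig:
    """Detector parameters.

    sigma      -- matching response threshold for accepting a proposal
    r_init     -- initial template diameter in px (should exceed the
                  largest expected droplet diameter)
    r_min      -- smallest admissible template diameter in px
    min_shrink -- upper bound on the shrink ratio r_next / r_cur, so the
                  scale strictly decreases even when the response is ~1
    nms_iou    -- circle-IoU threshold of the final suppression pass
    """

    sigma: float = 0.98
    r_init: float = 48.0
    r_min: float = 8.0
    min_shrink: float = 0.95
    nms_iou: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma <= 1.0):
            raise ValueError("sigma must lie in (0, 1]")
        if self.r_min >= self.r_init:
            raise ValueError("r_min must be smaller than r_init")
        if not (0.0 < self.min_shrink < 1.0):
            raise ValueError("min_shrink must lie in (0, 1)")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("nms_iou must lie in (0, 1)")


@dataclass(frozen=True)
class CircleProposal:
    """Candidate droplet: bounding circle plus its matching response."""

    center_x: float
    center_y: float
    radius: float
    score: float

    @property
    def circle(self) -> tuple[float, float, float]:
        return (self.center_x, self.center_y, self.radius)


def binarize_foreground(image: np.ndarray) -> np.ndarray:
    """Otsu binarization of a brightfield frame; droplets become True.

    Droplets image darker than the oil background, so the foreground is the
    below-threshold class; interior holes (bright droplet centers, cells)
    are filled so each droplet is a solid disk.  A separation sanity check
    rejects frames whose two Otsu classes are not genuinely distinct (e.g. a
    droplet-free frame of pure background noise), returning an empty mask.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("image is empty")
    if np.ptp(img) == 0:
        log.info("constant image: empty foreground")
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    fg = img < t
    if not fg.any() or fg.all():
        return np.zeros(img.shape, dtype=bool)
    # class separation must dominate within-class spread to be real foreground
    mu_fg, mu_bg = img[fg].mean(), img[~fg].mean()
    sd = max(img[fg].std(), img[~fg].std(), 1e-9)
    if (mu_bg - mu_fg) / sd < 4.0:
        log.info("Otsu classes not separated (ratio %.2f): empty foreground",
                 (mu_bg - mu_fg) / sd)
        return np.zeros(img.shape, dtype=bool)
    return binary_fill_holes(fg)


def circular_template(r: float) -> np.ndarray:
    """Binary disk raster of diameter ``r``: T(a,b)=1 iff the pixel lies
    within r/2 of the template center (r/2, r/2)."""
    n = int(round(r))
    if n < 1:
        raise ValueError("template diameter must be >= 1 px")
    a, b = np.mgrid[0:n, 0:n]
    return ((a - r / 2.0) ** 2 + (b - r / 2.0) ** 2 <= (r / 2.0) ** 2)


def response_map(F: np.ndarray, r: float) -> np.ndarray:
    """Normalized matching response of the diameter-``r`` disk template at
    every pixel (zero-padded borders); values in [0, 1]."""
    T = circular_template(r).astype(np.float64)
    area = T.sum()
    D = fftconvolve(F.astype(np.float64), T[::-1, ::-1] / area, mode="same")
    return np.clip(D, 0.0, 1.0)


def match_response(F: np.ndarray, r: float, x: int, y: int) -> float:
    """Matching response at a single pixel (x = column, y = row): the
    fraction of the template area covered by foreground."""
    T = circular_template(r)
    n = T.shape[0]
    area = int(T.sum())
    h, w = F.shape
    acc = 0
    for a in range(n):
        for b in range(n):
            if not T[a, b]:
                continue
            yy = y + a - n // 2
            xx = x + b - n // 2
            if 0 <= yy < h and 0 <= xx < w and F[yy, xx]:
                acc += 1
    return acc / area


def _accept_plateaus(D: np.ndarray, sigma: float):
    """Centers of the connected response plateaus above sigma.

    A template slightly smaller than a droplet responds ~1 on a small
    plateau of centers; the response-weighted centroid of each connected
    above-threshold component estimates the droplet center, which is both
    more accurate and better defined than an arbitrary tie-broken maximum.
    """
    mask = D >= sigma
    if not mask.any():
        return []
    lab, n = label(mask)
    centers = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(lab == i)
        wts = D[ys, xs]
        centers.append((float(np.average(xs, weights=wts)),
                        float(np.average(ys, weights=wts)),
                        float(wts.max())))
    return centers


def _coverage(F: np.ndarray, cx: float, cy: float, r: float) -> float:
    """Fraction of the disk of radius r at (cx, cy) covered by foreground."""
    h, w = F.shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    area = int(disk.sum())
    if area == 0:
        return 0.0
    return float(F[y0:y1, x0:x1][disk].sum()) / area


def _refine_radius(F: np.ndarray, cx: float, cy: float, r: float,
                   sigma: float, growth: float = 1.6, step: float = 0.25) -> float:
    """Grow an accepted circle while its foreground coverage stays >= sigma.

    The adaptive shrink (next scale = response x current scale) can jump
    below a droplet's true diameter, in which case the droplet is accepted
    at the first undershot scale; growing the bounding circle until
    coverage falls below the acceptance threshold recovers the droplet's
    actual extent.  Growth is capped so an accepted circle cannot swallow
    an adherent neighbour.
    """
    best = r
    cand = r + step
    while cand <= growth * r:
        if _coverage(F, cx, cy, cand) >= sigma:
            best = cand
        else:
            break
        cand += step
    return best


def _erase_disk(F: np.ndarray, cx: float, cy: float, r: float) -> None:
    h, w = F.shape
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    F[y0:y1, x0:x1] &= ~((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r)


def greedy_propose(F: np.ndarray, cfg: AstmConfig) -> list[CircleProposal]:
    """Greedy multi-scale search of the foreground for droplet proposals.

    At each scale the full response map is computed; all above-threshold
    plateaus are accepted as proposals (with the radius refined upward to
    the droplet's actual extent, see _refine_radius) and their foreground
    erased, then the same scale is re-searched until its maximum response
    drops below sigma.  The scale then shrinks by r_next = Dmax * r_cur
    (clamped to at most min_shrink * r_cur so the sequence strictly
    decreases), stopping below r_min or when the foreground is exhausted.
    """
    F = np.asarray(F, dtype=bool).copy()
    proposals: list[CircleProposal] = []
    r_cur = float(cfg.r_init)
    while r_cur >= cfg.r_min and F.any():
        D = response_map(F, r_cur)
        centers = _accept_plateaus(D, cfg.sigma)
        if centers:
            for cx, cy, score in centers:
                radius = _refine_radius(F, cx, cy, r_cur / 2.0, cfg.sigma)
                proposals.append(
                    CircleProposal(center_x=cx, center_y=cy, radius=radius,
                                   score=score)
                )
                _erase_disk(F, cx, cy, radius)
            continue  # re-search the same scale on the erased foreground
        d_max = float(D.max())
        r_next = d_max * r_cur
        if r_next > cfg.min_shrink * r_cur:
            log.debug("shrink clamp binds at r=%.2f (Dmax=%.4f)", r_cur, d_max)
            r_next = cfg.min_shrink * r_cur
        r_cur = r_next
    return proposals


def nms_circles(proposals: list[CircleProposal], nms_iou: float) -> list[CircleProposal]:
    """Suppress lower-scoring proposals overlapping a kept one (circle IoU >
    nms_iou).  Output is sorted by descending score; idempotent."""
    ranked = sorted(proposals, key=lambda p: (-p.score, p.center_y, p.center_x))
    kept: list[CircleProposal] = []
    for p in ranked:
        if all(circle_iou(p.circle, q.circle) <= nms_iou for q in kept):
            kept.append(p)
    return kept


def detect_droplets(
    image: np.ndarray, cfg: AstmConfig | None = None
) -> list[CircleProposal]:
    """Full stage-1 pipeline: Otsu foreground -> greedy ASTM -> circle NMS."""
    if cfg is None:
        cfg = AstmConfig()
    F = binarize_foreground(image)
    return nms_circles(greedy_propose(F, cfg), cfg.nms_iou)
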