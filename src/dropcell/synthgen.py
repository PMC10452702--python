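"""Seeded synthetic micrographs of cell-encapsulated droplets.

Real training data for droplet recognition is a brightfield frame: a bright
oil background, densely packed adherent droplets showing a dark rim and a
slightly darkened interior, and cells as small dark blobs inside droplets.
This module renders frames with that statistical and geometric structure —
droplet diameters drawn from a truncated normal, centers packed by rejection
sampling so neighbours adhere, per-droplet cell counts drawn Poisson(lambda)
— together with complete ground truth (bounding circles, cell centroids,
droplet-level category labels), so the detector and counting network can be
trained and evaluated without any external data.

The generator makes no attempt at photorealism (no refraction, no shading,
no debris); it reproduces only the structure the recognizers rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

__all__ = [
    "EMPTY",
    "SINGLE",
    "MULTIPLE",
    "CATEGORY_NAMES",
    "SceneConfig",
    "SceneTruth",
    "PatchDataset",
    "render_scene",
    "render_batch",
    "extract_patch",
    "make_patch_dataset",
]

EMPTY, SINGLE, MULTIPLE = 0, 1, 2
CATEGORY_NAMES = {EMPTY: "empty", SINGLE: "single", MULTIPLE: "multiple"}

#: droplet rim thickness in px (annulus drawn inside the bounding circle)
RIM_WIDTH = 2.0
#: cells are placed uniformly within this fraction of the droplet radius
CELL_PLACEMENT_FRACTION = 0.8


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic frame.

    Intensity parameters are in 8-bit grey levels; geometric parameters in
    pixels.  ``cpd_lambda`` is the mean number of cells per droplet (CPD).
    The same config and seed always render the identical frame.
    """

    frame_width: int = 640
    frame_height: int = 480
    n_droplets: int = 150
    droplet_diameter_mean: float = 22.0
    droplet_diameter_cv: float = 0.08
    cpd_lambda: float = 0.5
    cell_diameter_range: tuple[float, float] = (4.0, 8.0)
    max_overlap: float = 0.15
    background_level: float = 200.0
    droplet_rim_contrast: float = 90.0
    droplet_interior_contrast: float = 30.0
    cell_contrast: float = 80.0
    noise_sd: float = 4.0
    min_cell_separation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")
        if self.droplet_diameter_mean <= 0:
            raise ValueError("droplet_diameter_mean must be positive")
        if self.droplet_diameter_cv < 0:
            raise ValueError("droplet_diameter_cv must be >= 0")
        if self.cpd_lambda < 0:
            raise ValueError("cpd_lambda must be >= 0")
        if not (0.0 <= self.max_overlap < 1.0):
            raise ValueError("max_overlap must lie in [0, 1)")
        lo, hi = self.cell_diameter_range
        if lo <= 0 or hi < lo:
            raise ValueError("cell_diameter_range must be a positive interval")


@dataclass
class SceneTruth:
    """Ground truth of one rendered frame.

    ``circles`` are (center_x, center_y, radius) in pixel coordinates
    (x = column, y = row, 0-based, origin top-left); ``cells_per_droplet``
    holds the cell centroids of each droplet; categories follow the count:
    0 cells -> empty, 1 -> single, >=2 -> multiple.
    """

    circles: list[tuple[float, float, float]] = field(default_factory=list)
    cells_per_droplet: list[list[tuple[float, float]]] = field(default_factory=list)
    category_per_droplet: list[int] = field(default_factory=list)

    @property
    def n_droplets(self) -> int:
        return len(self.circles)

    def counts(self) -> list[int]:
        return [len(c) for c in self.cells_per_droplet]

    def to_dict(self) -> dict:
        return {
            "circles": [list(c) for c in self.circles],
            "cells_per_droplet": [[list(p) for p in c] for c in self.cells_per_droplet],
            "category_per_droplet": [CATEGORY_NAMES[c] for c in self.category_per_droplet],
        }


def _place_droplets(cfg: SceneConfig, rng: np.random.Generator, max_tries: int = 400):
    """Rejection-sample droplet centers so circles stay in frame and two
    centers are no closer than (r1 + r2) * (1 - max_overlap)."""
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    sd = cfg.droplet_diameter_cv * cfg.droplet_diameter_mean
    for _ in range(cfg.n_droplets):
        placed = False
        for _try in range(max_tries):
            d = rng.normal(cfg.droplet_diameter_mean, sd)
            if d < 4.0:  # truncate unphysically small draws
                continue
            r = d / 2.0
            if 2 * r + 2 >= min(cfg.frame_width, cfg.frame_height):
                continue
            cx = rng.uniform(r + 1.0, cfg.frame_width - r - 1.0)
            cy = rng.uniform(r + 1.0, cfg.frame_height - r - 1.0)
            if centers:
                c = np.asarray(centers)
                rr = np.asarray(radii)
                dist = np.hypot(c[:, 0] - cx, c[:, 1] - cy)
                if np.any(dist < (rr + r) * (1.0 - cfg.max_overlap)):
                    continue
            centers.append((cx, cy))
            radii.append(r)
            placed = True
            break
        if not placed:
            break  # frame saturated; caller reports the achieved count
    return centers, radii


def _place_cells(
    cfg: SceneConfig,
    center: tuple[float, float],
    radius: float,
    n_cells: int,
    rng: np.random.Generator,
    max_tries: int = 60,
) -> list[tuple[float, float]]:
    """Uniform placement in the inner disk, preferring min separation.

    If the droplet is too crowded to honour the separation after bounded
    retries the constraint is dropped for that cell, emulating the crowded
    multicell encapsulations that defeat count-by-eye as well.
    """
    pts: list[tuple[float, float]] = []
    rmax = CELL_PLACEMENT_FRACTION * radius
    for _ in range(n_cells):
        best = None
        for _try in range(max_tries):
            rho = rmax * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            x = center[0] + rho * math.cos(phi)
            y = center[1] + rho * math.sin(phi)
            best = (x, y)
            if all(
                math.hypot(x - px, y - py) >= cfg.min_cell_separation
                for px, py in pts
            ):
                break
        pts.append(best)
    return pts


def render_scene(cfg: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Render one frame; returns (uint8 image of shape (H, W), truth).

    Rendering is deterministic in (config, seed).  Placement, cell loading
    and pixel noise use independent sub-streams of the seed so that e.g. the
    Poisson loading of droplet i does not depend on how many placement
    retries earlier droplets needed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    place_rng, load_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    centers, radii = _place_droplets(cfg, place_rng)
    counts = load_rng.poisson(cfg.cpd_lambda, size=len(centers)) if centers else []

    truth = SceneTruth()
    h, w = cfg.frame_height, cfg.frame_width
    img = np.full((h, w), cfg.background_level, dtype=np.float64)

    # droplet bodies: darker-wins composition so adherent droplets merge
    # into one foreground blob exactly as overlapping dark disks would
    for (cx, cy), r in zip(centers, radii):
        x0, x1 = int(math.floor(cx - r - 1)), int(math.ceil(cx + r + 2))
        y0, y1 = int(math.floor(cy - r - 1)), int(math.ceil(cy + r + 2))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx, yy - cy)
        local = img[y0:y1, x0:x1]
        interior = dist <= r
        rim = interior & (dist >= r - RIM_WIDTH)
        level = np.full(local.shape, np.inf)
        level[interior] = cfg.background_level - cfg.droplet_interior_contrast
        level[rim] = cfg.background_level - cfg.droplet_rim_contrast
        np.minimum(local, level, out=local)

    for (cx, cy), r, n in zip(centers, radii, counts):
        pts = _place_cells(cfg, (cx, cy), r, int(n), load_rng)
        truth.circles.append((cx, cy, r))
        truth.cells_per_droplet.append(pts)
        truth.category_per_droplet.append(min(int(n), 2))
        for px, py in pts:
            d_cell = load_rng.uniform(*cfg.cell_diameter_range)
            sigma = d_cell / 4.0
            ext = int(math.ceil(2.5 * sigma))
            x0, x1 = int(math.floor(px)) - ext, int(math.floor(px)) + ext + 1
            y0, y1 = int(math.floor(py)) - ext, int(math.floor(py)) + ext + 1
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, w), min(y1, h)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            blob = np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * sigma**2))
            img[y0:y1, x0:x1] -= cfg.cell_contrast * blob

    if cfg.noise_sd > 0:
        img += noise_rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


def render_batch(cfg: SceneConfig, n_frames: int) -> list[tuple[np.ndarray, SceneTruth]]:
    """Render ``n_frames`` frames with per-frame seeds derived from cfg.seed."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_frames) % (2**31)
    return [render_scene(replace(cfg, seed=int(s))) for s in seeds]


# ---------------------------------------------------------------------------
# patch datasets for network training

#: side of the square crop around a droplet, as a multiple of its radius
CROP_FACTOR = 2.4
DEFAULT_PATCH_SIZE = 32


@dataclass
class PatchDataset:
    """Fixed-size grayscale patches with droplet-level weak labels.

    ``images`` is (N, S, S) float32 in [0, 1].  ``is_droplet`` separates
    background crops from droplet crops; ``count_label`` is the weak count
    label 0 / 1 / 2 ("at least two"), only meaningful for droplet patches.
    ``true_counts`` and ``cell_xy`` (patch coordinates) retain the full
    ground truth for evaluation; they are never used for training.
    ``crop_scale`` is the patch-px-per-frame-px factor of each crop, needed
    to express frame-pixel distances in patch coordinates.  ``split``
    assigns each patch to "train" / "val" / "test" at 4:1:1.
    """

    images: np.ndarray
    is_droplet: np.ndarray
    count_label: np.ndarray
    true_counts: np.ndarray
    cell_xy: list[list[tuple[float, float]]]
    crop_scale: np.ndarray
    split: np.ndarray
    patch_size: int

    def subset(self, name: str) -> "PatchDataset":
        m = self.split == name
        idx = np.flatnonzero(m)
        return PatchDataset(
            images=self.images[m],
            is_droplet=self.is_droplet[m],
            count_label=self.count_label[m],
            true_counts=self.true_counts[m],
            cell_xy=[self.cell_xy[i] for i in idx],
            crop_scale=self.crop_scale[m],
            split=self.split[m],
            patch_size=self.patch_size,
        )

    def __len__(self) -> int:
        return len(self.images)


def extract_patch(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    patch_size: int = DEFAULT_PATCH_SIZE,
    background_level: float = 200.0,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Crop a CROP_FACTOR * r square around ``center`` and resize.

    Returns the float32 patch in [0, 1] and the transform (x0, y0, scale)
    mapping patch coordinates to frame coordinates:
    ``frame = origin + (patch + 0.5) / scale - 0.5``.
    """
    h, w = image.shape
    side = max(int(round(CROP_FACTOR * radius)), 4)
    x0 = int(round(center[0])) - side // 2
    y0 = int(round(center[1])) - side // 2
    crop = np.full((side, side), background_level, dtype=np.float64)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + side, w), min(y0 + side, h)
    if sx1 > sx0 and sy1 > sy0:
        crop[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[sy0:sy1, sx0:sx1]
    scale = patch_size / side
    patch = resize(
        crop, (patch_size, patch_size), order=1, anti_aliasing=side > patch_size,
        preserve_range=True,
    )
    return (patch / 255.0).astype(np.float32), (float(x0), float(y0), scale)


def _frame_to_patch(xy, transform):
    x0, y0, s = transform
    return [((x - x0 + 0.5) * s - 0.5, (y - y0 + 0.5) * s - 0.5) for x, y in xy]


def _background_window_ok(x0, y0, side, circles) -> bool:
    """True if the axis-aligned square does not intersect any truth circle."""
    for cx, cy, r in circles:
        nx = min(max(cx, x0), x0 + side)
        ny = min(max(cy, y0), y0 + side)
        if math.hypot(cx - nx, cy - ny) <= r:
            return False
    return True


def make_patch_dataset(
    cfg: SceneConfig,
    n_per_category: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
) -> PatchDataset:
    """Build a balanced labeled patch set of all four sample types.

    Scenes are rendered (seeds derived from ``cfg.seed``) until the quota of
    ``n_per_category`` patches is met for each of background, empty, single
    and multiple.  Droplet patches are cropped from truth circles;
    background patches are random windows that intersect no truth circle.
    The dataset is split 4:1:1 into train / validation / test, stratified
    per category.
    """
    if n_per_category <= 0:
        raise ValueError("n_per_category must be positive")
    quota = {"background": n_per_category, EMPTY: n_per_category,
             SINGLE: n_per_category, MULTIPLE: n_per_category}
    got = {k: 0 for k in quota}
    images, is_drop, count_lab, true_counts = [], [], [], []
    cell_xy, scales, cats = [], [], []

    ss = np.random.SeedSequence(cfg.seed)
    bg_rng = np.random.default_rng(ss.spawn(1)[0])
    scene_i = 0
    mean_side = int(round(CROP_FACTOR * cfg.droplet_diameter_mean / 2.0))
    while any(got[k] < quota[k] for k in quota):
        if scene_i > 10000:
            raise RuntimeError("patch quota not reachable with this config")
        seed = int(ss.generate_state(scene_i + 1)[-1] % (2**31))
        frame, truth = render_scene(replace(cfg, seed=seed))
        scene_i += 1
        for (cx, cy, r), pts, cat in zip(
            truth.circles, truth.cells_per_droplet, truth.category_per_droplet
        ):
            if got[cat] >= quota[cat]:
                continue
            patch, tf = extract_patch(
                frame, (cx, cy), r, patch_size, cfg.background_level
            )
            images.append(patch)
            is_drop.append(True)
            count_lab.append(cat)  # weak label: 0, 1 or 2 ("at least two")
            true_counts.append(len(pts))
            cell_xy.append(_frame_to_patch(pts, tf))
            scales.append(tf[2])
            cats.append(cat)
            got[cat] += 1
        # background windows from the same frame
        for _ in range(200):
            if got["background"] >= quota["background"]:
                break
            x0 = bg_rng.integers(0, cfg.frame_width - mean_side)
            y0 = bg_rng.integers(0, cfg.frame_height - mean_side)
            if not _background_window_ok(x0, y0, mean_side, truth.circles):
                continue
            patch, bg_tf = extract_patch(
                frame,
                (x0 + mean_side / 2, y0 + mean_side / 2),
                cfg.droplet_diameter_mean / 2.0,
                patch_size,
                cfg.background_level,
            )
            images.append(patch)
            is_drop.append(False)
            count_lab.append(0)
            true_counts.append(0)
            cell_xy.append([])
            scales.append(bg_tf[2])
            cats.append("background")
            got["background"] += 1

    # stratified 4:1:1 split, deterministic in cfg.seed
    split = np.empty(len(images), dtype=object)
    split_rng = np.random.default_rng(ss.spawn(2)[1])
    cats_arr = np.asarray(cats, dtype=object)
    for cat in quota:
        idx = np.flatnonzero(cats_arr == cat)
        idx = split_rng.permutation(idx)
        n = len(idx)
        n_train = (4 * n) // 6
        n_val = n // 6
        split[idx[:n_train]] = "train"
        split[idx[n_train : n_train + n_val]] = "val"
        split[idx[n_train + n_val :]] = "test"

    return PatchDataset(
        images=np.stack(images).astype(np.float32),
        is_droplet=np.asarray(is_drop, dtype=bool),
        count_label=np.asarray(count_lab, dtype=np.int64),
        true_counts=np.asarray(true_counts, dtype=np.int64),
        cell_xy=cell_xy,
        crop_scale=np.asarray(scales, dtype=np.float64),
        split=split.astype(str),
        patch_size=patch_size,
    )
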