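"""File I/O for frames, truth, detections and run configuration.

Frames are 8-bit grayscale PNG/TIFF; ground truth is written both as JSON
(full structure) and as a flat per-droplet CSV; detections go to CSV with a
header comment stating the 0-based pixel coordinate convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .astm import AstmConfig, CircleProposal
from .synthgen import CATEGORY_NAMES, SceneConfig, SceneTruth
from .wscnet import DropletDetection, TrainConfig

__all__ = [
    "read_image",
    "read_images",
    "write_image",
    "write_truth",
    "read_truth",
    "proposals_to_frame",
    "detections_to_frame",
    "write_overlay",
    "RunConfig",
]

log = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}

COORD_COMMENT = "# coordinates: 0-based pixels, x = column, y = row, origin top-left\n"


def _to_gray8(arr: np.ndarray) -> np.ndarray:
    """Any imageio array -> uint8 grayscale by luminance / range rescale."""
    a = np.asarray(arr)
    if a.ndim == 3:  # RGB(A) -> luminance
        a = a[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
    a = a.astype(np.float64)
    if a.max() > 255.0:  # e.g. 16-bit TIFF
        a = a * (255.0 / a.max())
    return np.clip(np.rint(a), 0, 255).astype(np.uint8)


def read_image(path) -> np.ndarray:
    return _to_gray8(iio.imread(Path(path)))


def read_images(path):
    """Yield (name, gray8 frame) from a file or directory, in name order.

    Unreadable files are skipped with a warning; an empty yield set raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = (
        [path]
        if path.is_file()
        else sorted(p for p in path.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    )
    if not files:
        raise ValueError(f"no images found under {path}")
    n_ok = 0
    for f in files:
        try:
            img = read_image(f)
        except Exception as exc:  # unreadable file: warn and continue
            log.warning("skipping unreadable image %s: %s", f, exc)
            continue
        n_ok += 1
        yield f.stem, img
    if n_ok == 0:
        raise ValueError(f"all {len(files)} images under {path} were unreadable")


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_truth(out_dir, frame_id: str, truth: SceneTruth) -> None:
    """Write one frame's truth as JSON and append to the flat CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{frame_id}_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=1)
    )
    rows = [
        {
            "frame_id": frame_id,
            "cx": cx,
            "cy": cy,
            "r": r,
            "n_cells": len(cells),
            "category": CATEGORY_NAMES[cat],
        }
        for (cx, cy, r), cells, cat in zip(
            truth.circles, truth.cells_per_droplet, truth.category_per_droplet
        )
    ]
    csv_path = out_dir / "truth.csv"
    header = not csv_path.exists()
    if header:
        csv_path.write_text(COORD_COMMENT)
    pd.DataFrame(rows).to_csv(csv_path, mode="a", header=header, index=False)


def read_truth(path) -> SceneTruth:
    d = json.loads(Path(path).read_text())
    names = {v: k for k, v in CATEGORY_NAMES.items()}
    return SceneTruth(
        circles=[tuple(c) for c in d["circles"]],
        cells_per_droplet=[[tuple(p) for p in c] for c in d["cells_per_droplet"]],
        category_per_droplet=[names[c] for c in d["category_per_droplet"]],
    )


def proposals_to_frame(frame_id: str, proposals: list[CircleProposal]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame_id": frame_id,
                "cx": p.center_x,
                "cy": p.center_y,
                "r": p.radius,
                "score": p.score,
            }
            for p in proposals
        ]
    )


def detections_to_frame(frame_id: str, detections: list[DropletDetection]) -> pd.DataFrame:
    rows = []
    for d in detections:
        rows.append(
            {
                "frame_id": frame_id,
                "cx": d.proposal.center_x,
                "cy": d.proposal.center_y,
                "r": d.proposal.radius,
                "score": d.proposal.score,
                "is_droplet": d.is_droplet,
                "dsum": d.dsum if d.dsum is not None else "",
                "count": d.predicted_count if d.predicted_count is not None else "",
                "category": CATEGORY_NAMES.get(d.category, ""),
                "cells": ";".join(f"{x:.1f},{y:.1f}" for x, y in d.cell_locations),
            }
        )
    return pd.DataFrame(rows)


#: overlay colors follow the standard scheme: empty red, single blue,
#: multicell green; rejected (false-positive) proposals yellow
_CATEGORY_RGB = {0: (220, 40, 40), 1: (40, 80, 220), 2: (40, 180, 60)}
_FALSE_POSITIVE_RGB = (230, 220, 40)


def write_overlay(path, image: np.ndarray, detections: list[DropletDetection]) -> None:
    from skimage.draw import circle_perimeter

    rgb = np.stack([image] * 3, axis=-1).astype(np.uint8)
    h, w = image.shape
    for d in detections:
        color = (
            _CATEGORY_RGB.get(d.category, _FALSE_POSITIVE_RGB)
            if d.is_droplet
            else _FALSE_POSITIVE_RGB
        )
        rr, cc = circle_perimeter(
            int(round(d.proposal.center_y)),
            int(round(d.proposal.center_x)),
            max(int(round(d.proposal.radius)), 1),
            shape=(h, w),
        )
        rgb[rr, cc] = color
        for x, y in d.cell_locations:
            yy, xx = int(round(y)), int(round(x))
            if 0 <= yy < h and 0 <= xx < w:
                rgb[max(yy - 1, 0) : yy + 2, max(xx - 1, 0) : xx + 2] = (220, 40, 40)
    iio.imwrite(Path(path), rgb)


class RunConfig:
    """Validated pipeline configuration loaded from YAML.

    Sections: ``synth`` (SceneConfig), ``astm`` (AstmConfig), ``train``
    (TrainConfig), plus top-level ``seed`` and ``log_level``.  Unknown keys
    are rejected so typos fail loudly.
    """

    _SECTIONS = {"synth": SceneConfig, "astm": AstmConfig, "train": TrainConfig}

    def __init__(self, synth=None, astm=None, train=None, seed: int = 0,
                 log_level: str = "INFO"):
        self.synth = synth or SceneConfig()
        self.astm = astm or AstmConfig()
        self.train = train or TrainConfig()
        self.seed = seed
        self.log_level = log_level

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known_top = set(cls._SECTIONS) | {"seed", "log_level"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, typ in cls._SECTIONS.items():
            section = raw.get(name, {}) or {}
            valid = {f.name for f in fields(typ)}
            bad = set(section) - valid
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            if name == "synth" and "cell_diameter_range" in section:
                section["cell_diameter_range"] = tuple(section["cell_diameter_range"])
            kwargs[name] = typ(**section)
        return cls(seed=raw.get("seed", 0), log_level=raw.get("log_level", "INFO"),
                   **kwargs)

    def to_dict(self) -> dict:
        return {
            "synth": asdict(self.synth),
            "astm": asdict(self.astm),
            "train": asdict(self.train),
            "seed": self.seed,
            "log_level": self.log_level,
        }
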