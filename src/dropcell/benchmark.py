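"""Seeded desk-scale benchmarks of the recognition pipeline.

These routines generate the synthetic study conditions, run the pipeline
end to end and measure the headline quantities: droplet-proposal recall and
precision of the stage-1 detector at circle-IoU thresholds 0.5 and 0.8,
per-category recognition F1 of the full pipeline at threshold 0.7, and
cell-localization precision at a 10 px valid-area radius.

The benchmark conditions mirror the acquisition they emulate: 640x480
frames of ~150 adherent droplets, diameter 22 px with 8% CV, centers
allowed to encroach 15% of the joint radius, moderate sensor noise.
"""

from __future__ import annotations

import numpy as np

from . import astm, metrics, synthgen, wscnet

__all__ = [
    "benchmark_scene_config",
    "astm_benchmark",
    "train_desk_model",
    "recognition_benchmark",
    "localization_benchmark",
]

#: radius (px) of the valid area around a true centroid for localization
LOCALIZATION_RADIUS_PX = 10.0


def benchmark_scene_config(seed: int, cpd_lambda: float = 0.5) -> synthgen.SceneConfig:
    """The synthetic stand-in for one acquisition frame."""
    return synthgen.SceneConfig(
        frame_width=640,
        frame_height=480,
        n_droplets=150,
        droplet_diameter_mean=22.0,
        droplet_diameter_cv=0.08,
        cpd_lambda=cpd_lambda,
        max_overlap=0.15,
        seed=seed,
    )


def _frame_seeds(seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence([seed, salt])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def astm_benchmark(seed: int, n_frames: int = 20) -> dict:
    """Stage-1 detection quality on seeded synthetic frames.

    Returns recall and precision at circle-IoU 0.5 and recall at 0.8,
    pooled over all frames.
    """
    cfg = astm.AstmConfig()
    tallies = {0.5: [0, 0, 0], 0.8: [0, 0, 0]}  # tp, fp, fn
    for s in _frame_seeds(seed, n_frames, salt=1):
        img, truth = synthgen.render_scene(benchmark_scene_config(s))
        props = astm.detect_droplets(img, cfg)
        circles = [p.circle for p in props]
        for theta in tallies:
            m = metrics.match_detections(truth.circles, circles, theta)
            tallies[theta][0] += m.tp
            tallies[theta][1] += m.fp
            tallies[theta][2] += m.fn
    p5, r5, _ = metrics.prf1(*tallies[0.5])
    _, r8, _ = metrics.prf1(*tallies[0.8])
    return {
        "recall_iou_0.5": r5,
        "precision_iou_0.5": p5,
        "recall_iou_0.8": r8,
        "n_truth_droplets": tallies[0.5][0] + tallies[0.5][2],
    }


def train_desk_model(
    seed: int,
    n_per_category: int = 3000,
    max_epochs: int = 20,
) -> tuple[wscnet.WSCNet, synthgen.PatchDataset, wscnet.TrainConfig]:
    """Train the counting network at desk scale.

    ~12k patches (4 x n_per_category), mini-batches of 256 and a higher
    initial learning rate than the full-scale default so the small epoch
    budget suffices; scenes for patch extraction use lambda = 0.8 to yield
    multicell droplets at a workable rate.
    """
    scene = benchmark_scene_config(seed, cpd_lambda=0.8)
    patches = synthgen.make_patch_dataset(scene, n_per_category)
    cfg = wscnet.TrainConfig(
        batch_size=256, max_epochs=max_epochs, learning_rate=1e-3, seed=seed
    )
    model = wscnet.build_model(seed=seed)
    wscnet.train(model, patches, cfg)
    return model, patches, cfg


def recognition_benchmark(
    model: wscnet.WSCNet, seed: int, n_frames: int = 6, theta: float = 0.7
) -> dict:
    """Full-pipeline per-category F1 at matching threshold ``theta``.

    Fresh frames are rendered, stage 1 proposes droplets, the network
    filters and reclassifies them via the density integral, and detections
    are matched to truth one-to-one; a matched droplet with the wrong
    category counts against both categories.
    """
    acfg = astm.AstmConfig()
    tp = {0: 0, 1: 0, 2: 0}
    fp = {0: 0, 1: 0, 2: 0}
    fn = {0: 0, 1: 0, 2: 0}
    for s in _frame_seeds(seed, n_frames, salt=2):
        img, truth = synthgen.render_scene(benchmark_scene_config(s, cpd_lambda=0.8))
        props = astm.detect_droplets(img, acfg)
        dets = [d for d in wscnet.infer_frame(model, img, props) if d.is_droplet]
        match = metrics.match_detections(
            truth.circles, [d.proposal.circle for d in dets], theta
        )
        for i, j, _ in match.pairs:
            ct, cp = truth.category_per_droplet[i], dets[j].category
            if ct == cp:
                tp[ct] += 1
            else:
                fn[ct] += 1
                fp[cp] += 1
        for i in match.unmatched_truth:
            fn[truth.category_per_droplet[i]] += 1
        for j in match.unmatched_pred:
            fp[dets[j].category] += 1
    out = {}
    f1s = []
    for c, name in synthgen.CATEGORY_NAMES.items():
        _, _, f1 = metrics.prf1(tp[c], fp[c], fn[c])
        out[f"f1_{name}"] = f1
        f1s.append(f1)
    out["mean_f1"] = float(np.mean(f1s))
    return out


def localization_benchmark(
    model: wscnet.WSCNet,
    patches: synthgen.PatchDataset,
    radius_px: float = LOCALIZATION_RADIUS_PX,
) -> dict:
    """Cell localization on held-out multicell patches.

    Predicted density maxima are scored against true centroids with a
    valid-area radius given in frame pixels (converted to patch
    coordinates through the crop scale of a mean-diameter droplet).
    """
    te = patches.subset("test")
    _, density = model.forward(te.images, train=False)
    dsum = density.sum(axis=(1, 2))
    mask = te.is_droplet & (te.count_label == 2)
    tp = fp = fn = 0
    for i in np.flatnonzero(mask):
        k = int(np.floor(dsum[i] + 0.5))
        peaks = wscnet.density_peaks(density[i], k)
        # valid radius converted to this patch's coordinate scale
        s = metrics.localization_score(
            te.cell_xy[i], peaks, radius_px * te.crop_scale[i]
        )
        tp += s.tp
        fp += s.fp
        fn += s.fn
    return {
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "n_patches": int(mask.sum()),
    }
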