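"""Weakly supervised counting network (WSCNet) for droplet patches.

Stage 2 of the recognition pipeline.  Each droplet proposal is cropped to a
fixed-size grayscale patch and fed to a small two-branch CNN trained from
droplet-level labels only:

* a classification branch (cross-entropy, background vs droplet) that
  filters false-positive proposals, and
* a counting branch emitting a nonnegative single-channel density map at
  the input resolution.  The integral of the map (Dsum) estimates the
  number of encapsulated cells and its leading local maxima estimate the
  cell positions — although no cell position or exact count above one was
  ever labeled.

The weak count labels are y in {0, 1, 2}, where 2 means "at least two".
Because a multicell droplet only guarantees >= 2 cells, the counting
prediction is truncated at 2 (with a small residual slope gamma so the
gradient never vanishes), and a max-value regularizer keeps any single
density peak from exceeding 1, preventing the truncation from inflating
per-cell mass.

The network has exactly seven 3x3 convolutions: a four-layer shared trunk
and a three-layer counting head; the classification branch reads the trunk
through global average pooling and one linear layer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .astm import CircleProposal
from .nn import Adam, Conv3x3, FeatureNorm, Linear, relu, relu_grad
from .synthgen import DEFAULT_PATCH_SIZE, PatchDataset, extract_patch

__all__ = [
    "TrainConfig",
    "WSCNet",
    "DropletDetection",
    "build_model",
    "truncated_count",
    "max_regularizer",
    "counting_loss",
    "total_loss",
    "reclassify",
    "density_peaks",
    "train",
    "infer",
    "infer_frame",
    "save_checkpoint",
    "load_checkpoint",
]

#: channel widths of the trunk (4 convs) and the counting head (3 convs)
TRUNK_CHANNELS = (8, 12, 12, 12)
HEAD_CHANNELS = (8, 8, 1)
#: minimum separation of reported density peaks, patch px
PEAK_MIN_SEPARATION = 3.0


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    gamma is the residual slope of the truncated count prediction; omega
    weights the counting loss against the classification loss.
    """

    gamma: float = 0.001
    omega: float = 1.0
    learning_rate: float = 1e-4
    batch_size: int = 1024
    max_epochs: int = 30
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


class WSCNet:
    """Two-branch counting network on NumPy arrays (NHWC, float32)."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.seed = seed
        chans = (1,) + TRUNK_CHANNELS
        self.trunk = [Conv3x3(chans[i], chans[i + 1], rng) for i in range(4)]
        hchans = (TRUNK_CHANNELS[-1],) + HEAD_CHANNELS
        self.head = [Conv3x3(hchans[i], hchans[i + 1], rng) for i in range(3)]
        # the final map layer starts near (but not at) zero: the truncated
        # count has slope gamma << 1 once Dsum >= 2, so a large initial map
        # integral would see almost no gradient; a tiny positive bias keeps
        # the output ReLU alive while Dsum starts around 1
        self.head[-1].W *= 0.05
        self.head[-1].b[:] = 1.0e-3
        self.norm = FeatureNorm(TRUNK_CHANNELS[-1])
        self.fc = Linear(TRUNK_CHANNELS[-1], 2, rng)
        self._cache: dict = {}

    # -- parameter plumbing -------------------------------------------------
    @property
    def layers(self):
        return [*self.trunk, *self.head, self.fc]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def buffers(self):
        return self.norm.buffers()

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in [*self.params(), *self.buffers()]:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def architecture_hash(self) -> str:
        desc = json.dumps([list(p.shape) for p in self.params()])
        return hashlib.sha256(desc.encode()).hexdigest()[:16]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True):
        """x: (B, S, S) in [0, 1] -> (logits (B, 2), density (B, S, S))."""
        a = np.asarray(x)[..., None]
        if a.dtype != np.float64:  # float64 kept for numerical checks
            a = a.astype(np.float32)
        acts = []
        for conv in self.trunk:
            a = relu(conv.forward(a, train))
            acts.append(a)
        trunk_out = a
        c = trunk_out
        head_acts = []
        for conv in self.head:
            c = relu(conv.forward(c, train))
            head_acts.append(c)
        density = c[..., 0]
        pooled = self.norm.forward(trunk_out.mean(axis=(1, 2)), train)
        logits = self.fc.forward(pooled, train)
        if train:
            self._cache = {"acts": acts, "head_acts": head_acts}
        return logits, density

    def backward(self, dlogits: np.ndarray, ddensity: np.ndarray) -> None:
        """Accumulate gradients for both branches.

        The classification branch trains its own readout (feature norm +
        linear); its gradient is not propagated into the shared trunk.  The
        trunk and counting head are shaped by the counting objective alone,
        which keeps the two branches from competing for the 12 trunk
        channels: the droplet/background decision is linearly separable in
        pooled trunk features regardless of what the trunk learned, whereas
        cell-density features are destroyed when amplified classification
        gradients dominate the trunk.
        """
        acts = self._cache["acts"]
        head_acts = self._cache["head_acts"]
        # classification readout: linear <- feature norm (stops at pooling)
        self.norm.backward(self.fc.backward(dlogits.astype(np.float32)))
        # counting branch: density head back into the trunk
        dc = ddensity[..., None].astype(acts[-1].dtype)
        for conv, a in zip(reversed(self.head), reversed(head_acts)):
            dc = conv.backward(relu_grad(a, dc))
        dtrunk = dc
        for conv, a in zip(reversed(self.trunk), reversed(acts)):
            dtrunk = conv.backward(relu_grad(a, dtrunk))
        self._cache = {}


def build_model(seed: int = 0) -> WSCNet:
    """Deterministically initialized network; same seed -> same weights."""
    return WSCNet(seed=seed)


# ---------------------------------------------------------------------------
# loss pieces (defined on density maps or directly on Dsum / Dmax scalars)


def _dsum(d) -> float:
    d = np.asarray(d, dtype=float)
    return float(d.sum()) if d.ndim > 0 else float(d)


def truncated_count(density, gamma: float) -> float:
    """Count prediction f(D): Dsum below 2, then 2 + gamma * Dsum.

    The truncation encodes the weak "at least two" label; gamma keeps a
    small gradient so heavily overfull maps are still pushed down.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    s = _dsum(density)
    return s if s < 2.0 else 2.0 + gamma * s


def max_regularizer(density) -> float:
    """psi(D) = Dmax - 1 when the map's maximum exceeds 1, else 0."""
    d = np.asarray(density, dtype=float)
    dmax = float(d.max()) if d.ndim > 0 else float(d)
    return dmax - 1.0 if dmax > 1.0 else 0.0


def counting_loss(density, y: int, gamma: float) -> float:
    """Truncated squared count error plus the max regularizer."""
    if y not in (0, 1, 2):
        raise ValueError("count label must be 0, 1 or 2")
    err = truncated_count(density, gamma) - y
    return err * err + max_regularizer(density)


def total_loss(class_loss: float, count_loss: float, omega: float) -> float:
    """Joint objective L = Lclass + omega * Lcount."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return class_loss + omega * count_loss


def reclassify(dsum: float) -> int:
    """Droplet category from the density integral: nearest of {0, 1, 2}.

    Ties (Dsum exactly 0.5 or 1.5) go to the smaller count.
    """
    if dsum < 0:
        raise ValueError("Dsum must be >= 0")
    dists = [(dsum - k) ** 2 for k in (0, 1, 2)]
    return int(np.argmin(dists))


# ---------------------------------------------------------------------------
# training


def _softmax_ce(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient wrt logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def _count_loss_batch(density: np.ndarray, y: np.ndarray, mask: np.ndarray,
                      gamma: float):
    """Mean truncated counting loss over the masked (droplet) patches and
    its gradient wrt the density maps; background patches get zero grad."""
    B, H, W = density.shape
    ddensity = np.zeros_like(density, dtype=np.float32)
    m = int(mask.sum())
    if m == 0:
        return 0.0, ddensity
    dsum = density.sum(axis=(1, 2))
    trunc = dsum >= 2.0
    f = np.where(trunc, 2.0 + gamma * dsum, dsum)
    err = f - y
    dmax = density.max(axis=(1, 2))
    over = dmax > 1.0
    loss = float(np.sum(mask * (err**2 + np.where(over, dmax - 1.0, 0.0))) / m)
    # d/dDsum of the squared error term; uniform over pixels
    dfd = np.where(trunc, gamma, 1.0)
    per = (2.0 * err * dfd * mask / m).astype(np.float32)
    ddensity += per[:, None, None]
    # max regularizer: unit gradient at the argmax pixel of offending maps
    for i in np.flatnonzero(mask & over):
        r, c = np.unravel_index(int(np.argmax(density[i])), (H, W))
        ddensity[i, r, c] += 1.0 / m
    return loss, ddensity


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def _epoch_loss(model: WSCNet, x, cls, y, droplet_mask, cfg: TrainConfig,
                batch: int = 512, counting_only: bool = False) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        sl = slice(i, i + batch)
        nb = min(batch, len(x) - i)
        logits, density = model.forward(x[sl], train=False)
        lc = 0.0 if counting_only else _softmax_ce(logits, cls[sl])[0]
        lk, _ = _count_loss_batch(density, y[sl], droplet_mask[sl], cfg.gamma)
        total += total_loss(lc, lk, cfg.omega) * nb
        n += nb
    return total / n


def _trunk_pooled(model: WSCNet, x: np.ndarray, batch: int = 512) -> np.ndarray:
    """Raw (un-normalized) pooled trunk features, eval mode, batched."""
    feats = []
    for i in range(0, len(x), batch):
        a = x[i : i + batch, ..., None].astype(np.float32)
        for conv in model.trunk:
            a = relu(conv.forward(a, train=False))
        feats.append(a.mean(axis=(1, 2)))
    return np.concatenate(feats, axis=0)


def _fit_classifier(model: WSCNet, x, cls, rng, lr: float = 1e-2,
                    steps: int = 400, batch: int = 256) -> None:
    """Fit the classification readout (feature norm + linear) on the frozen
    trunk: features are computed once, so this phase costs almost nothing."""
    feats = _trunk_pooled(model, x)
    model.norm.running_mean[:] = feats.mean(axis=0)
    model.norm.running_var[:] = feats.var(axis=0)
    z = ((feats - model.norm.running_mean)
         / np.sqrt(model.norm.running_var + model.norm.eps)).astype(np.float32)
    opt = Adam(model.fc.params(), lr=lr)
    for _ in range(steps):
        idx = rng.integers(0, len(z), size=min(batch, len(z)))
        logits = model.fc.forward(z[idx], train=True)
        _, dlogits = _softmax_ce(logits, cls[idx])
        model.fc.backward(dlogits)
        opt.step(model.fc.grads())


def train(model: WSCNet, patches: PatchDataset, cfg: TrainConfig) -> TrainHistory:
    """Mini-batch training from droplet-level labels only.

    Training runs in two phases.  First the counting objective (truncated
    squared error + max regularizer, droplet patches only) shapes the
    shared trunk and the counting head; the learning rate is halved when
    the validation counting loss stops improving for ``cfg.patience``
    epochs, and the best-validation weights are restored.  Then the
    classification readout (feature standardization + linear layer) is
    fitted on the frozen trunk features with all patches (background
    negative, droplets positive).  Fitting the readout after the
    representation has settled avoids the two branches competing for the
    narrow trunk; the droplet/background decision is linearly separable in
    pooled trunk features in any case.
    """
    for cat, present in (
        ("background", np.any(~patches.is_droplet)),
        ("empty", np.any(patches.count_label[patches.is_droplet] == 0)),
        ("single", np.any(patches.count_label[patches.is_droplet] == 1)),
        ("multiple", np.any(patches.count_label[patches.is_droplet] == 2)),
    ):
        if not present:
            raise ValueError(f"training data contains no {cat!r} patches")

    tr = patches.subset("train")
    va = patches.subset("val")
    x_tr = tr.images
    cls_tr = tr.is_droplet.astype(np.int64)
    y_tr = tr.count_label.astype(np.float64)
    m_tr = tr.is_droplet
    x_va, cls_va = va.images, va.is_droplet.astype(np.int64)
    y_va, m_va = va.count_label.astype(np.float64), va.is_droplet

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_params = [p.copy() for p in model.params()]
    stale = 0

    zeros2 = None
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, n_batches = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            _logits, density = model.forward(x_tr[idx], train=True)
            lk, ddensity = _count_loss_batch(density, y_tr[idx], m_tr[idx], cfg.gamma)
            if zeros2 is None or len(zeros2) != len(idx):
                zeros2 = np.zeros((len(idx), 2), dtype=np.float32)
            model.backward(zeros2, cfg.omega * ddensity)
            opt.step(model.grads())
            ep_loss += lk
            n_batches += 1
        val = _epoch_loss(model, x_va, cls_va, y_va, m_va, cfg,
                          counting_only=True)
        history.train_loss.append(ep_loss / max(n_batches, 1))
        history.val_loss.append(val)
        history.lr.append(opt.lr)
        if val < best_val - 1e-4:
            best_val = val
            best_params = [p.copy() for p in model.params()]
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                opt.lr /= 2.0
                stale = 0
    for p, bp in zip(model.params(), best_params):
        p[...] = bp

    _fit_classifier(model, x_tr, cls_tr, rng)
    return history


# ---------------------------------------------------------------------------
# inference


def density_peaks(density: np.ndarray, k: int,
                  min_separation: float = PEAK_MIN_SEPARATION):
    """First k maxima of a density map, greedy with disk suppression.

    Ties are resolved by raster order (argmax convention).  Returns (x, y)
    patch coordinates.
    """
    d = np.array(density, dtype=float)
    H, W = d.shape
    yy, xx = np.mgrid[0:H, 0:W]
    peaks: list[tuple[float, float]] = []
    for _ in range(k):
        if not np.any(d > -np.inf):
            break
        r, c = np.unravel_index(int(np.argmax(d)), d.shape)
        peaks.append((float(c), float(r)))
        d[(xx - c) ** 2 + (yy - r) ** 2 <= min_separation**2] = -np.inf
    return peaks


@dataclass
class DropletDetection:
    """Per-proposal recognition result.

    ``cell_locations`` are frame coordinates; the density-derived fields
    are only populated when the proposal is classified as a droplet.
    """

    proposal: CircleProposal
    is_droplet: bool
    droplet_confidence: float
    dsum: float | None = None
    predicted_count: int | None = None
    category: int | None = None
    cell_locations: list[tuple[float, float]] = field(default_factory=list)


def _patch_to_frame(points, transform):
    x0, y0, s = transform
    return [(x0 + (px + 0.5) / s - 0.5, y0 + (py + 0.5) / s - 0.5)
            for px, py in points]


def infer_frame(
    model: WSCNet,
    frame: np.ndarray,
    proposals: list[CircleProposal],
    patch_size: int = DEFAULT_PATCH_SIZE,
    background_level: float = 200.0,
) -> list[DropletDetection]:
    """Run the network on every proposal of a frame (batched forward)."""
    h, w = frame.shape
    for p in proposals:
        if not (0 <= p.center_x < w and 0 <= p.center_y < h):
            raise ValueError(f"proposal center ({p.center_x}, {p.center_y}) "
                             f"outside {w}x{h} frame")
    if not proposals:
        return []
    patches, transforms = [], []
    for p in proposals:
        patch, tf = extract_patch(frame, (p.center_x, p.center_y), p.radius,
                                  patch_size, background_level)
        patches.append(patch)
        transforms.append(tf)
    logits, density = model.forward(np.stack(patches), train=False)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    out: list[DropletDetection] = []
    for p, tf, pr, dmap in zip(proposals, transforms, probs, density):
        is_droplet = bool(pr[1] >= pr[0])
        det = DropletDetection(
            proposal=p, is_droplet=is_droplet, droplet_confidence=float(pr[1])
        )
        if is_droplet:
            dsum = float(dmap.sum())
            count = int(np.floor(dsum + 0.5))
            det.dsum = dsum
            det.predicted_count = count
            det.category = reclassify(dsum)
            det.cell_locations = _patch_to_frame(density_peaks(dmap, count), tf)
        out.append(det)
    return out


def infer(
    model: WSCNet,
    proposal: CircleProposal,
    frame: np.ndarray,
    patch_size: int = DEFAULT_PATCH_SIZE,
    background_level: float = 200.0,
) -> DropletDetection:
    """Recognize a single proposal; see infer_frame."""
    return infer_frame(model, frame, [proposal], patch_size, background_level)[0]


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: WSCNet, path, cfg: TrainConfig | None = None,
                    patch_size: int = DEFAULT_PATCH_SIZE) -> None:
    """Write weights (.npz) plus a JSON sidecar with the architecture hash
    and the training configuration."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    np.savez(path, **arrays)
    meta = {
        "architecture_hash": model.architecture_hash(),
        "patch_size": patch_size,
        "seed": model.seed,
        "gamma": cfg.gamma if cfg else None,
        "omega": cfg.omega if cfg else None,
    }
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> tuple[WSCNet, dict]:
    """Load a checkpoint; raises if the stored architecture differs."""
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    model = WSCNet(seed=0)
    with np.load(path) as data:
        n_p = sum(1 for f in data.files if f.startswith("p"))
        stored = [data[f"p{i}"] for i in range(n_p)]
        stored_buf = [data[f"b{i}"] for i in range(len(data.files) - n_p)]
    params = model.params()
    if len(stored) != len(params) or any(
        s.shape != p.shape for s, p in zip(stored, params)
    ):
        raise ValueError(
            f"checkpoint architecture mismatch (expected "
            f"{model.architecture_hash()})"
        )
    for p, s in zip(params, stored):
        p[...] = s
    for b, s in zip(model.buffers(), stored_buf):
        b[...] = s
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if meta.get("architecture_hash") not in (None, model.architecture_hash()):
        raise ValueError(
            f"checkpoint architecture hash {meta['architecture_hash']} != "
            f"{model.architecture_hash()}"
        )
    return model, meta
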