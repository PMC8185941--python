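"""Point-supervised cellular localization (C-Net).

Point annotations are expanded into per-class binary disk target maps; a
compact fully-convolutional encoder-decoder with five sigmoid heads (one per
cell class, one-vs-rest) and a half-resolution deep-supervision head is
trained with the weighted pixel-wise cross-entropy

    phi(p, t) = lambda * |p - t| ** gamma
    L = -mean_{b,i,c} phi * (t * log p + (1 - t) * log(1 - p))

(lambda = gamma = 3 by default), a focal-style weighting that concentrates
gradient on hard pixels — in particular the valleys between close/adhesive
tumor cells that plain cross-entropy tends to fuse into one blob.
Detections are the class-wise local maxima of the predicted probability
maps after non-maximum suppression.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from ._nn import (
    EncoderDecoder,
    MomentumSGD,
    NetConfig,
    avgpool2,
)
from .annotio import CLASS_INDEX, CLASS_ORDER, CellAnnotation, CellClass

logger = logging.getLogger("pdl1tps")

EPS = 1e-7  # probability clamp for the logarithms


@dataclass(frozen=True)
class LossConfig:
    """Weighted pixel-wise cross-entropy parameters."""

    lam: float = 3.0    # weight scale lambda
    gamma: float = 3.0  # focusing exponent

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class Detection:
    """A predicted cell: coordinate (cell scale, 0-based), class, confidence."""

    x: int
    y: int
    cls: CellClass
    score: float


# ---------------------------------------------------------------------------
# target maps
# ---------------------------------------------------------------------------

def make_target_maps(annotations: Sequence[CellAnnotation],
                     shape: tuple[int, int], disk_radius: int = 9) -> np.ndarray:
    """Expand point annotations into per-class binary disk maps.

    Channel ``c`` (ordered as :data:`~pdl1tps.annotio.CLASS_ORDER`) carries a
    disk of ones of the given radius centred on each class-``c`` annotation
    (union where disks overlap), clipped to the tile; pixels at integer
    offsets with ``dx**2 + dy**2 <= disk_radius**2`` belong to the disk.
    """
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    h, w = shape
    maps = np.zeros((len(CLASS_ORDER), h, w), dtype=np.float32)
    r = int(disk_radius)
    for a in annotations:
        if not (0 <= a.x < w and 0 <= a.y < h):
            raise ValueError(f"annotation ({a.x}, {a.y}) outside tile shape {shape}")
        c = CLASS_INDEX[a.cls]
        x0, x1 = max(0, a.x - r), min(w, a.x + r + 1)
        y0, y1 = max(0, a.y - r), min(h, a.y + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (xx - a.x) ** 2 + (yy - a.y) ** 2 <= disk_radius ** 2
        maps[c, y0:y1, x0:x1][disk] = 1.0
    return maps


# ---------------------------------------------------------------------------
# weighted pixel-wise cross-entropy
# ---------------------------------------------------------------------------

def weight_matrix(pred: np.ndarray, target: np.ndarray,
                  cfg: LossConfig = LossConfig()) -> np.ndarray:
    """Per-pixel weights ``phi = lambda * |pred - target| ** gamma``."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return cfg.lam * np.abs(pred - target) ** cfg.gamma


def weighted_pixelwise_ce(pred: np.ndarray, target: np.ndarray,
                          cfg: LossConfig = LossConfig()) -> float:
    """Scalar weighted pixel-wise cross-entropy (mean over all elements).

    Reduces to standard mean binary cross-entropy for ``lam=1, gamma=0``.
    Predictions are clamped to ``[EPS, 1-EPS]`` before the logarithms.
    """
    pred, target = np.asarray(pred, dtype=np.float64), np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if not (np.isfinite(pred).all() and np.isfinite(target).all()):
        raise ValueError("non-finite values in loss inputs")
    p = np.clip(pred, EPS, 1.0 - EPS)
    phi = weight_matrix(p, target, cfg)
    ce = target * np.log(p) + (1.0 - target) * np.log1p(-p)
    return float(-(phi * ce).mean())


def _wpce_value_and_grad(pred: np.ndarray, target: np.ndarray,
                         cfg: LossConfig) -> tuple[float, np.ndarray]:
    """Loss and dL/d(pred), differentiating through the weight matrix."""
    p = np.clip(pred, EPS, 1.0 - EPS)
    diff = p - target
    absd = np.abs(diff)
    phi = cfg.lam * absd ** cfg.gamma
    ce = target * np.log(p) + (1.0 - target) * np.log1p(-p)
    loss = float(-(phi * ce).mean())
    dce = target / p - (1.0 - target) / (1.0 - p)
    if cfg.gamma == 0:
        dphi = np.zeros_like(p)
    else:
        # |x|**(g-1) * sign(x); safe at x == 0 for g >= 1
        with np.errstate(divide="ignore", invalid="ignore"):
            dphi = cfg.lam * cfg.gamma * np.where(
                absd > 0, absd ** (cfg.gamma - 1.0), 0.0) * np.sign(diff)
    grad = -(dphi * ce + phi * dce) / p.size
    inside = (pred > EPS) & (pred < 1.0 - EPS)
    return loss, np.where(inside, grad, 0.0)


# ---------------------------------------------------------------------------
# network construction / persistence
# ---------------------------------------------------------------------------

@dataclass
class CNet:
    """A C-Net handle: network weights plus input whitening statistics."""

    net: EncoderDecoder
    mean: np.ndarray  # per-channel, from the training set
    std: np.ndarray
    disk_radius: int = 9

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Per-class probability maps (5, H, W) for an RGB (H, W, 3) tile."""
        x = self._normalize(image)
        return self.net.predict(x).astype(np.float64)

    def _normalize(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32) / 255.0
        x = (x - self.mean[None, None, :]) / self.std[None, None, :]
        return x.transpose(2, 0, 1)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.net.save(path)
        with np.load(path) as data:
            arrays = dict(data)
        arrays["__norm_mean__"] = self.mean
        arrays["__norm_std__"] = self.std
        arrays["__disk_radius__"] = np.array([self.disk_radius])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CNet":
        net = EncoderDecoder.load(path)
        with np.load(Path(path)) as data:
            mean = data["__norm_mean__"]
            std = data["__norm_std__"]
            disk_radius = int(data["__disk_radius__"][0])
        return cls(net=net, mean=mean, std=std, disk_radius=disk_radius)


def build_cnet(n_classes: int = 5, base_width: int = 8, depth: int = 3,
               seed: int = 0, aux_head: bool = True) -> CNet:
    """Build an untrained C-Net (sigmoid one-vs-rest heads, deep supervision)."""
    cfg = NetConfig(in_channels=3, n_classes=n_classes, base_width=base_width,
                    depth=depth, head="sigmoid", aux_head=aux_head)
    net = EncoderDecoder(cfg, seed=seed)
    logger.info("C-Net built: depth=%d base_width=%d parameters=%d (config %s)",
                depth, base_width, net.n_parameters(), cfg.hash())
    return CNet(net=net, mean=np.zeros(3, np.float32), std=np.ones(3, np.float32))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Online augmentation: rotation, shear, shift, zoom, flips.

    Magnitudes follow common practice for IHC patches: rotation uniform in
    +/-180 deg, shear +/-10 deg, shift +/-10% of the tile, zoom 0.9-1.1,
    horizontal/vertical flips with p=0.5.  Input whitening (per-channel
    standardization by training-set mean/SD) is applied separately.
    """

    rotate_deg: float = 180.0
    shear_deg: float = 10.0
    shift_frac: float = 0.10
    zoom: tuple[float, float] = (0.9, 1.1)
    flip_p: float = 0.5


def _augment_pair(image_chw: np.ndarray, target: np.ndarray,
                  aug: AugmentConfig, rng: np.random.Generator):
    """Apply one random affine + flips to an image and its target maps."""
    if rng.random() < aug.flip_p:
        image_chw = image_chw[:, :, ::-1]
        target = target[:, :, ::-1]
    if rng.random() < aug.flip_p:
        image_chw = image_chw[:, ::-1, :]
        target = target[:, ::-1, :]
    th = np.deg2rad(rng.uniform(-aug.rotate_deg, aug.rotate_deg))
    sh = np.deg2rad(rng.uniform(-aug.shear_deg, aug.shear_deg))
    zx = rng.uniform(*aug.zoom)
    zy = rng.uniform(*aug.zoom)
    h, w = image_chw.shape[1:]
    tx = rng.uniform(-aug.shift_frac, aug.shift_frac) * w
    ty = rng.uniform(-aug.shift_frac, aug.shift_frac) * h
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, np.tan(sh)], [0.0, 1.0]])
    zoom = np.diag([1.0 / zy, 1.0 / zx])
    m = rot @ shear @ zoom
    center = np.array([h / 2.0, w / 2.0])
    offset = center - m @ center + np.array([ty, tx])
    img_out = np.stack([
        ndimage.affine_transform(ch, m, offset=offset, order=1, mode="reflect")
        for ch in image_chw
    ])
    tgt_out = np.stack([
        ndimage.affine_transform(ch, m, offset=offset, order=0, mode="constant")
        for ch in target
    ])
    return img_out.astype(image_chw.dtype), tgt_out.astype(target.dtype)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer/training settings.

    The full-scale recipe is batch size 4, initial learning rate 0.001,
    momentum optimizer, maximum 200 epochs; desk-scale smoke runs use the
    same optimizer with fewer epochs and a larger learning rate.
    """

    epochs: int = 200
    batch_size: int = 4
    lr: float = 0.001            # initial learning rate
    momentum: float = 0.9
    lr_decay: float = 0.1        # step decay factor applied late in training
    lr_decay_at: float = 0.75    # fraction of epochs after which lr decays
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    aux_weight: float = 0.4
    augment: AugmentConfig | None = None

    def to_dict(self):
        d = asdict(self)
        return d


def _check_finite(value: float, cfg: TrainConfig, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            "training diverged (non-finite loss) at epoch "
            f"{epoch}; config: {json.dumps(cfg.to_dict(), default=str)}"
        )


def train_cnet(tiles: Sequence[np.ndarray], targets: Sequence[np.ndarray],
               cfg: TrainConfig = TrainConfig(),
               val_tiles: Sequence[np.ndarray] = (),
               val_targets: Sequence[np.ndarray] = (),
               base_width: int = 8, depth: int = 3,
               disk_radius: int = 9) -> tuple[CNet, dict]:
    """Train a C-Net on RGB tiles and their binary target maps.

    Deterministic for a fixed ``cfg.seed``.  Returns the checkpoint with the
    best validation loss (final weights when no validation set is given) and
    the loss history ``{"train": [...], "val": [...]}``.
    """
    if len(tiles) == 0:
        raise ValueError("empty training set")
    if len(tiles) != len(targets):
        raise ValueError("tiles and targets must pair up")

    model = build_cnet(base_width=base_width, depth=depth, seed=cfg.seed)
    model.disk_radius = disk_radius
    stack = np.stack([np.asarray(t, dtype=np.float32) / 255.0 for t in tiles])
    model.mean = stack.mean(axis=(0, 1, 2)).astype(np.float32)
    model.std = np.maximum(stack.std(axis=(0, 1, 2)), 1e-3).astype(np.float32)

    xs = [model._normalize(t) for t in tiles]
    ys = [np.asarray(t, dtype=np.float32) for t in targets]
    vxs = [model._normalize(t) for t in val_tiles]
    vys = [np.asarray(t, dtype=np.float32) for t in val_targets]

    rng = np.random.default_rng(cfg.seed)
    opt = MomentumSGD(model.net, lr=cfg.lr, momentum=cfg.momentum)
    history = {"train": [], "val": []}
    best_val = np.inf
    best_state = None

    for epoch in range(cfg.epochs):
        if cfg.epochs > 1 and epoch == int(cfg.lr_decay_at * cfg.epochs):
            opt.lr = cfg.lr * cfg.lr_decay
        order = rng.permutation(len(xs))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            bx, by = [], []
            for i in idx:
                xi, yi = xs[i], ys[i]
                if cfg.augment is not None:
                    xi, yi = _augment_pair(xi, yi, cfg.augment, rng)
                bx.append(xi)
                by.append(yi)
            x = np.stack(bx)
            y = np.stack(by)
            model.net.zero_grad()
            prob, aux = model.net.forward(x, train=True)
            loss, dmain = _wpce_value_and_grad(prob, y, cfg.loss)
            daux = None
            if aux is not None:
                y_aux = avgpool2(y)
                aux_loss, daux = _wpce_value_and_grad(aux, y_aux, cfg.loss)
                loss = loss + cfg.aux_weight * aux_loss
                daux = cfg.aux_weight * daux
            _check_finite(loss, cfg, epoch)
            model.net.backward(dmain.astype(np.float32),
                               None if daux is None else daux.astype(np.float32))
            opt.step()
            epoch_losses.append(loss)
        history["train"].append(float(np.mean(epoch_losses)))
        if vxs:
            vloss = []
            for xi, yi in zip(vxs, vys):
                p, _ = model.net.forward(xi[None], train=False)
                vloss.append(weighted_pixelwise_ce(p[0], yi, cfg.loss))
            v = float(np.mean(vloss))
            _check_finite(v, cfg, epoch)
            history["val"].append(v)
            if v < best_val:
                best_val = v
                best_state = copy.deepcopy(model.net.state_arrays())
    if best_state is not None:
        for i, layer in enumerate(model.net.layers()):
            layer.W[...] = best_state[f"W{i}"]
            layer.b[...] = best_state[f"b{i}"]
    logger.info("C-Net training done: %d epochs, final train loss %.5f",
                cfg.epochs, history["train"][-1])
    return model, history


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def extract_detections(prob: np.ndarray, threshold: float = 0.5,
                       min_distance: int = 9) -> list[Detection]:
    """Probability maps (5, H, W) -> point detections via NMS.

    Per channel, local maxima above ``threshold`` are found (plateaus —
    e.g. binary disks — are reduced to their centroid); then a single
    greedy pass keeps, among all detections within ``min_distance`` of a
    kept one (same or different class), only the highest-scoring one, ties
    broken by row-major order then channel order.
    """
    prob = np.asarray(prob)
    size = 2 * int(np.ceil(min_distance)) + 1
    candidates = []  # (score, y, x, class_idx)
    for c in range(prob.shape[0]):
        ch = prob[c]
        mask = (ch >= threshold) & (ch == ndimage.maximum_filter(ch, size=size))
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)
        for comp in range(1, n + 1):
            ys, xs = np.nonzero(labels == comp)
            y = int(round(ys.mean()))
            x = int(round(xs.mean()))
            candidates.append((float(ch[ys[0], xs[0]]), y, x, c))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    kept: list[Detection] = []
    r2 = float(min_distance) ** 2
    for score, y, x, c in candidates:
        if any((x - k.x) ** 2 + (y - k.y) ** 2 < r2 for k in kept):
            continue
        kept.append(Detection(x=x, y=y, cls=CLASS_ORDER[c], score=score))
    return kept
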