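"""Low-magnification tumor-region segmentation (R-Net) and the ensemble step.

R-Net is a compact fully-convolutional softmax segmenter over three region
classes — TC(+) region, TC(-) region, normal/stromal region — at region
scale (1/4 of the cell-scale linear resolution, mirroring 10x region
annotations against 40x cell annotations).  Its tumor-probability map
(TC(+) + TC(-) probabilities, bilinearly upsampled to cell scale)
multiplicatively suppresses the C-Net tumor-cell channels outside tumor
regions: the multistage ensemble.  Masking is applied to the
post-activation probability maps, which decouples the two networks while
giving non-tumor cells a minimal probability after activation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize

from ._nn import EncoderDecoder, MomentumSGD, NetConfig
from .annotio import RegionLabel, RegionMask
from .cnet import TrainConfig, _check_finite

logger = logging.getLogger("pdl1tps")

#: R-Net softmax channel order
REGION_CLASS_ORDER = (
    RegionLabel.TC_POS_REGION,
    RegionLabel.TC_NEG_REGION,
    RegionLabel.NORMAL_REGION,
)


@dataclass
class RNet:
    """An R-Net handle: network weights plus input whitening statistics."""

    net: EncoderDecoder
    mean: np.ndarray
    std: np.ndarray

    def predict(self, region_image: np.ndarray) -> np.ndarray:
        """(3, h, w) softmax region probability maps for an RGB region tile."""
        x = self._normalize(region_image)
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
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RNet":
        net = EncoderDecoder.load(path)
        with np.load(Path(path)) as data:
            mean, std = data["__norm_mean__"], data["__norm_std__"]
        return cls(net=net, mean=mean, std=std)


def build_rnet(n_classes: int = 3, base_width: int = 8, depth: int = 2,
               seed: int = 0) -> RNet:
    """Build an untrained R-Net (softmax over the three region classes)."""
    cfg = NetConfig(in_channels=3, n_classes=n_classes, base_width=base_width,
                    depth=depth, head="softmax", aux_head=False)
    net = EncoderDecoder(cfg, seed=seed)
    logger.info("R-Net built: depth=%d base_width=%d parameters=%d (config %s)",
                depth, base_width, net.n_parameters(), cfg.hash())
    return RNet(net=net, mean=np.zeros(3, np.float32), std=np.ones(3, np.float32))


def downsample_to_region_scale(image: np.ndarray, factor: int = 4) -> np.ndarray:
    """Block-mean downsample a cell-scale RGB tile to region scale."""
    h, w = image.shape[:2]
    h2, w2 = h // factor, w // factor
    x = np.asarray(image, dtype=np.float64)[: h2 * factor, : w2 * factor]
    x = x.reshape(h2, factor, w2, factor, -1).mean(axis=(1, 3))
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def _mask_to_onehot(mask: RegionMask) -> np.ndarray:
    """Region label mask -> (3, h, w) one-hot training target.

    BACKGROUND pixels (bare glass) are folded into the normal/stromal class:
    both are non-tumor for the purposes of the ensemble.
    """
    labels = mask.labels
    valid = {int(v) for v in RegionLabel}
    present = set(np.unique(labels).tolist())
    if not present <= valid:
        raise ValueError(f"mask contains labels outside {sorted(valid)}")
    onehot = np.zeros((3,) + labels.shape, dtype=np.float32)
    onehot[0] = labels == int(RegionLabel.TC_POS_REGION)
    onehot[1] = labels == int(RegionLabel.TC_NEG_REGION)
    onehot[2] = ((labels == int(RegionLabel.NORMAL_REGION))
                 | (labels == int(RegionLabel.BACKGROUND)))
    return onehot


def train_rnet(region_tiles: Sequence[np.ndarray], region_masks: Sequence[RegionMask],
               cfg: TrainConfig = TrainConfig(),
               val_tiles: Sequence[np.ndarray] = (),
               val_masks: Sequence[RegionMask] = (),
               base_width: int = 8, depth: int = 2) -> tuple[RNet, dict]:
    """Train R-Net with pixel-wise 3-class cross-entropy (momentum SGD).

    Deterministic for a fixed seed; identical call -> identical history.
    """
    if len(region_tiles) == 0:
        raise ValueError("empty training set")
    if len(region_tiles) != len(region_masks):
        raise ValueError("tiles and masks must pair up")

    model = build_rnet(base_width=base_width, depth=depth, seed=cfg.seed)
    stack = np.stack([np.asarray(t, dtype=np.float32) / 255.0 for t in region_tiles])
    model.mean = stack.mean(axis=(0, 1, 2)).astype(np.float32)
    model.std = np.maximum(stack.std(axis=(0, 1, 2)), 1e-3).astype(np.float32)

    xs = [model._normalize(t) for t in region_tiles]
    ys = [_mask_to_onehot(m) for m in region_masks]
    vxs = [model._normalize(t) for t in val_tiles]
    vys = [_mask_to_onehot(m) for m in val_masks]

    rng = np.random.default_rng(cfg.seed)
    opt = MomentumSGD(model.net, lr=cfg.lr, momentum=cfg.momentum)
    history = {"train": [], "val": []}
    best_val, best_state = np.inf, None
    eps = 1e-7

    def ce_and_grad(prob, onehot):
        p = np.clip(prob, eps, 1.0)
        loss = float(-(onehot * np.log(p)).sum(axis=1).mean())
        grad = -(onehot / p) / (prob.shape[0] * prob.shape[2] * prob.shape[3])
        return loss, grad

    for epoch in range(cfg.epochs):
        if cfg.epochs > 1 and epoch == int(cfg.lr_decay_at * cfg.epochs):
            opt.lr = cfg.lr * cfg.lr_decay
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = np.stack([xs[i] for i in idx])
            y = np.stack([ys[i] for i in idx])
            model.net.zero_grad()
            prob, _ = model.net.forward(x, train=True)
            loss, dprob = ce_and_grad(prob, y)
            _check_finite(loss, cfg, epoch)
            model.net.backward(dprob.astype(np.float32))
            opt.step()
            losses.append(loss)
        history["train"].append(float(np.mean(losses)))
        if vxs:
            v = float(np.mean([
                ce_and_grad(model.net.forward(xi[None], train=False)[0], yi[None])[0]
                for xi, yi in zip(vxs, vys)
            ]))
            _check_finite(v, cfg, epoch)
            history["val"].append(v)
            if v < best_val:
                best_val, best_state = v, copy.deepcopy(model.net.state_arrays())
    if best_state is not None:
        for i, layer in enumerate(model.net.layers()):
            layer.W[...] = best_state[f"W{i}"]
            layer.b[...] = best_state[f"b{i}"]
    logger.info("R-Net training done: %d epochs, final train loss %.5f",
                cfg.epochs, history["train"][-1])
    return model, history


# ---------------------------------------------------------------------------
# ensemble step
# ---------------------------------------------------------------------------

def tumor_probability(region_prob: np.ndarray, scale_factor: int = 4) -> np.ndarray:
    """Cell-scale tumor-probability map from (3, h, w) region probabilities.

    tumor_prob = P(TC(+) region) + P(TC(-) region), bilinearly upsampled by
    ``scale_factor``; values stay within [0, 1].
    """
    if scale_factor < 1:
        raise ValueError("scale_factor must be >= 1")
    tp = region_prob[0] + region_prob[1]
    if scale_factor == 1:
        return np.clip(tp, 0.0, 1.0)
    out = resize(tp, (tp.shape[0] * scale_factor, tp.shape[1] * scale_factor),
                 order=1, mode="edge", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def mask_cell_maps(cell_prob: np.ndarray, tumor_prob: np.ndarray) -> np.ndarray:
    """Multiplicatively suppress C-Net tumor-cell channels outside tumor.

    Channels 0 and 1 (TC(+), TC(-)) are multiplied pixel-wise by
    ``tumor_prob``; immune/stromal channels pass through unchanged.
    """
    if cell_prob.shape[1:] != tumor_prob.shape:
        raise ValueError(
            f"shape mismatch: cell maps {cell_prob.shape[1:]} vs "
            f"tumor_prob {tumor_prob.shape}")
    out = cell_prob.copy()
    out[0] = out[0] * tumor_prob
    out[1] = out[1] * tumor_prob
    return out
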