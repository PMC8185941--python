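"""Minimal fully-convolutional network core in numpy.

Implements exactly what the cell-localization (C-Net) and region-segmentation
(R-Net) contracts need: 3x3 'same' convolutions via im2col, ReLU, transition
blocks (1x1 convolution + 2x2 average pooling), nearest-neighbour x2
upsampling with skip concatenation, sigmoid / softmax heads, an auxiliary
deep-supervision head at half resolution, and momentum SGD.  Gradients are
hand-derived and verified against finite differences in the test suite.

Arrays are NCHW float32 by default (float64 for gradient checks).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2D:
    """k x k 'same' convolution (zero padding), He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * scale).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k)
        y = cols @ self.W.reshape(len(self.W), -1).T + self.b
        if train:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    # -- backward ----------------------------------------------------------
    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, cout, h, w = dy.shape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        self.dW += (dyf.T @ self._cols).reshape(self.W.shape)
        self.db += dyf.sum(axis=0)
        dcols = (dyf @ self.W.reshape(cout, -1)).reshape(n, h, w, -1, k, k)
        cin = self._xshape[1]
        dcols = dcols.reshape(n, h, w, cin, k, k)
        dxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x, train: bool = True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        return dy * self._mask


def avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


def upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_channels(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# encoder-decoder network
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    in_channels: int = 3
    n_classes: int = 5
    base_width: int = 8
    depth: int = 3                 # number of resolution levels
    head: str = "sigmoid"          # 'sigmoid' (one-vs-rest) or 'softmax'
    aux_head: bool = True          # deep supervision at half resolution
    aux_weight: float = 0.4
    head_bias: float = -2.0        # prior bias of sigmoid heads: rare-foreground
                                   # init so the focal weighting sees a low
                                   # background probability from step one
    dtype: str = "float32"

    def to_dict(self):
        return dict(self.__dict__)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


class EncoderDecoder:
    """Compact U-shaped FCN with transition blocks and deep supervision.

    Encoder: one 3x3 conv + ReLU per level (two at the bottom), widths
    ``base_width * 2**level``; between levels a transition block
    (1x1 conv + 2x2 average pool).  Decoder: nearest x2 upsampling, skip
    concatenation, 3x3 conv + ReLU.  Heads are 1x1 convolutions; the main
    head sits at full resolution, the auxiliary head (training only) on the
    half-resolution decoder features with loss weight ``aux_weight``.
    """

    def __init__(self, cfg: NetConfig, seed: int = 0):
        if cfg.depth < 2:
            raise ValueError("depth must be >= 2")
        if cfg.head not in ("sigmoid", "softmax"):
            raise ValueError("head must be 'sigmoid' or 'softmax'")
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(seed)
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth)]
        self.widths = widths

        self.enc = []
        cin = cfg.in_channels
        for i, wdt in enumerate(widths):
            convs = [Conv2D(cin, wdt, 3, rng, dtype)]
            if i == cfg.depth - 1:
                convs.append(Conv2D(wdt, wdt, 3, rng, dtype))
            self.enc.append(convs)
            cin = wdt
        # transition blocks (1x1 conv before each downsample)
        self.trans = [Conv2D(widths[i], widths[i], 1, rng, dtype)
                      for i in range(cfg.depth - 1)]
        # decoder convs, from bottom-1 up to level 0
        self.dec = []
        cin = widths[-1]
        for i in range(cfg.depth - 2, -1, -1):
            self.dec.append(Conv2D(cin + widths[i], widths[i], 3, rng, dtype))
            cin = widths[i]
        self.head = Conv2D(widths[0], cfg.n_classes, 1, rng, dtype)
        # deep-supervision head at half resolution: on the half-res decoder
        # features for depth >= 3, on the bottom encoder features for depth 2
        self._aux_site = "dec" if cfg.depth >= 3 else "bottom"
        aux_cin = widths[1] if cfg.depth >= 3 else widths[-1]
        self.aux = Conv2D(aux_cin, cfg.n_classes, 1, rng, dtype) if cfg.aux_head else None
        if cfg.head == "sigmoid":
            self.head.b[...] = cfg.head_bias
            if self.aux is not None:
                self.aux.b[...] = cfg.head_bias
        self.relu_enc = [[ReLU() for _ in lvl] for lvl in self.enc]
        self.relu_dec = [ReLU() for _ in self.dec]

    # -- parameter plumbing --------------------------------------------------
    def layers(self):
        out = []
        for lvl in self.enc:
            out.extend(lvl)
        out.extend(self.trans)
        out.extend(self.dec)
        out.append(self.head)
        if self.aux is not None:
            out.append(self.aux)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers() for p, _ in layer.params())

    def zero_grad(self):
        for layer in self.layers():
            for _, g in layer.params():
                g[...] = 0.0

    # -- forward -------------------------------------------------------------
    def _pad_to_multiple(self, x: np.ndarray):
        m = 2 ** (self.cfg.depth - 1)
        n, c, h, w = x.shape
        ph = (-h) % m
        pw = (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (h, w)

    def forward(self, x: np.ndarray, train: bool = True):
        """Return (main probability maps, aux probability maps or None).

        Input sizes not divisible by 2**(depth-1) are reflect-padded
        internally and the output cropped back.
        """
        x = x.astype(self.cfg.dtype, copy=False)
        x, (h0, w0) = self._pad_to_multiple(x)
        self._pad_hw = (h0, w0)
        skips = []
        for i, convs in enumerate(self.enc):
            for conv, relu in zip(convs, self.relu_enc[i]):
                x = relu.forward(conv.forward(x, train), train)
            if i < self.cfg.depth - 1:
                skips.append(x)
                x = avgpool2(self.trans[i].forward(x, train))
        aux_prob = None
        if self.aux is not None and self._aux_site == "bottom":
            aux_prob = self._apply_head(self.aux, x, train)
        self._concat_splits = []
        for j, conv in enumerate(self.dec):
            x = upsample2(x)
            skip = skips[-(j + 1)]
            self._concat_splits.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = self.relu_dec[j].forward(conv.forward(x, train), train)
            if (self.aux is not None and self._aux_site == "dec"
                    and j == len(self.dec) - 2):
                aux_prob = self._apply_head(self.aux, x, train)
        z = self.head.forward(x, train)
        prob = self._activate(z)
        if train:
            self._main_prob = prob
            self._aux_prob = aux_prob
        prob_out = prob[:, :, :h0, :w0]
        aux_out = aux_prob  # aux stays at its own (half) resolution
        return prob_out, aux_out

    def _apply_head(self, head: Conv2D, x: np.ndarray, train: bool):
        return self._activate(head.forward(x, train))

    def _activate(self, z: np.ndarray) -> np.ndarray:
        return sigmoid(z) if self.cfg.head == "sigmoid" else softmax_channels(z)

    def predict(self, image_chw: np.ndarray) -> np.ndarray:
        """Inference on a single CHW image; returns (n_classes, H, W) maps."""
        prob, _ = self.forward(image_chw[None], train=False)
        return prob[0]

    # -- backward ------------------------------------------------------------
    def backward(self, dprob: np.ndarray, daux: np.ndarray | None = None):
        """Backprop given dL/d(prob maps) at cropped size (and aux size)."""
        h0, w0 = self._pad_hw
        full = self._main_prob
        dp = np.zeros_like(full)
        dp[:, :, :h0, :w0] = dprob
        dz = self._dactivation(full, dp)
        dx = self.head.backward(dz)
        self._dskips = {}
        for j in range(len(self.dec) - 1, -1, -1):
            if (self.aux is not None and self._aux_site == "dec"
                    and j == len(self.dec) - 2 and daux is not None):
                dza = self._dactivation(self._aux_prob, daux.astype(dx.dtype))
                dx = dx + self.aux.backward(dza)
            dx = self.relu_dec[j].backward(dx)
            dx = self.dec[j].backward(dx)
            split = self._concat_splits[j]
            dx, dskip = dx[:, :split], dx[:, split:]
            dx = upsample2_backward(dx)
            self._dskips[len(self.dec) - 1 - j] = dskip
        if (self.aux is not None and self._aux_site == "bottom"
                and daux is not None):
            dza = self._dactivation(self._aux_prob, daux.astype(dx.dtype))
            dx = dx + self.aux.backward(dza)
        for i in range(self.cfg.depth - 1, -1, -1):
            if i < self.cfg.depth - 1:
                dx = self.trans[i].backward(avgpool2_backward(dx))
                dx = dx + self._dskips[i]
            for conv, relu in zip(reversed(self.enc[i]), reversed(self.relu_enc[i])):
                dx = conv.backward(relu.backward(dx))
        self._dskips = {}
        return dx

    def _dactivation(self, prob, dprob):
        if self.cfg.head == "sigmoid":
            return dprob * prob * (1.0 - prob)
        s = (dprob * prob).sum(axis=1, keepdims=True)
        return prob * (dprob - s)

    # -- persistence ---------------------------------------------------------
    def state_arrays(self):
        out = {}
        for i, layer in enumerate(self.layers()):
            out[f"W{i}"] = layer.W
            out[f"b{i}"] = layer.b
        return out

    def save(self, path: str | Path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = dict(self.cfg.to_dict())
        meta["config_hash"] = self.cfg.hash()
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "EncoderDecoder":
        data = np.load(Path(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta.pop("config_hash", None)
        net = cls(NetConfig(**meta))
        for i, layer in enumerate(net.layers()):
            layer.W[...] = data[f"W{i}"]
            layer.b[...] = data[f"b{i}"]
        return net


class MomentumSGD:
    """Classic momentum optimizer (v = m*v - lr*g; w += v)."""

    def __init__(self, net: EncoderDecoder, lr: float = 0.001,
                 momentum: float = 0.9):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self.v = [np.zeros_like(p) for layer in net.layers()
                  for p, _ in layer.params()]

    def step(self):
        i = 0
        for layer in self.net.layers():
            for p, g in layer.params():
                self.v[i] = self.momentum * self.v[i] - self.lr * g
                p += self.v[i]
                i += 1
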