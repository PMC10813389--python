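"""NumPy U-Net pixel classifier (two classes: cell-center disk vs background).

Same-padding architecture: ``depth`` encoder levels (two 3x3 conv + ReLU each,
2x2 max-pool between levels), a bottleneck level, and a symmetric expanding
path (nearest-neighbour upsampling followed by a 2x2 convolution, skip
concatenation, two 3x3 conv + ReLU), closed by a 1x1 convolution to 2 classes.
Output spatial size equals input size for inputs divisible by 2**depth;
``predict_proba`` pads/crops automatically for arbitrary sizes.

Implemented directly on NumPy (im2col convolutions, manual backprop, Adam);
no deep-learning framework is available in the target environment. Gradients
are verified against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_channels: int = 16
    in_channels: int = 1
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("in_channels >= 1 and n_classes >= 2 required")

    @property
    def down_factor(self) -> int:
        return 2 ** self.depth


@dataclass
class ProbabilityMap:
    """Per-pixel two-class posterior; ``probs`` has shape (H, W, 2)."""

    probs: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if p.ndim != 3 or p.shape[-1] < 2:
            raise ValueError("probs must be H x W x n_classes")
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ValueError("probabilities out of [0, 1]")
        if np.abs(p.sum(axis=-1) - 1.0).max() > 1e-5:
            raise ValueError("per-pixel probabilities must sum to 1")

    @property
    def foreground(self) -> np.ndarray:
        return self.probs[..., 1]


@dataclass
class LabelMask:
    """Binary training target: union of disks stamped at annotated centers."""

    mask: np.ndarray
    disk_radius_px: int


def rasterize_labels(
    centers: np.ndarray, shape: tuple[int, int], disk_radius_px: int = 3
) -> LabelMask:
    """Stamp a disk of radius ``disk_radius_px`` (dx^2+dy^2 <= r^2) at each center."""
    if disk_radius_px < 1:
        raise ValueError("disk_radius_px must be >= 1")
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 2)
    r = int(disk_radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (dx * dx + dy * dy) <= r * r
    offs = np.column_stack([dx[disk], dy[disk]])  # (k, 2) as (dx, dy)
    for x, y in centers:
        cx, cy = int(round(x)), int(round(y))
        xs = cx + offs[:, 0]
        ys = cy + offs[:, 1]
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        mask[ys[ok], xs[ok]] = 1
    return LabelMask(mask=mask, disk_radius_px=r)


# ---------------------------------------------------------------------------
# primitive layers (functional, explicit caches)


def _same_pad(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


def conv_forward(x, W, b):
    """x: (N,C,H,W); W: (Cout,Cin,kh,kw); same padding. Returns out, cache."""
    n, c, h, w = x.shape
    cout, cin, kh, kw = W.shape
    pt, pb = _same_pad(kh)
    pl, pr = _same_pad(kw)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * kh * kw
    )
    out = cols @ W.reshape(cout, -1).T + b
    out = out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), (cols, x.shape, W.shape)


def conv_backward(dout, W, cache):
    cols, x_shape, w_shape = cache
    n, c, h, w = x_shape
    cout, cin, kh, kw = w_shape
    dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, cout)
    dW = (dflat.T @ cols).reshape(w_shape)
    db = dflat.sum(axis=0)
    dcols = dflat @ W.reshape(cout, -1)
    dcols = dcols.reshape(n, h, w, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    pt, pb = _same_pad(kh)
    pl, pr = _same_pad(kw)
    dxp = np.zeros((n, c, h + pt + pb, w + pl + pr), dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
    dx = dxp[:, :, pt : pt + h, pl : pl + w]
    return dx, dW, db


def relu_forward(x):
    out = np.maximum(x, 0)
    return out, x > 0


def relu_backward(dout, mask):
    return dout * mask


def maxpool2_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout, cache):
    idx, x_shape = cache
    n, c, h, w = x_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx.reshape(n, c, h, w))


def upsample2_forward(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_channels(logits):
    """Stable softmax over axis 1 of (N, K, H, W)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model


class UNet:
    """Two-class U-Net; parameters live in ``self.params`` (name -> ndarray)."""

    def __init__(self, cfg: UNetConfig, dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self._build(np.random.default_rng(cfg.seed))

    # layer bookkeeping -----------------------------------------------------
    def _add_conv(self, rng, name: str, cin: int, cout: int, k: int) -> None:
        std = np.sqrt(2.0 / (cin * k * k))
        self.params[f"{name}_W"] = rng.normal(0, std, size=(cout, cin, k, k)).astype(self.dtype)
        self.params[f"{name}_b"] = np.zeros(cout, dtype=self.dtype)

    def _build(self, rng) -> None:
        cfg = self.cfg
        chans = [cfg.base_channels * 2 ** i for i in range(cfg.depth + 1)]
        cin = cfg.in_channels
        for i, c in enumerate(chans[:-1]):
            self._add_conv(rng, f"enc{i}_1", cin, c, 3)
            self._add_conv(rng, f"enc{i}_2", c, c, 3)
            cin = c
        self._add_conv(rng, "bot_1", chans[-2], chans[-1], 3)
        self._add_conv(rng, "bot_2", chans[-1], chans[-1], 3)
        for i in reversed(range(cfg.depth)):
            self._add_conv(rng, f"up{i}", chans[i + 1], chans[i], 2)
            self._add_conv(rng, f"dec{i}_1", 2 * chans[i], chans[i], 3)
            self._add_conv(rng, f"dec{i}_2", chans[i], chans[i], 3)
        self._add_conv(rng, "final", chans[0], cfg.n_classes, 1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # forward / backward ----------------------------------------------------
    def _conv_relu(self, x, name, caches):
        h, cc = conv_forward(x, self.params[f"{name}_W"], self.params[f"{name}_b"])
        h, rc = relu_forward(h)
        caches[name] = (cc, rc)
        return h

    def forward(self, x, caches=None):
        """x: (N, in_channels, H, W) with H, W divisible by 2**depth -> logits."""
        x = np.asarray(x, dtype=self.dtype)
        d = self.cfg.depth
        if x.shape[2] % 2 ** d or x.shape[3] % 2 ** d:
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by {2 ** d}")
        record = caches is not None
        caches = caches if record else {}
        skips = []
        h = x
        for i in range(d):
            h = self._conv_relu(h, f"enc{i}_1", caches)
            h = self._conv_relu(h, f"enc{i}_2", caches)
            skips.append(h)
            h, pc = maxpool2_forward(h)
            caches[f"pool{i}"] = pc
        h = self._conv_relu(h, "bot_1", caches)
        h = self._conv_relu(h, "bot_2", caches)
        for i in reversed(range(d)):
            h = upsample2_forward(h)
            h = self._conv_relu(h, f"up{i}", caches)
            caches[f"skipdim{i}"] = (skips[i].shape[1], h.shape[1])
            h = np.concatenate([skips[i], h], axis=1)
            h = self._conv_relu(h, f"dec{i}_1", caches)
            h = self._conv_relu(h, f"dec{i}_2", caches)
        logits, fc = conv_forward(h, self.params["final_W"], self.params["final_b"])
        caches["final"] = fc
        return logits

    def _backward_conv_relu(self, dh, name, caches, grads):
        cc, rc = caches[name]
        dh = relu_backward(dh, rc)
        dx, dW, db = conv_backward(dh, self.params[f"{name}_W"], cc)
        grads[f"{name}_W"] = dW
        grads[f"{name}_b"] = db
        return dx

    def backward(self, dlogits, caches):
        """Gradient of the scalar loss w.r.t. all parameters; returns grads dict."""
        grads: dict[str, np.ndarray] = {}
        d = self.cfg.depth
        dh, dW, db = conv_backward(dlogits, self.params["final_W"], caches["final"])
        grads["final_W"] = dW
        grads["final_b"] = db
        dskips = {}
        for i in range(d):
            dh = self._backward_conv_relu(dh, f"dec{i}_2", caches, grads)
            dh = self._backward_conv_relu(dh, f"dec{i}_1", caches, grads)
            n_skip, _ = caches[f"skipdim{i}"]
            dskips[i] = dh[:, :n_skip]
            dh = dh[:, n_skip:]
            dh = self._backward_conv_relu(dh, f"up{i}", caches, grads)
            dh = upsample2_backward(dh)
        dh = self._backward_conv_relu(dh, "bot_2", caches, grads)
        dh = self._backward_conv_relu(dh, "bot_1", caches, grads)
        for i in reversed(range(d)):
            dh = maxpool2_backward(dh, caches[f"pool{i}"])
            dh = dh + dskips[i]
            dh = self._backward_conv_relu(dh, f"enc{i}_2", caches, grads)
            dh = self._backward_conv_relu(dh, f"enc{i}_1", caches, grads)
        return grads

    # loss ------------------------------------------------------------------
    def loss_and_grads(self, x, labels, class_weights=(1.0, 1.0)):
        """Weighted pixelwise cross-entropy; labels: (N, H, W) ints in [0, K)."""
        caches: dict = {}
        logits = self.forward(x, caches)
        loss, dlogits = cross_entropy(logits, labels, class_weights)
        grads = self.backward(dlogits.astype(self.dtype), caches)
        return loss, grads

    def loss(self, x, labels, class_weights=(1.0, 1.0)) -> float:
        logits = self.forward(x)
        loss, _ = cross_entropy(logits, labels, class_weights)
        return loss

    # inference -------------------------------------------------------------
    def predict_proba(self, pixels: np.ndarray, image_id: str = "") -> ProbabilityMap:
        """Full-image posterior for a 2-D [0, 255] image of arbitrary size."""
        img = np.asarray(pixels, dtype=self.dtype) / 255.0
        h, w = img.shape
        f = self.cfg.down_factor
        ph = (-h) % f
        pw = (-w) % f
        if ph or pw:
            img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
        logits = self.forward(img[None, None])
        probs = softmax_channels(logits)[0, :, :h, :w].transpose(1, 2, 0)
        return ProbabilityMap(probs=np.asarray(probs, dtype=np.float64), image_id=image_id)

    # (de)serialization -----------------------------------------------------
    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=self.dtype).copy()

    def save(self, path: str | Path) -> None:
        meta = json.dumps(asdict(self.cfg))
        np.savez(Path(path), __config__=np.asarray(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        with np.load(Path(path)) as data:
            cfg = UNetConfig(**json.loads(str(data["__config__"])))
            model = cls(cfg)
            model.set_params({k: data[k] for k in data.files if k != "__config__"})
        return model


def cross_entropy(logits, labels, class_weights=(1.0, 1.0)):
    """Weighted softmax cross-entropy averaged over pixels.

    Returns (loss, dloss/dlogits). The loss is normalized by the total pixel
    weight so the scale is stable under class reweighting.
    """
    labels = np.asarray(labels)
    n, k, h, w = logits.shape
    probs = softmax_channels(np.asarray(logits, dtype=np.float64))
    wvec = np.asarray(class_weights, dtype=np.float64)
    if wvec.shape != (k,):
        raise ValueError(f"class_weights must have length {k}")
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    pix_w = wvec[labels]  # (N, H, W)
    total_w = pix_w.sum()
    logp = np.log(np.clip(np.take_along_axis(probs, labels[:, None], axis=1)[:, 0], 1e-12, None))
    loss = float(-(pix_w * logp).sum() / total_w)
    dlogits = (probs - onehot) * pix_w[:, None] / total_w
    return loss, dlogits


class Adam:
    """Plain Adam over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for k, g in grads.items():
            g = np.asarray(g, dtype=np.float64)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = self.lr * (self.m[k] / bias1) / (np.sqrt(self.v[k] / bias2) + self.eps)
            params[k] = (params[k] - update).astype(params[k].dtype)


def build_model(cfg: UNetConfig) -> UNet:
    """Construct a randomly initialized model from its config."""
    return UNet(cfg)
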