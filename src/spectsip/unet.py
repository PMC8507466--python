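"""Small 3D U-net for sinogram inpainting, in pure numpy.

The network maps a packed projection cube (the sparse views replicated into
a (side, side, angle_slots) tensor, see :func:`spectsip.sips.pack_input`)
to a tensor of the same shape whose slots at one synthetic index set are
trained to match the held-out views. Three independent networks — one per
synthetic set — are trained with an L2 loss evaluated only on that set's
angle slots.

Architecture: an encoder of ``depth`` levels (3D convolution + ReLU, 2x max
pooling, feature channels doubling from ``base_channels``), a bottleneck
convolution doubling once more, and a mirrored decoder (2x transposed
convolution + ReLU halving the channels, skip concatenation with the
matching encoder level, convolution + ReLU), closed by a linear 1-channel
convolution. Forward and backward passes are written out explicitly
(im2col-style einsums) and optimized with Adam; everything is seeded, so
training is bit-reproducible.

This is deliberately a desk-scale model: at 32-voxel sides and a handful of
base channels it trains on a laptop-class CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import ValidationError


@dataclass
class NetworkConfig:
    input_side: int = 128
    angle_slots: int = 128
    depth: int = 3
    base_channels: int = 16
    kernel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ValidationError("kernel must be odd and >= 1")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        f = 2**self.depth
        if self.input_side % f or self.angle_slots % f:
            raise ValidationError(
                f"input dimensions must be divisible by 2^depth = {f}"
            )


@dataclass
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss: str = "L2"  # {"L2", "L1"}
    seed: int = 0
    val_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValidationError("val_fraction must be in (0, 1)")
        if self.loss not in ("L2", "L1"):
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be non-negative")


# ---------------------------------------------------------------------------
# layers: each holds params, caches the forward pass, returns input grads
# ---------------------------------------------------------------------------


class Conv3d:
    """Same-padded 3D convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        self._win = win
        self._xshape = x.shape
        return (
            np.einsum("oiabc,idhwabc->odhw", self.W, win, optimize=True)
            + self.b[:, None, None, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        self.dW = np.einsum("odhw,idhwabc->oiabc", dy, self._win, optimize=True)
        self.db = dy.sum(axis=(1, 2, 3))
        c_in, D, H, W_ = self._xshape
        dxp = np.zeros((c_in, D + 2 * p, H + 2 * p, W_ + 2 * p))
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    dxp[:, a : a + D, b : b + H, c : c + W_] += np.einsum(
                        "oi,odhw->idhw", self.W[:, :, a, b, c], dy, optimize=True
                    )
        self._win = None
        return dxp[:, p : p + D, p : p + H, p : p + W_] if p else dxp

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ConvTranspose3d:
    """Stride-2, kernel-2 transposed convolution (2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 8
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, 2, 2, 2))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        t = np.einsum("ioabc,idhw->odahbwc", self.W, x, optimize=True)
        c_out = self.W.shape[1]
        _, D, H, W_ = x.shape
        return t.reshape(c_out, 2 * D, 2 * H, 2 * W_) + self.b[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out = self.W.shape[1]
        _, D, H, W_ = self._x.shape
        t = dy.reshape(c_out, D, 2, H, 2, W_, 2)  # odahbwc ordering
        self.dW = np.einsum("idhw,odahbwc->ioabc", self._x, t, optimize=True)
        self.db = dy.sum(axis=(1, 2, 3))
        dx = np.einsum("ioabc,odahbwc->idhw", self.W, t, optimize=True)
        self._x = None
        return dx

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class MaxPool3d:
    """2x2x2 max pooling; ties break toward the first (lowest-offset) voxel."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, D, H, W_ = x.shape
        r = x.reshape(C, D // 2, 2, H // 2, 2, W_ // 2, 2)
        flat = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(C, D // 2, H // 2, W_ // 2, 8)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, D, H, W_ = self._shape
        flat = np.zeros((C, D // 2, H // 2, W_ // 2, 8))
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        out = (
            flat.reshape(C, D // 2, H // 2, W_ // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(C, D, H, W_)
        )
        self._arg = None
        return out

    def params(self):
        return []


class UNet3D:
    """Encoder-decoder with skip connections; see the module docstring."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        ch = [config.base_channels * 2**l for l in range(config.depth)]
        self.encoder_channels = list(ch)
        self.bottleneck_channels = config.base_channels * 2**config.depth
        self.decoder_channels = list(reversed(ch))

        self.enc_convs, self.enc_relus, self.pools = [], [], []
        c_prev = 1
        for c in ch:
            self.enc_convs.append(Conv3d(c_prev, c, k, rng))
            self.enc_relus.append(ReLU())
            self.pools.append(MaxPool3d())
            c_prev = c
        self.bottleneck = Conv3d(c_prev, self.bottleneck_channels, k, rng)
        self.bottleneck_relu = ReLU()

        self.ups, self.up_relus, self.dec_convs, self.dec_relus = [], [], [], []
        c_prev = self.bottleneck_channels
        for c in self.decoder_channels:
            self.ups.append(ConvTranspose3d(c_prev, c, rng))
            self.up_relus.append(ReLU())
            self.dec_convs.append(Conv3d(2 * c, c, k, rng))  # after skip concat
            self.dec_relus.append(ReLU())
            c_prev = c
        self.head = Conv3d(c_prev, 1, k, rng)

    # -- plumbing -----------------------------------------------------------

    def _layers(self):
        for conv, relu in zip(self.enc_convs, self.enc_relus):
            yield conv
            yield relu
        yield self.bottleneck
        yield self.bottleneck_relu
        for up, ur, conv, relu in zip(
            self.ups, self.up_relus, self.dec_convs, self.dec_relus
        ):
            yield up
            yield ur
            yield conv
            yield relu
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            for name, arr, gname in layer.params():
                out.append((layer, name, gname))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(layer, name).copy() for layer, name, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name, _), w in zip(self.parameters(), weights):
            setattr(layer, name, w.copy())

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (side, side, angle_slots) -> same-shape output."""
        h = x[None]  # channel axis
        self._skips = []
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            h = relu.forward(conv.forward(h))
            self._skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck_relu.forward(self.bottleneck.forward(h))
        for up, ur, conv, relu, skip in zip(
            self.ups, self.up_relus, self.dec_convs, self.dec_relus,
            reversed(self._skips),
        ):
            h = ur.forward(up.forward(h))
            h = np.concatenate([skip, h], axis=0)
            h = relu.forward(conv.forward(h))
        out = self.head.forward(h)
        return out[0]

    def backward(self, dout: np.ndarray) -> None:
        dh = self.head.backward(dout[None])
        dskips = [None] * len(self._skips)
        for i in range(len(self.ups) - 1, -1, -1):
            dh = self.dec_convs[i].backward(self.dec_relus[i].backward(dh))
            c_skip = self._skips[len(self._skips) - 1 - i].shape[0]
            dskip, dh = dh[:c_skip], dh[c_skip:]
            dskips[len(self._skips) - 1 - i] = dskip
            dh = self.ups[i].backward(self.up_relus[i].backward(dh))
        dh = self.bottleneck.backward(self.bottleneck_relu.backward(dh))
        for i in range(len(self.enc_convs) - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc_convs[i].backward(self.enc_relus[i].backward(dh))
        self._skips = None


def build_network(config: NetworkConfig) -> UNet3D:
    """Construct a seeded U-net; identical seeds give identical parameters."""
    return UNet3D(config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, model: UNet3D, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, n)) for l, n, _ in model.parameters()]
        self.v = [np.zeros_like(getattr(l, n)) for l, n, _ in model.parameters()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (layer, name, gname) in enumerate(self.model.parameters()):
            g = getattr(layer, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            getattr(layer, name)[...] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def masked_loss_and_grad(
    pred: np.ndarray, target_slots: np.ndarray, slot_idx: np.ndarray, loss: str
) -> tuple[float, np.ndarray]:
    """Loss over the target angle slots only; gradient w.r.t. the full output.

    ``target_slots`` is (n_slots, side, side) matching ``slot_idx`` (0-based
    slot positions along the last tensor axis).
    """
    sel = pred[:, :, slot_idx]  # (side, side, n)
    tgt = target_slots.transpose(1, 2, 0)
    diff = sel - tgt
    n = diff.size
    grad = np.zeros_like(pred)
    if loss == "L2":
        value = float(np.mean(diff**2))
        grad[:, :, slot_idx] = 2.0 * diff / n
    else:
        value = float(np.mean(np.abs(diff)))
        grad[:, :, slot_idx] = np.sign(diff) / n
    return value, grad


def train_sip_network(
    model: UNet3D,
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    tc: TrainingConfig,
) -> tuple[UNet3D, list[float]]:
    """Train one SIP network on (input cube, target slots, slot indices) triples.

    Returns the model (updated in place) and the per-epoch mean training
    loss history. Mini-batch gradients are averaged over the batch;
    shuffling and optimization are fully seeded.
    """
    if not dataset:
        raise ValidationError("empty training dataset")
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model, tc.learning_rate)
    history: list[float] = []
    n = len(dataset)
    for _epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            batch = order[start : start + tc.batch_size]
            grads_accum = None
            for j in batch:
                x, tgt, slot_idx = dataset[j]
                pred = model.forward(x)
                value, dout = masked_loss_and_grad(pred, tgt, slot_idx, tc.loss)
                losses.append(value)
                model.backward(dout / len(batch))
                g = [getattr(l, gn).copy() for l, _, gn in model.parameters()]
                grads_accum = g if grads_accum is None else [
                    a + b for a, b in zip(grads_accum, g)
                ]
            for (layer, _, gname), g in zip(model.parameters(), grads_accum):
                setattr(layer, gname, g)
            opt.step()
        history.append(float(np.mean(losses)))
    return model, history


def evaluate_loss(
    model: UNet3D,
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    loss: str = "L2",
) -> float:
    vals = [
        masked_loss_and_grad(model.forward(x), tgt, idx, loss)[0]
        for x, tgt, idx in dataset
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# checkpointing: npz with an embedded JSON header
# ---------------------------------------------------------------------------


def save_checkpoint(path: str, model: UNet3D, extra: dict | None = None) -> None:
    header = {"network": asdict(model.config), **(extra or {})}
    arrays = {f"p{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str) -> tuple[UNet3D, dict]:
    data = np.load(path)
    header = json.loads(bytes(data["header"]).decode())
    model = build_network(NetworkConfig(**header["network"]))
    weights = [data[f"p{i}"] for i in range(len(model.get_weights()))]
    model.set_weights(weights)
    return model, header
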