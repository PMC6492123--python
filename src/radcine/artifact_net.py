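"""Spatio-temporal (2D+time) residual U-Net for deep artifact
suppression, with its training loop.

The network maps an artifact-contaminated magnitude cine to a clean
one.  It is a multi-scale encoder/decoder with a skip connection at
each scale; every convolution is 3x3x3 (isotropic across the two
spatial axes and time, so no direction is favoured) followed by a
ReLU, except the final layer which produces a residual update.  The
output is ReLU(input + residual), enforcing non-negativity of the
magnitude images.  Downsampling is 2x2x2 max-pooling, upsampling a
2x2x2 stride-2 transposed convolution.

Everything — convolutions (im2col), pooling, backpropagation, Adam —
is implemented directly on numpy arrays in float32.  Arrays are
channel-first (C, T, H, W); spatial/temporal extents must be divisible
by 2^(n_scales - 1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .phantom import CineVolume

__all__ = ["NetConfig", "ResidualUNet", "TrainedModel", "build_network",
           "train", "suppress"]

F32 = np.float32


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimization settings.

    ``epochs`` defaults to the benchmark (desk-scale) profile; the
    reference full-scale regime (350 epochs, batch 8, 3 scales with
    32/64/128 channels) is expressed by the same fields.
    """

    n_scales: int = 3
    base_channels: int = 32
    channel_growth: int = 2
    loss: str = "l2"
    lr: float = 1e-3
    batch: int = 8
    epochs: int = 30
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    zero_init_last: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.loss not in ("l1", "l2"):
            raise ValueError("loss must be 'l1' or 'l2'")

    @property
    def channels(self) -> Tuple[int, ...]:
        return tuple(self.base_channels * self.channel_growth ** i
                     for i in range(self.n_scales))


# --------------------------------------------------------------------
# layers


class _Conv3x3:
    """3x3x3 convolution, stride 1, zero padding 1, via im2col."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 zero_init: bool = False):
        fan_in = cin * 27
        std = np.sqrt(2.0 / fan_in)
        if zero_init:
            self.w = np.zeros((fan_in, cout), dtype=F32)
        else:
            self.w = rng.normal(0.0, std, (fan_in, cout)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.cin, self.cout = cin, cout
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        m = d * h * w
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        # column matrix in (C*27, DHW) orientation: 27 contiguous
        # shifted-slice copies instead of a strided 7-axis gather
        col = np.empty((c, 27, m), dtype=F32)
        for o, (i, j, k) in enumerate(np.ndindex(3, 3, 3)):
            col[:, o, :] = xp[:, i:i + d, j:j + h, k:k + w].reshape(c, m)
        self._col = col.reshape(c * 27, m)
        self._shape = (d, h, w)
        out = self.w.T @ self._col + self.b[:, None]
        return out.reshape(self.cout, d, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d, h, w = self._shape
        dflat = dout.reshape(self.cout, -1)
        self.gw += self._col @ dflat.T
        self.gb += dflat.sum(axis=1)
        dcol = (self.w @ dflat).reshape(self.cin, 27, d, h, w)
        dxp = np.zeros((self.cin, d + 2, h + 2, w + 2), dtype=F32)
        for o, (i, j, k) in enumerate(np.ndindex(3, 3, 3)):
            dxp[:, i:i + d, j:j + h, k:k + w] += dcol[:, o]
        self._col = None
        return dxp[:, 1:-1, 1:-1, 1:-1]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dout, F32(0.0))
        self._mask = None
        return out


class _MaxPool2:
    """Non-overlapping 2x2x2 max pooling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        r = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        r = r.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2,
                                                     w // 2, 8)
        self._arg = np.argmax(r, axis=-1)
        self._shape = (c, d, h, w)
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        r = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=F32)
        np.put_along_axis(r, self._arg[..., None], dout[..., None], axis=-1)
        r = r.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        r = r.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)
        self._arg = None
        return r


class _UpConv2:
    """2x2x2 stride-2 transposed convolution (non-overlapping blocks)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 8))
        self.w = rng.normal(0.0, std, (cin, cout, 2, 2, 2)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        c, d, h, w = x.shape
        out = np.einsum("cdhw,coijk->odihjwk", x, self.w, optimize=True)
        cout = self.w.shape[1]
        out = out.reshape(cout, 2 * d, 2 * h, 2 * w)
        return out + self.b[:, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d, h, w = self._x.shape
        cout = self.w.shape[1]
        dr = dout.reshape(cout, d, 2, h, 2, w, 2)
        self.gw += np.einsum("cdhw,odihjwk->coijk", self._x, dr,
                             optimize=True)
        self.gb += dout.sum(axis=(1, 2, 3))
        dx = np.einsum("odihjwk,coijk->cdhw", dr, self.w, optimize=True)
        self._x = None
        return dx


# --------------------------------------------------------------------
# network


class ResidualUNet:
    """Multi-scale residual U-Net; output = ReLU(input + residual)."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        self.enc: List[List] = []
        cin = 1
        for i, c in enumerate(ch):
            self.enc.append([_Conv3x3(cin, c, rng), _ReLU(),
                             _Conv3x3(c, c, rng), _ReLU()])
            cin = c
        self.pools = [_MaxPool2() for _ in range(cfg.n_scales - 1)]
        self.ups: List[_UpConv2] = []
        self.dec: List[List] = []
        for i in range(cfg.n_scales - 2, -1, -1):
            self.ups.append(_UpConv2(ch[i + 1], ch[i], rng))
            self.dec.append([_Conv3x3(2 * ch[i], ch[i], rng), _ReLU(),
                             _Conv3x3(ch[i], ch[i], rng), _ReLU()])
        self.final = _Conv3x3(ch[0], 1, rng, zero_init=cfg.zero_init_last)
        self.out_relu = _ReLU()

    # -- parameter plumbing -----------------------------------------
    def _layers_with_params(self):
        for blk in self.enc:
            yield blk[0]
            yield blk[2]
        for up in self.ups:
            yield up
        for blk in self.dec:
            yield blk[0]
            yield blk[2]
        yield self.final

    def parameters(self):
        for layer in self._layers_with_params():
            yield from layer.params()

    def zero_grad(self):
        for _, _, g in self.parameters():
            g[...] = 0.0

    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def state_arrays(self) -> List[np.ndarray]:
        return [p for _, p, _ in self.parameters()]

    # -- forward / backward -----------------------------------------
    def _check_shape(self, shape):
        div = 2 ** (self.cfg.n_scales - 1)
        if any(s % div for s in shape):
            raise ValueError(
                f"input extents {shape} must be divisible by {div} for "
                f"{self.cfg.n_scales} scales")

    def forward(self, vol: np.ndarray, train: bool = False) -> np.ndarray:
        """(T, H, W) in -> (T, H, W) out, non-negative."""
        vol = np.asarray(vol, dtype=F32)
        if vol.ndim != 3:
            raise ValueError("input must be a (frames, rows, cols) volume")
        self._check_shape(vol.shape)
        x = vol[None]  # (1, T, H, W)
        skips = []
        for i, blk in enumerate(self.enc):
            for layer in blk:
                x = layer.forward(x)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x)
        for j, (up, blk) in enumerate(zip(self.ups, self.dec)):
            x = up.forward(x)
            skip = skips[len(skips) - 1 - j]
            x = np.concatenate([skip, x], axis=0)
            for layer in blk:
                x = layer.forward(x)
        res = self.final.forward(x)
        out = self.out_relu.forward(vol[None] + res)
        return out[0]

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/d(output).

        Mirrors the forward wiring: decoder stage j (fine to coarse)
        splits its concat gradient into the skip branch (kept pending)
        and the up branch; the encoder walk then adds each pending
        skip gradient back in after its pooling layer.
        """
        ch = self.cfg.channels
        s = self.cfg.n_scales
        g = self.out_relu.backward(np.asarray(dout, dtype=F32)[None])
        g = self.final.backward(g)
        pending = {}
        for j in range(s - 2, -1, -1):
            for layer in reversed(self.dec[j]):
                g = layer.backward(g)
            i = s - 2 - j  # skip level consumed by decoder stage j
            g_skip, g = g[:ch[i]], g[ch[i]:]
            g = self.ups[j].backward(g)
            pending[i] = g_skip
        for i in range(s - 1, 0, -1):
            for layer in reversed(self.enc[i]):
                g = layer.backward(g)
            g = self.pools[i - 1].backward(g)
            g = g + pending[i - 1]
        for layer in reversed(self.enc[0]):
            g = layer.backward(g)


def build_network(cfg: NetConfig) -> ResidualUNet:
    """Construct the residual U-Net for a configuration."""
    return ResidualUNet(cfg)


# --------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for _, p, _ in self.params]
        self.v = [np.zeros_like(p) for _, p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    """A trained network plus the manifest identifying its run."""

    model: ResidualUNet
    net_config: NetConfig
    training_manifest: Dict = field(default_factory=dict)

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["net_config"] = json.dumps(asdict(self.net_config))
            f.attrs["manifest"] = json.dumps(self.training_manifest,
                                             default=float)
            for i, arr in enumerate(self.model.state_arrays()):
                f.create_dataset(f"p{i:03d}", data=arr)

    @classmethod
    def load_h5(cls, path) -> "TrainedModel":
        import h5py

        with h5py.File(path, "r") as f:
            cfg = NetConfig(**json.loads(f.attrs["net_config"]))
            manifest = json.loads(f.attrs["manifest"])
            model = build_network(cfg)
            for i, arr in enumerate(model.state_arrays()):
                arr[...] = f[f"p{i:03d}"][()]
        return cls(model, cfg, manifest)


def _dataset_checksum(pairs) -> str:
    h = hashlib.sha256()
    for truth, aliased in pairs:
        h.update(np.ascontiguousarray(truth.frames, dtype=F32).tobytes())
        h.update(np.ascontiguousarray(aliased.frames, dtype=F32).tobytes())
    return h.hexdigest()[:16]


def train(model: ResidualUNet, paired_dataset: Sequence,
          cfg: NetConfig) -> TrainedModel:
    """Optimize the network on (truth, aliased) CineVolume pairs.

    Minimizes the mean squared error (``loss='l2'``) or mean absolute
    error (``'l1'``) of the output against the ground truth with Adam.
    Deterministic given ``cfg.seed`` (numpy arithmetic, fixed shuffle
    stream); per-epoch mean loss is logged in the manifest.
    """
    if len(paired_dataset) == 0:
        raise ValueError("empty training dataset")
    vols = []
    for truth, aliased in paired_dataset:
        tf = np.asarray(truth.frames, dtype=F32)
        af = np.asarray(aliased.frames, dtype=F32)
        if tf.shape != af.shape:
            raise ValueError("paired volumes must have identical shapes")
        vols.append((tf, af))

    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.parameters(), cfg.lr, cfg.beta1, cfg.beta2, cfg.eps)
    epoch_losses = []
    n = len(vols)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            model.zero_grad()
            for i in idx:
                tf, af = vols[i]
                out = model.forward(af, train=True)
                diff = out - tf
                if cfg.loss == "l2":
                    losses.append(float(np.mean(diff ** 2)))
                    dout = (2.0 / diff.size) * diff
                else:
                    losses.append(float(np.mean(np.abs(diff))))
                    dout = np.sign(diff) / diff.size
                model.backward(dout / len(idx))
            opt.step()
        epoch_losses.append(float(np.mean(losses)))
    manifest = dict(dataset_checksum=_dataset_checksum(paired_dataset),
                    seed=cfg.seed, epochs_run=cfg.epochs,
                    n_pairs=n, epoch_losses=epoch_losses,
                    n_params=model.n_params())
    return TrainedModel(model, cfg, manifest)


def suppress(trained: TrainedModel, aliased: CineVolume) -> CineVolume:
    """Single forward pass: artifact-suppressed version of a prepared cine.

    The input must be a prepared volume (fixed frame count, square
    crop, [0, 1] intensities); shape problems raise.  Pure function of
    (weights, input): repeated calls are identical.
    """
    out = trained.model.forward(aliased.frames)
    return aliased.copy_with(np.asarray(out, dtype=float))
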