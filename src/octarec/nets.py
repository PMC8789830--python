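"""Two-stage reconstruction generator and the adversarial discriminator.

The generator maps an undersampled, two-repeat (LR, LQ) enface
angiogram to its fully-sampled, eight-repeat (HR, HQ) counterpart in
two stages run in series:

* **SR module** — pixel super-resolution.  A 9x9 convolution extracts
  low-level features, a *Deep layer* of 3x3 convolution blocks with
  PReLU activations (densely or residually connected) extracts
  high-level residuals, the two paths merge by element-wise summation,
  and pixel-shuffle stages upsample by the sampling ratio r (one x2
  shuffle per factor of two).
* **QE module** — quality enhancement at constant resolution: the same
  low-level / Deep-layer / summation pipeline without upsampling,
  closed by a 9x9 output convolution.

Both modules squash their output through a sigmoid, so predictions are
bounded in (0, 1) to match the data normalization while staying
differentiable everywhere (a hard clip permanently silences gradients
once a module saturates, which stalls training on dark angiograms).
The discriminator is a strided convolution stack with leaky-ReLU
activations and batch normalization, global average pooling and a
sigmoid output probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._autograd import Tensor, concat, no_grad
from .nn import Module, Conv2d, PReLU, BatchNorm2d

__all__ = ["NetConfig", "pixel_shuffle", "DeepLayer", "SRModule", "QEModule",
           "Generator", "Discriminator", "save_generator", "load_generator"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyper-parameters shared by the SR and QE modules."""

    connection: str = "dense"
    n_blocks: int = 5
    base_channels: int = 64
    outer_kernel: int = 9
    inner_kernel: int = 3
    upsample_ratio: int = 2

    def __post_init__(self):
        if self.connection not in ("dense", "residual"):
            raise ValueError("connection must be 'dense' or 'residual'")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        r = self.upsample_ratio
        if r < 1 or (r & (r - 1)):
            raise ValueError("upsample_ratio must be a power of 2")
        if self.outer_kernel % 2 == 0 or self.inner_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")


def pixel_shuffle(features: np.ndarray, s: int) -> np.ndarray:
    """Periodic sub-pixel rearrangement (C*s^2, H, W) -> (C, s*H, s*W).

    out[c, s*h + a, s*w + b] = in[c*s^2 + a*s + b, h, w]; bijective, so
    upsampling by shuffle moves information without interpolation.
    """
    features = np.asarray(features)
    if features.ndim != 3:
        raise ValueError("features must be (C, H, W)")
    c2, h, w = features.shape
    if c2 % (s * s):
        raise ValueError(f"channel count {c2} not divisible by s^2 = {s * s}")
    c = c2 // (s * s)
    return (features.reshape(c, s, s, h, w)
            .transpose(0, 3, 1, 4, 2).reshape(c, s * h, s * w))


class DeepLayer(Module):
    """Stack of 3x3 conv blocks with PReLU, densely or residually wired.

    Dense: block k consumes the channel-concatenation of the layer input
    and all previous block outputs; a final 1x1 fusion convolution
    restores ``channels``.  Residual: each block's output is added to its
    input.  Spatial shape is preserved either way.
    """

    def __init__(self, cfg: NetConfig, rng):
        c, k = cfg.base_channels, cfg.inner_kernel
        self.connection = cfg.connection
        self.convs = []
        self.acts = []
        for b in range(cfg.n_blocks):
            in_ch = c * (b + 1) if cfg.connection == "dense" else c
            self.convs.append(Conv2d(in_ch, c, k, rng))
            self.acts.append(PReLU(c))
        self.fusion = (Conv2d(c * (cfg.n_blocks + 1), c, 1, rng)
                       if cfg.connection == "dense" else None)

    def __call__(self, x: Tensor) -> Tensor:
        if self.connection == "residual":
            out = x
            for conv, act in zip(self.convs, self.acts):
                out = out + act(conv(out))
            return out
        feats = [x]
        for conv, act in zip(self.convs, self.acts):
            inp = feats[0] if len(feats) == 1 else concat(feats, axis=1)
            feats.append(act(conv(inp)))
        return self.fusion(concat(feats, axis=1))


class _UpsampleStage(Module):
    """Conv to 4x channels followed by a x2 pixel shuffle."""

    def __init__(self, channels: int, kernel: int, rng):
        self.conv = Conv2d(channels, 4 * channels, kernel, rng)
        self.act = PReLU(channels)

    def __call__(self, x: Tensor) -> Tensor:
        return self.act(self.conv(x).pixel_shuffle(2))


class SRModule(Module):
    """Pixel super-resolution by ratio ``cfg.upsample_ratio``."""

    def __init__(self, cfg: NetConfig, rng):
        c, ko = cfg.base_channels, cfg.outer_kernel
        self.cfg = cfg
        self.head = Conv2d(1, c, ko, rng)
        self.head_act = PReLU(c)
        self.deep = DeepLayer(cfg, rng)
        n_stages = int(np.log2(cfg.upsample_ratio))
        self.up = [_UpsampleStage(c, cfg.inner_kernel, rng)
                   for _ in range(n_stages)]
        self.tail = Conv2d(c, 1, ko, rng)
        # small-scale logit init keeps first predictions near mid-range
        self.tail.weight.data *= 0.1

    def __call__(self, x: Tensor) -> Tensor:
        low = self.head_act(self.head(x))
        feat = self.deep(low) + low
        for stage in self.up:
            feat = stage(feat)
        return self.tail(feat).sigmoid()


class QEModule(Module):
    """Quality enhancement at constant resolution."""

    def __init__(self, cfg: NetConfig, rng):
        c, ko = cfg.base_channels, cfg.outer_kernel
        self.cfg = cfg
        self.head = Conv2d(1, c, ko, rng)
        self.head_act = PReLU(c)
        self.deep = DeepLayer(cfg, rng)
        self.tail = Conv2d(c, 1, ko, rng)
        self.tail.weight.data *= 0.1

    def __call__(self, x: Tensor) -> Tensor:
        low = self.head_act(self.head(x))
        feat = self.deep(low) + low
        return self.tail(feat).sigmoid()


def _to_batch(img) -> tuple[Tensor, bool]:
    """Accept EnfaceImage / (H,W) / (N,H,W) / Tensor; return (N,1,H,W)."""
    if isinstance(img, Tensor):
        t = img
    else:
        pixels = getattr(img, "pixels", img)
        t = Tensor(np.asarray(pixels))  # coerced to the working dtype
    single = t.ndim == 2
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    elif t.ndim != 4:
        raise ValueError("expected a 2-D image or a batch of 2-D images")
    return t, single


class Generator(Module):
    """End-to-end reconstruction model: QE(SR(x))."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.sr = SRModule(cfg, rng)
        self.qe = QEModule(cfg, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.qe(self.sr(x))

    def _apply(self, module, img):
        t, single = _to_batch(img)
        with no_grad():
            out = module(t).data
        out = out[:, 0]
        return out[0] if single else out

    def sr_forward(self, img) -> np.ndarray:
        """Numpy convenience: (H, W) -> (r*H, r*W) in [0, 1]."""
        return self._apply(self.sr, img)

    def qe_forward(self, img) -> np.ndarray:
        """Numpy convenience: shape-preserving enhancement."""
        return self._apply(self.qe, img)

    def reconstruct(self, img) -> np.ndarray:
        """Numpy convenience: full (LR, LQ) -> (HR, HQ) mapping."""
        return self._apply(lambda t: self(t), img)


class Discriminator(Module):
    """Real-vs-reconstructed classifier for adversarial training.

    Strided 3x3 convolution stack; channels double at each stride-2
    stage from ``base_channels`` up to ``8 * base_channels``, each stage
    followed by batch normalization (except the first convolution) and
    leaky-ReLU.  Global average pooling and a 1x1 convolution produce a
    single sigmoid probability per image.
    """

    def __init__(self, base_channels: int = 64, seed: int = 0,
                 lrelu_slope: float = 0.2):
        rng = np.random.default_rng(seed)
        self.slope = lrelu_slope
        c = base_channels
        self.conv0 = Conv2d(1, c, 3, rng)
        self.convs, self.bns = [], []
        widths = [c, 2 * c, 4 * c, 8 * c]
        in_ch = c
        for w in widths:
            self.convs.append(Conv2d(in_ch, w, 3, rng, stride=2))
            self.bns.append(BatchNorm2d(w))
            in_ch = w
        self.head = Conv2d(in_ch, 1, 1, rng)

    def __call__(self, img) -> Tensor:
        t, _ = _to_batch(img)
        h = self.conv0(t).leaky_relu(self.slope)
        for conv, bn in zip(self.convs, self.bns):
            h = bn(conv(h)).leaky_relu(self.slope)
        pooled = h.mean(axis=2, keepdims=True).mean(axis=3, keepdims=True)
        logit = self.head(pooled)
        n = logit.shape[0]
        # keep probabilities strictly inside (0, 1) even when the sigmoid
        # saturates in floating point, so the log losses stay finite
        return logit.reshape(n).sigmoid().clip(1e-7, 1.0 - 1e-7)

    def predict(self, img) -> np.ndarray:
        """Probabilities in evaluation mode, without recording a graph."""
        self.eval()
        with no_grad():
            out = self(img).data
        self.train()
        return out


def save_generator(G: Generator, path) -> None:
    """Checkpoint: config JSON plus all parameter arrays in one .npz."""
    arrays = {f"arr_{i}": a for i, a in enumerate(G.state_arrays())}
    np.savez(path, config=json.dumps(asdict(G.cfg)), **arrays)


def load_generator(path) -> Generator:
    with np.load(path, allow_pickle=False) as data:
        cfg = NetConfig(**json.loads(str(data["config"])))
        G = Generator(cfg)
        n = len([k for k in data.files if k.startswith("arr_")])
        G.load_state_arrays([data[f"arr_{i}"] for i in range(n)])
    return G
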