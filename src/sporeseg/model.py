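"""The spore-UNet segmentation network.

A four-level encoder-decoder UNet for brightfield images of bacterial
spores and outgrowing vegetative cells.  Each encoder level applies a
double 3x3 convolution (doubling the channel count) followed by 2x2 max
pooling; each decoder level bilinearly upsamples, concatenates the
corresponding encoder feature through an attention-gated skip
connection, and applies a double convolution that halves the channels.
A final 1x1 convolution produces a single-channel logit map.

Attention is applied to skip features only - the main encoder stream is
left untouched so full image detail reaches the bottleneck.  Two blocks
act on each skip: an optional squeeze-excitation channel attention and
the spatial attention gate, which combines the encoder feature ``x``
with a coarser decoder gating signal ``g``::

    theta_x = Conv2x2, stride 2 (x)          -> H/2 x W/2 x C_int
    phi_g   = Conv1x1 (g), upsampled to theta_x's size
    f       = ReLU(theta_x + phi_g)
    psi     = sigmoid(Conv1x1(f))            -> H/2 x W/2 x 1
    F_s     = x * Repeat(Upsample(psi), C_x)

followed by a 1x1 convolution and batch normalization restoring the
original channel count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .io_annotation import BinaryMask, GrayImage

__all__ = [
    "ModelConfig",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "DoubleConv",
    "ChannelAttention",
    "SpatialAttentionGate",
    "SporeUNet",
    "build_model",
    "predict_mask",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``inter_channels_ratio`` sets the attention gate's internal width
    C_int as a fraction of the gated skip's channel count (C_int =
    C_x / 2 by default).  ``input_size`` must be divisible by
    ``2**depth`` so the spatial dimensions survive the pooling ladder.
    """

    depth: int = 4
    base_channels: int = 64
    inter_channels_ratio: float = 0.5
    input_size: tuple[int, int] = (256, 256)
    output_channels: int = 1
    channel_attention: bool = True
    spatial_attention: bool = True

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")
        h, w = self.input_size
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )


class Module:
    """Minimal layer container with recursive parameter discovery."""

    training: bool = True

    def children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self) -> list[Tensor]:
        out = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    out.append(v)
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, v in self.__dict__.items():
            if name.startswith("last_"):
                continue  # cached activations, not state
            key = prefix + name
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_dict(key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{key}.{i}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, v in self.__dict__.items():
            if name.startswith("last_"):
                continue
            key = prefix + name
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[key]).astype(v.data.dtype).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state_dict(state, key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Tensor(
            (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum,
        )


class DoubleConv(Module):
    """Two 3x3 same-padding convolutions, each with batch norm + ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, pad=1, dtype=dtype)
        self.bn1 = BatchNorm2d(out_ch, dtype=dtype)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, pad=1, dtype=dtype)
        self.bn2 = BatchNorm2d(out_ch, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.relu(self.bn1(self.conv1(x)))
        return ag.relu(self.bn2(self.conv2(x)))


class ChannelAttention(Module):
    """Squeeze-excitation channel reweighting of a skip feature."""

    def __init__(self, channels: int, rng, reduction: int = 8, dtype=np.float32):
        mid = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, mid, 1, rng, dtype=dtype)
        self.fc2 = Conv2d(mid, channels, 1, rng, dtype=dtype)
        self.force_identity = False

    def forward(self, x: Tensor) -> Tensor:
        if self.force_identity:
            return x
        w = ag.sigmoid(self.fc2(ag.relu(self.fc1(ag.global_avg_pool(x)))))
        return ag.mul(x, w)


class SpatialAttentionGate(Module):
    """Spatial attention over a skip connection.

    ``x`` is the encoder feature (H x W x C_x) and ``g`` the decoder
    gating signal at half resolution.  The attention map psi lies in
    (0, 1) everywhere (sigmoid codomain); the gated output has exactly
    the shape of ``x`` so the gate is a drop-in on the skip path.

    Diagnostics: after a forward pass, ``last_psi`` holds the attention
    map and ``last_gated`` the pre-normalization gated product.
    """

    def __init__(self, c_x: int, c_g: int, c_int: int, rng, dtype=np.float32):
        self.theta = Conv2d(c_x, c_int, 2, rng, stride=2, dtype=dtype)
        self.phi = Conv2d(c_g, c_int, 1, rng, dtype=dtype)
        self.psi = Conv2d(c_int, 1, 1, rng, dtype=dtype)
        self.out_conv = Conv2d(c_x, c_x, 1, rng, dtype=dtype)
        self.bn = BatchNorm2d(c_x, dtype=dtype)
        self.force_identity = False
        self.last_psi: np.ndarray | None = None
        self.last_gated: np.ndarray | None = None

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        if self.force_identity:
            return x
        t = self.theta(x)
        p = self.phi(g)
        while p.shape[2] < t.shape[2]:
            p = ag.upsample_bilinear2x(p)
        if p.shape[2:] != t.shape[2:]:
            raise ValueError(
                f"gating signal spatial size {g.shape[2:]} incompatible with "
                f"skip feature {x.shape[2:]} (expected half resolution)"
            )
        f = ag.relu(ag.add(t, p))
        psi = ag.sigmoid(self.psi(f))
        self.last_psi = psi.data
        psi_up = ag.upsample_bilinear2x(psi)
        gated = ag.mul(x, psi_up)  # broadcast over the channel axis
        self.last_gated = gated.data
        return self.bn(self.out_conv(gated))


class SporeUNet(Module):
    """Attention-gated encoder-decoder segmentation network."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        config = config or ModelConfig()
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.depth
        enc_ch = [config.base_channels * 2**i for i in range(d)]
        bott_ch = config.base_channels * 2**d

        self.encoders = []
        in_ch = 1
        for ch in enc_ch:
            self.encoders.append(DoubleConv(in_ch, ch, rng))
            in_ch = ch
        self.bottleneck = DoubleConv(enc_ch[-1], bott_ch, rng)

        if config.channel_attention:
            self.channel_attns = [ChannelAttention(ch, rng) for ch in enc_ch]
        else:
            self.channel_attns = []
        if config.spatial_attention:
            # gating signal at level i is the decoder/bottleneck feature
            # one resolution step deeper
            g_ch = [enc_ch[i + 1] if i + 1 < d else bott_ch for i in range(d)]
            self.gates = [
                SpatialAttentionGate(
                    enc_ch[i], g_ch[i],
                    max(int(enc_ch[i] * config.inter_channels_ratio), 1), rng,
                )
                for i in range(d)
            ]
        else:
            self.gates = []

        self.decoders = []
        deeper = bott_ch
        for ch in reversed(enc_ch):
            self.decoders.append(DoubleConv(deeper + ch, ch, rng))
            deeper = ch
        self.head = Conv2d(enc_ch[0], config.output_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Map a (N, 1, H, W) batch to (N, 1, H, W) logits."""
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = ag.max_pool2x2(x)
        x = self.bottleneck(x)
        for level in range(self.config.depth - 1, -1, -1):
            skip = skips[level]
            if self.channel_attns:
                skip = self.channel_attns[level](skip)
            if self.gates:
                skip = self.gates[level](skip, x)  # g: feature before upsampling
            x = ag.upsample_bilinear2x(x)
            x = ag.concat_channels([skip, x])
            x = self.decoders[self.config.depth - 1 - level](x)
        return self.head(x)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> SporeUNet:
    """Construct a seeded spore-UNet from an architecture config."""
    return SporeUNet(config, seed=seed)


def _forward_prob(net: SporeUNet, tile: np.ndarray) -> np.ndarray:
    logits = net(Tensor(tile[None, None].astype(np.float32)))
    return 1.0 / (1.0 + np.exp(-logits.data[0, 0].astype(np.float64)))


def predict_mask(
    net: SporeUNet,
    image: GrayImage,
    threshold: float = 0.5,
    overlap: int = 32,
) -> BinaryMask:
    """Segment a (preprocessed) frame into a binary mask.

    Frames no larger than the network input size are reflect-padded to a
    multiple of ``2**depth``, segmented in one pass and cropped back.
    Larger frames are processed as a grid of input-size tiles with
    ``overlap`` pixels of overlap; sigmoid probabilities are averaged in
    the overlap regions before thresholding (strictly greater than
    ``threshold``).
    """
    net.eval()
    arr = image.pixels.astype(np.float32)
    h, w = arr.shape
    th, tw = net.config.input_size
    step = 2**net.config.depth

    if h <= th and w <= tw:
        ph = -h % step
        pw = -w % step
        padded = np.pad(arr, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else arr
        prob = _forward_prob(net, padded)[:h, :w]
        return BinaryMask(prob > threshold)

    # tiled inference with overlap averaging
    ph = max(th - h, 0)
    pw = max(tw - w, 0)
    work = np.pad(arr, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else arr
    hh, ww = work.shape
    def starts(total, tile, stride):
        s = list(range(0, total - tile + 1, stride))
        if s[-1] != total - tile:
            s.append(total - tile)
        return s

    rows = starts(hh, th, th - overlap)
    cols = starts(ww, tw, tw - overlap)
    acc = np.zeros((hh, ww))
    weight = np.zeros((hh, ww))
    for r in rows:
        for c in cols:
            acc[r : r + th, c : c + tw] += _forward_prob(net, work[r : r + th, c : c + tw])
            weight[r : r + th, c : c + tw] += 1.0
    prob = (acc / weight)[:h, :w]
    return BinaryMask(prob > threshold)


def save_model(net: SporeUNet, path: str | Path) -> None:
    """Serialize weights (.npz) with a JSON sidecar of the config."""
    path = Path(path)
    np.savez(path, **net.state_dict())
    cfg = asdict(net.config)
    cfg["input_size"] = list(cfg["input_size"])
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(cfg, fh, indent=2)


def load_model(path: str | Path) -> SporeUNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        cfg = json.load(fh)
    cfg["input_size"] = tuple(cfg["input_size"])
    net = SporeUNet(ModelConfig(**cfg))
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
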