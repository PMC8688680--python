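"""Residual U-Net for 3-class forearm segmentation, plus the plain-U-Net
ablation baseline and an architecture audit.

Topology
--------
Encoder: five Resblocks with a 2x2 max-pool after each of the first
four. A Resblock is two stacked residual units; each unit runs
[3x3 conv -> BN -> ReLU -> 3x3 conv -> BN] on the main path and a
[1x1 conv -> BN] projection on the shortcut, adds them and applies a
final ReLU — four 3x3 and two 1x1 convolutions per block in total.
Channel widths double per stage from ``base_channels`` (default 32:
32, 64, 128, 256, 512).

Decoder: four stages of [2x2 stride-2 transposed conv -> concatenate
with the matching encoder feature along channels -> Convblock of two
(3x3 conv -> BN -> ReLU)]. The head is a 1x1 convolution from
``base_channels`` feature channels to 3 classes followed by a per-pixel
softmax.

The ablation baseline swaps each encoder Resblock for a Convblock and
keeps everything else identical. All convolutions use 'same' padding,
so spatial size is preserved everywhere and skip concatenation needs no
cropping; inputs must have height and width divisible by 16 (the four
poolings), which ``segment_image`` arranges by reflect-padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for training code)
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Layer,
    MaxPool2d,
    ReLU,
    softmax_backward,
    softmax_channels,
)


@dataclass
class NetworkSpec:
    """Declarative architecture description.

    ``encoder_channels`` is derived: base_channels doubling over five
    stages. The default base of 32 gives (32, 64, 128, 256, 512) and a
    head mapping 32 feature channels to 3 classes.
    """

    n_classes: int = 3
    base_channels: int = 32
    depth: int = 5

    def __post_init__(self):
        if self.base_channels <= 0 or self.n_classes <= 0:
            raise ValueError("base_channels and n_classes must be positive")
        if self.depth != 5:
            raise ValueError("this architecture is defined for depth 5")

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(self.depth))


class ResidualUnit(Layer):
    """One residual unit: main [3x3-BN-ReLU-3x3-BN], shortcut [1x1-BN], add, ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.conv_sc = Conv2d(in_ch, out_ch, 1, rng)
        self.bn_sc = BatchNorm2d(out_ch)
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        main = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train), train), train)
        short = self.bn_sc.forward(self.conv_sc.forward(x, train), train)
        return self.relu_out.forward(main + short, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        dshort = self.conv_sc.backward(self.bn_sc.backward(d))
        return dmain + dshort


class ResBlock(Layer):
    """Encoder block of two residual units (in_ch->out_ch, out_ch->out_ch)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.unit1 = ResidualUnit(in_ch, out_ch, rng)
        self.unit2 = ResidualUnit(out_ch, out_ch, rng)

    def forward(self, x, train=False):
        return self.unit2.forward(self.unit1.forward(x, train), train)

    def backward(self, dy):
        return self.unit1.backward(self.unit2.backward(dy))


class ConvBlock(Layer):
    """Two (3x3 conv -> BN -> ReLU) stages; decoder block and baseline encoder block."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        if in_ch <= 0 or out_ch <= 0:
            raise ValueError("channel counts must be positive")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.relu2 = ReLU()

    def forward(self, x, train=False):
        x = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        return self.relu2.forward(self.bn2.forward(self.conv2.forward(x, train), train), train)

    def backward(self, dy):
        d = self.conv2.backward(self.bn2.backward(self.relu2.backward(dy)))
        return self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))


class SegNet(Layer):
    """Encoder-decoder segmentation network with softmax head.

    ``residual_encoder=True`` builds the proposed Resblock variant;
    False builds the plain-U-Net ablation baseline.
    """

    def __init__(self, spec: NetworkSpec, residual_encoder: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.residual_encoder = residual_encoder
        ch = spec.encoder_channels
        enc_cls = ResBlock if residual_encoder else ConvBlock
        ins = (1,) + ch[:-1]
        self.encoder_blocks = [enc_cls(i, o, rng) for i, o in zip(ins, ch)]
        self.pools = [MaxPool2d() for _ in range(4)]
        # decoder: stage i upsamples ch[i+1] -> ch[i], concat with skip ch[i]
        self.ups = [ConvTranspose2d(ch[i + 1], ch[i], rng) for i in reversed(range(4))]
        self.dec_blocks = [ConvBlock(2 * ch[i], ch[i], rng) for i in reversed(range(4))]
        self.head = Conv2d(ch[0], spec.n_classes, 1, rng)
        self._cache = None

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (N, 1, H, W)")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input height and width must be divisible by 16")
        skips = []
        for i, block in enumerate(self.encoder_blocks):
            x = block.forward(x, train)
            if i < 4:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        skip_ch = []
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            u = up.forward(x, train)
            cat = np.concatenate([skip, u], axis=1)
            skip_ch.append(skip.shape[1])
            x = dec.forward(cat, train)
        logits = self.head.forward(x, train)
        probs = softmax_channels(logits)
        if train:
            self._cache = (probs, skip_ch)
        return probs

    def backward(self, dprobs):
        probs, skip_ch = self._cache
        self._cache = None
        d = softmax_backward(probs, dprobs).astype(probs.dtype, copy=False)
        d = self.head.backward(d)
        dskips = []
        for up, dec, sc in zip(reversed(self.ups), reversed(self.dec_blocks), reversed(skip_ch)):
            dcat = dec.backward(d)
            dskips.append(dcat[:, :sc])
            d = up.backward(dcat[:, sc:])
        # dskips collected bottom-up: dskips[0] belongs to encoder stage 0's output
        for i in reversed(range(len(self.encoder_blocks))):
            if i < 4:
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.encoder_blocks[i].backward(d)
        return d

    # --- persistence -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array mapping of parameters and BN running stats."""
        state = {}
        for k, mod in enumerate(self.modules()):
            for j, p in enumerate(p for p in vars(mod).values() if hasattr(p, "grad") and hasattr(p, "data")):
                state[f"m{k}.p{j}"] = p.data
            if isinstance(mod, BatchNorm2d):
                state[f"m{k}.running_mean"] = mod.running_mean
                state[f"m{k}.running_var"] = mod.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, mod in enumerate(self.modules()):
            for j, p in enumerate(p for p in vars(mod).values() if hasattr(p, "grad") and hasattr(p, "data")):
                p.data[...] = state[f"m{k}.p{j}"]
            if isinstance(mod, BatchNorm2d):
                mod.running_mean[...] = state[f"m{k}.running_mean"]
                mod.running_var[...] = state[f"m{k}.running_var"]

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_arrays(dict(data))


def build_resblock(in_ch: int, out_ch: int, seed: int = 0) -> ResBlock:
    """Standalone Resblock builder (two residual units)."""
    return ResBlock(in_ch, out_ch, np.random.default_rng(seed))


def build_segmenter(spec: NetworkSpec | None = None, seed: int = 0) -> SegNet:
    """Build the proposed Resblock U-Net."""
    return SegNet(spec or NetworkSpec(), residual_encoder=True, seed=seed)


def build_unet_baseline(spec: NetworkSpec | None = None, seed: int = 0) -> SegNet:
    """Build the plain-U-Net ablation baseline (Convblock encoder)."""
    return SegNet(spec or NetworkSpec(), residual_encoder=False, seed=seed)


@dataclass
class AuditReport:
    """Layer census of a built network, derived by traversing it."""

    resblocks: int
    convblocks_encoder: int
    convblocks_decoder: int
    conv3x3_per_resblock: int
    conv1x1_per_resblock: int
    maxpools: int
    transconvs: int
    skip_connections: int
    head_in_channels: int
    head_out_channels: int
    n_parameters: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("extra")
        d.update(self.extra)
        return d


def count_parameters(model: SegNet) -> int:
    return int(sum(p.size for p in model.parameters()))


def audit_architecture(model: SegNet) -> AuditReport:
    """Count the network's structural elements by graph traversal.

    Counts come from the instantiated layer objects and their channel
    attributes, not from the NetworkSpec, so the report verifies what
    was actually built. Skip connections are counted as decoder stages
    whose Convblock consumes (encoder feature + upsampled feature)
    channels, i.e. concatenation wiring evidenced by channel arithmetic.
    """
    if not isinstance(model, SegNet):
        raise TypeError(f"audit_architecture expects a SegNet, got {type(model).__name__}")
    mods = list(model.modules())
    resblocks = [m for m in mods if isinstance(m, ResBlock)]
    convblocks = [m for m in mods if isinstance(m, ConvBlock)]
    enc_convblocks = [b for b in convblocks if b in model.encoder_blocks]
    dec_convblocks = [b for b in convblocks if b in model.dec_blocks]
    maxpools = [m for m in mods if isinstance(m, MaxPool2d)]
    transconvs = [m for m in mods if isinstance(m, ConvTranspose2d)]

    if resblocks:
        convs = [m for m in resblocks[0].modules() if isinstance(m, Conv2d)]
        c3 = sum(1 for c in convs if c.kernel == 3)
        c1 = sum(1 for c in convs if c.kernel == 1)
    else:
        c3 = c1 = 0

    skips = 0
    enc_out = [b.out_ch if isinstance(b, (ResBlock, ConvBlock)) else None for b in model.encoder_blocks]
    for up, dec in zip(model.ups, model.dec_blocks):
        if dec.in_ch == up.out_ch + enc_out[enc_out.index(up.out_ch)]:
            skips += 1

    return AuditReport(
        resblocks=len(resblocks),
        convblocks_encoder=len(enc_convblocks),
        convblocks_decoder=len(dec_convblocks),
        conv3x3_per_resblock=c3,
        conv1x1_per_resblock=c1,
        maxpools=len(maxpools),
        transconvs=len(transconvs),
        skip_connections=skips,
        head_in_channels=model.head.in_ch,
        head_out_channels=model.head.out_ch,
        n_parameters=count_parameters(model),
    )


def segment_image(model: SegNet, image: np.ndarray, return_probs: bool = False):
    """Segment a single [0, 1] grayscale image into a {0,1,2} label map.

    Images whose height or width is not divisible by 16 are
    reflect-padded up to the next multiple, segmented, and cropped back.
    Argmax ties break toward the lowest class index.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    h, w = image.shape
    ph = (-h) % 16
    pw = (-w) % 16
    padded = np.pad(image, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else image
    probs = model.forward(padded[None, None], train=False)[0]
    probs = probs[:, :h, :w]
    labels = probs.argmax(axis=0).astype(np.uint8)
    if return_probs:
        return labels, probs
    return labels
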