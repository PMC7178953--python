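"""The deeply supervised dilated FC-DenseNet (D2FC-DN).

Encoder: an initial 7x7 convolution, then three (dilated dense block,
transition down) stages; a dilated dense block bottleneck; decoder: three
transition-up stages, each concatenated with the encoder skip at its
resolution; two final 3x3 convolutions produce a single-channel logit map.
Dense blocks concatenate only their per-layer outputs (n_layers * growth_rate
channels); the tensor handed to the next transition additionally carries the
block input, which is also what the skip connections forward to the decoder.
The decoder deliberately contains no dense blocks, keeping the parameter
count low.

Deep supervision: after each transition-up stage a 1x1 convolution plus
sigmoid yields a probability map, bilinearly upsampled to the input
resolution.  The heads participate only in the training objective; inference
thresholds the main output at 0.5 (ties count as foreground).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import DTYPE, BatchNorm2d, Conv2d, ConvTranspose2d, Module


@dataclass(frozen=True)
class DenseBlockSpec:
    """A dilated dense block: n_layers layers each emitting growth_rate
    channels, with dilation factors 1, 2, ..., n_layers by default."""

    n_layers: int
    growth_rate: int
    dilation_schedule: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        sched = self.dilation_schedule
        if sched is None:
            sched = tuple(range(1, self.n_layers + 1))
            object.__setattr__(self, "dilation_schedule", sched)
        if len(sched) != self.n_layers:
            raise ValueError(
                f"dilation_schedule length {len(sched)} != n_layers {self.n_layers}")

    @property
    def out_channels(self) -> int:
        return self.n_layers * self.growth_rate


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of a D2FC-DN.

    The default is the published configuration: input 384x192 (width x
    height), initial 7x7 conv to 16 channels, four dense-block levels with
    (n_layers, growth_rate) = (4,8), (5,16), (6,32), (7,64) — the layer count
    grows by one and the growth rate doubles at each downsampling — transition
    downs to 32/64/128 channels, transition ups to 448/192/96, and final 3x3
    convolutions to 32 and 1 channels.
    """

    input_hw: tuple = (192, 384)
    init_channels: int = 16
    levels: tuple = ((4, 8), (5, 16), (6, 32), (7, 64))
    td_channels: tuple = (32, 64, 128)
    tu_channels: tuple = (448, 192, 96)
    penult_channels: int = 32
    threshold: float = 0.5

    def __post_init__(self):
        h, w = self.input_hw
        n_down = len(self.levels) - 1
        if h % (2 ** n_down) or w % (2 ** n_down):
            raise ValueError(
                f"input {w}x{h} not divisible by 2^{n_down} for {n_down} downsamplings")
        for i in range(1, len(self.levels)):
            n_prev, k_prev = self.levels[i - 1]
            n_cur, k_cur = self.levels[i]
            if n_cur != n_prev + 1:
                raise ValueError(
                    f"level {i}: n_layers must increase by 1 per downsampling "
                    f"({n_prev} -> {n_cur})")
            if k_cur != 2 * k_prev:
                raise ValueError(
                    f"level {i}: growth rate must double per downsampling "
                    f"({k_prev} -> {k_cur})")
        if len(self.td_channels) != n_down or len(self.tu_channels) != n_down:
            raise ValueError("need one transition per downsampling on each side")

    @classmethod
    def default(cls) -> "NetworkSpec":
        return cls()

    @classmethod
    def reduced(cls, input_hw=(48, 96)) -> "NetworkSpec":
        """A width-reduced preset with the same topology, small enough to
        train on a CPU; used for scaled-down end-to-end experiments."""
        return cls(input_hw=tuple(input_hw), init_channels=8,
                   levels=((2, 2), (3, 4), (4, 8), (5, 16)),
                   td_channels=(8, 16, 32), tu_channels=(80, 32, 16),
                   penult_channels=8)

    def block_specs(self):
        return [DenseBlockSpec(n, k) for n, k in self.levels]

    def to_json(self) -> str:
        return json.dumps({
            "input_hw": list(self.input_hw),
            "init_channels": self.init_channels,
            "levels": [list(l) for l in self.levels],
            "td_channels": list(self.td_channels),
            "tu_channels": list(self.tu_channels),
            "penult_channels": self.penult_channels,
            "threshold": self.threshold,
        })

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        return cls(input_hw=tuple(d["input_hw"]),
                   init_channels=d["init_channels"],
                   levels=tuple(tuple(l) for l in d["levels"]),
                   td_channels=tuple(d["td_channels"]),
                   tu_channels=tuple(d["tu_channels"]),
                   penult_channels=d["penult_channels"],
                   threshold=d["threshold"])


class DilatedDenseBlock(Module):
    """Each layer: batch norm -> ReLU -> 3x3 dilated conv emitting
    growth_rate channels; layer i uses dilation factor i (1-based).  The
    input of layer i is the concatenation of the block input with all
    previous layer outputs; the block output concatenates the per-layer
    outputs only."""

    def __init__(self, c_in, spec: DenseBlockSpec, rng=None):
        super().__init__()
        self.spec = spec
        self.bns = []
        self.convs = []
        c = c_in
        for l in spec.dilation_schedule:
            self.bns.append(BatchNorm2d(c))
            self.convs.append(Conv2d(c, spec.growth_rate, 3, dilation=l, rng=rng))
            c += spec.growth_rate

    def __call__(self, x: Tensor) -> Tensor:
        feats = [x]
        outs = []
        for bn, conv in zip(self.bns, self.convs):
            h = feats[0] if len(feats) == 1 else ag.concat(feats, axis=1)
            y = conv(ag.relu(bn(h)))
            feats.append(y)
            outs.append(y)
        return outs[0] if len(outs) == 1 else ag.concat(outs, axis=1)


class TransitionDown(Module):
    """Batch norm -> ReLU -> 1x1 conv -> 2x2 max pool (stride 2)."""

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        self.bn = BatchNorm2d(c_in)
        self.conv = Conv2d(c_in, c_out, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.max_pool2x2(self.conv(ag.relu(self.bn(x))))


class TransitionUp(Module):
    """Batch norm -> ReLU -> 3x3 transposed conv (stride 2)."""

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        self.bn = BatchNorm2d(c_in)
        self.tconv = ConvTranspose2d(c_in, c_out, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.tconv(ag.relu(self.bn(x)))


class D2FCDN(Module):
    """See module docstring.  forward() returns the main probability map and
    the list of supervision-head probability maps (coarsest first), all at
    the input resolution."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        blocks = spec.block_specs()
        n_down = len(spec.levels) - 1

        self.init_conv = Conv2d(1, spec.init_channels, 7, rng=rng)
        c = spec.init_channels
        self.enc_blocks = []
        self.tds = []
        self.skip_channels = []
        for i in range(n_down):
            blk = DilatedDenseBlock(c, blocks[i], rng=rng)
            self.enc_blocks.append(blk)
            c_skip = c + blk.spec.out_channels
            self.skip_channels.append(c_skip)
            self.tds.append(TransitionDown(c_skip, spec.td_channels[i], rng=rng))
            c = spec.td_channels[i]
        self.bottleneck = DilatedDenseBlock(c, blocks[-1], rng=rng)
        c = blocks[-1].out_channels

        self.tus = []
        self.heads = []
        for i in range(n_down):
            self.tus.append(TransitionUp(c, spec.tu_channels[i], rng=rng))
            self.heads.append(Conv2d(spec.tu_channels[i], 1, 1, rng=rng))
            # after upsampling, concatenate the encoder skip at this resolution
            skip = self.skip_channels[n_down - 1 - i]
            c = spec.tu_channels[i] + skip
        self.final_conv1 = Conv2d(c, spec.penult_channels, 3, rng=rng)
        self.final_conv2 = Conv2d(spec.penult_channels, 1, 3, rng=rng)

    def __call__(self, x: Tensor, trace: list | None = None):
        spec = self.spec
        n_down = len(spec.levels) - 1

        def record(t):
            if trace is not None:
                n, c, hh, ww = t.shape
                trace.append((ww, hh, c))

        h = self.init_conv(x)
        record(h)
        skips = []
        for blk, td in zip(self.enc_blocks, self.tds):
            out = blk(h)
            record(out)
            cat = ag.concat([h, out], axis=1)
            skips.append(cat)
            h = td(cat)
            record(h)
        h = self.bottleneck(h)
        record(h)

        head_probs = []
        for i, (tu, head) in enumerate(zip(self.tus, self.heads)):
            h = tu(h)
            record(h)
            factor = 2 ** (n_down - 1 - i)
            prob = ag.sigmoid(head(h))
            head_probs.append(ag.upsample_bilinear(prob, factor))
            h = ag.concat([h, skips[n_down - 1 - i]], axis=1)
        h = self.final_conv1(h)
        record(h)
        logits = self.final_conv2(h)
        record(logits)
        return ag.sigmoid(logits), head_probs

    def trace_forward(self) -> list:
        """Run a forward pass on a zero input and return the actual
        (width, height, channels) of every architecture-table row."""
        trace: list = []
        was_training = self.training
        self.eval()
        x = Tensor(np.zeros((1, 1, *self.spec.input_hw), dtype=DTYPE))
        self(x, trace=trace)
        self.train(was_training)
        return trace

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        """Probability map for one image (H, W), intensities in [0, 255] or
        [0, 1]; inference mode (running batch-norm statistics)."""
        x = _prepare_input(img, self.spec.input_hw)
        was_training = self.training
        self.eval()
        prob, _ = self(Tensor(x))
        self.train(was_training)
        return prob.data[0, 0].astype(np.float64)

    def predict(self, img: np.ndarray) -> np.ndarray:
        """Binary mask: probability >= threshold (default 0.5)."""
        return self.predict_proba(img) >= self.spec.threshold


def _prepare_input(img: np.ndarray, input_hw) -> np.ndarray:
    img = np.asarray(img)
    if img.shape != tuple(input_hw):
        raise ValueError(f"expected image of shape {tuple(input_hw)}, got {img.shape}")
    x = img.astype(DTYPE)
    if img.dtype == np.uint8 or x.max() > 1.5:
        x = x / 255.0
    return x[None, None]


def build_d2fc_dn(spec: NetworkSpec = None, seed: int = 0) -> D2FCDN:
    """Construct a D2FC-DN; defaults to the published architecture."""
    return D2FCDN(spec if spec is not None else NetworkSpec.default(), seed=seed)


def shape_trace(spec: NetworkSpec = None):
    """Analytic (layer, width, height, channels) rows of the architecture
    table; dense-block rows report the block-output concatenation width."""
    spec = spec if spec is not None else NetworkSpec.default()
    h, w = spec.input_hw
    blocks = spec.block_specs()
    n_down = len(spec.levels) - 1
    rows = [("Convolution 7x7", w, h, spec.init_channels)]
    for i in range(n_down):
        blk = blocks[i]
        rows.append((f"Dilated dense block [3x3 dilated conv] x{blk.n_layers}, "
                     f"k={blk.growth_rate}", w, h, blk.out_channels))
        h, w = h // 2, w // 2
        rows.append(("Transition down", w, h, spec.td_channels[i]))
    blk = blocks[-1]
    rows.append((f"Dilated dense block [3x3 dilated conv] x{blk.n_layers}, "
                 f"k={blk.growth_rate}", w, h, blk.out_channels))
    for i in range(n_down):
        h, w = h * 2, w * 2
        rows.append(("Transition up", w, h, spec.tu_channels[i]))
    rows.append(("Convolution 3x3", w, h, spec.penult_channels))
    rows.append(("Convolution 3x3", w, h, 1))
    return rows


def count_parameters(net: Module) -> int:
    """Total trainable scalars: conv/transposed-conv weights and biases plus
    batch-norm scales and shifts."""
    return net.count_parameters()


def describe(spec: NetworkSpec = None, file=None) -> str:
    """Print the architecture table with output sizes and parameter count."""
    spec = spec if spec is not None else NetworkSpec.default()
    net = build_d2fc_dn(spec)
    buf = io.StringIO()
    buf.write(f"{'Layer':<55s}{'Output size':>20s}\n")
    for name, w, h, c in shape_trace(spec):
        buf.write(f"{name:<55s}{f'{w} x {h} x {c}':>20s}\n")
    n = count_parameters(net)
    buf.write(f"Trainable parameters: {n:,} ({n / 1e6:.2f} million)\n")
    text = buf.getvalue()
    if file is not None:
        file.write(text)
    else:
        print(text, end="")
    return text


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(net: D2FCDN, path) -> None:
    """Serialize weights, batch-norm statistics, and the NetworkSpec."""
    arrays = {f"param/{k}": p.data for k, p in net.named_parameters()}
    arrays.update({f"buffer/{k}": b for k, b in net.buffers()})
    np.savez(path, __spec__=np.frombuffer(net.spec.to_json().encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> D2FCDN:
    with np.load(path) as data:
        spec = NetworkSpec.from_json(bytes(data["__spec__"]).decode())
        net = D2FCDN(spec)
        params = dict(net.named_parameters())
        buffers = dict(net.buffers())
        for key in data.files:
            if key.startswith("param/"):
                params[key[6:]].data = data[key].astype(DTYPE)
            elif key.startswith("buffer/"):
                buffers[key[7:]][...] = data[key]
    return net
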