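"""Generator and discriminator architectures for adversarial 3D segmentation.

The generator is an encoder–decoder: four stride-2 down-sampling blocks
(kernel 4, leaky ReLU, filters doubling from ``base_filters``), four
stride-1 residual blocks with dropout at the bottleneck, three stride-2
transposed-convolution up-sampling blocks (ReLU), and a final stride-2
transposed convolution with a per-voxel softmax over the four tissue
classes.  For a cube of side P the bottleneck is (P/16)³ with
``8 × base_filters`` channels — 8³×512 at P = 128, base 64.

The discriminator is a 3D patch critic: it sees the four image channels
concatenated with a four-channel segmentation (one-hot ground truth or
generator softmax), applies the same four down-sampling blocks, then a
single kernel-4 stride-1 convolution to one channel with a sigmoid,
yielding a (P/16)³×1 field of realness scores.

Instance normalisation is used in every block except the first
down-sampling block; leaky ReLU slope is 0.2.  Weights are zero-mean
Gaussian, std 0.02, drawn from a seeded generator so builds are
reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Conv3d,
    ConvTranspose3d,
    Dropout,
    InstanceNorm3d,
    LeakyReLU,
    ReLU,
    Residual,
    Sequential,
    Sigmoid,
    SoftmaxChannels,
)

N_CLASSES = 4
N_MODALITIES = 4


@dataclass
class GeneratorSpec:
    """Declarative generator configuration."""

    in_channels: int = N_MODALITIES
    out_channels: int = N_CLASSES
    base_filters: int = 64
    n_down_blocks: int = 4
    n_residual_blocks: int = 4
    n_up_blocks: int = 3
    kernel_size: int = 4
    down_stride: int = 2
    residual_stride: int = 1
    dropout: float = 0.2
    leaky_slope: float = 0.2
    init_std: float = 0.02
    normalization: str = "instance"   # "instance" | "none"
    skip_connections: bool = True

    def validate(self) -> None:
        if self.normalization not in ("instance", "none"):
            raise ValueError("normalization must be 'instance' or 'none'")
        if self.out_channels != N_CLASSES:
            raise ValueError("generator must emit one channel per label class")
        if self.n_up_blocks + 1 != self.n_down_blocks:
            raise ValueError(
                "up blocks + final head must undo the down-sampling: "
                f"need n_up_blocks = n_down_blocks - 1, got "
                f"{self.n_up_blocks} vs {self.n_down_blocks}")

    @property
    def min_divisor(self) -> int:
        return self.down_stride**self.n_down_blocks


@dataclass
class DiscriminatorSpec:
    """Declarative discriminator (patch critic) configuration."""

    in_channels: int = N_MODALITIES + N_CLASSES
    base_filters: int = 64
    n_down_blocks: int = 4
    kernel_size: int = 4
    down_stride: int = 2
    leaky_slope: float = 0.2
    init_std: float = 0.02
    normalization: str = "instance"   # "instance" | "none"

    def validate(self) -> None:
        if self.normalization not in ("instance", "none"):
            raise ValueError("normalization must be 'instance' or 'none'")
        if self.in_channels != N_MODALITIES + N_CLASSES:
            raise ValueError(
                "discriminator conditions on image + segmentation channels")

    @property
    def min_divisor(self) -> int:
        return self.down_stride**self.n_down_blocks


class Network(Sequential):
    """A Sequential tagged with its spec so checkpoints are self-describing."""

    def __init__(self, layers, spec):
        super().__init__(layers)
        self.spec = spec


class GeneratorNet:
    """Encoder–residual–decoder generator with optional skip connections.

    Skips concatenate each encoder block's output onto the matching
    decoder resolution, giving the decoder voxel-level pathways around
    the bottleneck — without them a (P/16)³ bottleneck cannot place
    small structures precisely.  All stage shapes of the skip-free path
    (bottleneck, output) are unchanged by the concatenation.
    """

    def __init__(self, down: list[Sequential], res: list,
                 up: list[Sequential], head: Sequential, spec):
        self.down, self.res, self.up, self.head = down, res, up, head
        self.spec = spec
        self._skip_grads: list = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        feats = []
        for blk in self.down:
            x = blk.forward(x, training=training)
            feats.append(x)
        self._feat_channels = [f.shape[1] for f in feats]
        for r in self.res:
            x = r.forward(x, training=training)
        for j, blk in enumerate(self.up):
            x = blk.forward(x, training=training)
            if self.spec.skip_connections:
                enc = feats[len(self.down) - 2 - j]
                x = np.concatenate([x, enc], axis=1)
        return self.head.forward(x, training=training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n_down = len(self.down)
        skip_grads: dict[int, np.ndarray] = {}
        d = self.head.backward(dout)
        for j in range(len(self.up) - 1, -1, -1):
            blk = self.up[j]
            if self.spec.skip_connections:
                enc_idx = n_down - 2 - j
                c_skip = self._feat_channels[enc_idx]
                skip_grads[enc_idx] = d[:, d.shape[1] - c_skip:]
                d = d[:, : d.shape[1] - c_skip]
            d = blk.backward(d)
        for r in reversed(self.res):
            d = r.backward(d)
        for i in range(n_down - 1, -1, -1):
            if i in skip_grads:
                d = d + skip_grads[i]
            d = self.down[i].backward(d)
        return d

    def params(self):
        out = []
        for blk in [*self.down, *self.res, *self.up, self.head]:
            out.extend(blk.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


def _down_block(c_in, c_out, k, stride, slope, rng, init_std, norm: bool):
    layers = [Conv3d(c_in, c_out, k, stride, rng, init_std)]
    if norm:
        layers.append(InstanceNorm3d(c_out))
    layers.append(LeakyReLU(slope))
    return layers


def build_generator(spec: GeneratorSpec, seed: int = 0) -> GeneratorNet:
    """Construct a seeded generator network from its spec."""
    spec.validate()
    rng = np.random.default_rng(seed)
    k, s = spec.kernel_size, spec.down_stride
    use_norm = spec.normalization == "instance"

    down: list[Sequential] = []
    enc_channels: list[int] = []
    c = spec.in_channels
    filters = spec.base_filters
    for i in range(spec.n_down_blocks):
        down.append(Sequential(_down_block(
            c, filters, k, s, spec.leaky_slope, rng, spec.init_std,
            norm=(i > 0 and use_norm))))
        enc_channels.append(filters)
        c, filters = filters, filters * 2

    res: list[Residual] = []
    for _ in range(spec.n_residual_blocks):
        body = [Conv3d(c, c, k, spec.residual_stride, rng, spec.init_std)]
        if use_norm:
            body.append(InstanceNorm3d(c))
        body += [LeakyReLU(spec.leaky_slope), Dropout(spec.dropout, rng)]
        res.append(Residual(Sequential(body)))

    up: list[Sequential] = []
    for j in range(spec.n_up_blocks):
        c_out = enc_channels[spec.n_down_blocks - 2 - j]
        block: list = [ConvTranspose3d(c, c_out, k, s, rng, spec.init_std)]
        if use_norm:
            block.append(InstanceNorm3d(c_out))
        block.append(ReLU())
        up.append(Sequential(block))
        c = c_out * 2 if spec.skip_connections else c_out

    head = Sequential([
        ConvTranspose3d(c, spec.out_channels, k, s, rng, spec.init_std),
        SoftmaxChannels(),
    ])
    return GeneratorNet(down, res, up, head, spec)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Network:
    """Construct a seeded patch-critic discriminator from its spec."""
    spec.validate()
    rng = np.random.default_rng(seed)
    k, s = spec.kernel_size, spec.down_stride
    layers: list = []

    use_norm = spec.normalization == "instance"
    c = spec.in_channels
    filters = spec.base_filters
    for i in range(spec.n_down_blocks):
        layers += _down_block(c, filters, k, s, spec.leaky_slope, rng,
                              spec.init_std, norm=(i > 0 and use_norm))
        c, filters = filters, filters * 2

    layers += [
        Conv3d(c, 1, k, 1, rng, spec.init_std),
        Sigmoid(),
    ]
    return Network(layers, spec)


def generator_shape_flow(spec: GeneratorSpec, patch_size: int) -> list[tuple[str, tuple]]:
    """Analytic (stage name, channels-last shape) trace through the generator.

    Computed from the spec alone, without building weights, so the shape
    contract can be checked at full scale cheaply.
    """
    spec.validate()
    if patch_size % spec.min_divisor:
        raise ValueError(
            f"patch size {patch_size} not divisible by {spec.min_divisor}")
    flow = [("input", (patch_size,) * 3 + (spec.in_channels,))]
    side, filters = patch_size, spec.base_filters
    enc = []
    for i in range(spec.n_down_blocks):
        side //= spec.down_stride
        flow.append((f"down{i + 1}", (side,) * 3 + (filters,)))
        enc.append(filters)
        filters *= 2
    filters //= 2
    for i in range(spec.n_residual_blocks):
        flow.append((f"residual{i + 1}", (side,) * 3 + (filters,)))
    for i in range(spec.n_up_blocks):
        side *= spec.down_stride
        c_out = enc[spec.n_down_blocks - 2 - i]
        c_stage = c_out * 2 if spec.skip_connections else c_out
        flow.append((f"up{i + 1}", (side,) * 3 + (c_stage,)))
    side *= spec.down_stride
    flow.append(("output", (side,) * 3 + (spec.out_channels,)))
    return flow


def discriminator_shape_flow(spec: DiscriminatorSpec, patch_size: int) -> list[tuple[str, tuple]]:
    """Analytic shape trace through the discriminator."""
    spec.validate()
    if patch_size % spec.min_divisor:
        raise ValueError(
            f"patch size {patch_size} not divisible by {spec.min_divisor}")
    flow = [("input", (patch_size,) * 3 + (spec.in_channels,))]
    side, filters = patch_size, spec.base_filters
    for i in range(spec.n_down_blocks):
        side //= spec.down_stride
        flow.append((f"down{i + 1}", (side,) * 3 + (filters,)))
        filters *= 2
    flow.append(("output", (side,) * 3 + (1,)))
    return flow


def count_parameters(network: Sequential) -> tuple[int, int, int]:
    """(trainable, non_trainable, total) parameter counts."""
    trainable = sum(p.size for p in network.params() if p.trainable)
    frozen = sum(p.size for p in network.params() if not p.trainable)
    return trainable, frozen, trainable + frozen


def spec_to_dict(spec) -> dict:
    return asdict(spec)


def generator_spec_from_dict(d: dict) -> GeneratorSpec:
    return GeneratorSpec(**d)


def discriminator_spec_from_dict(d: dict) -> DiscriminatorSpec:
    return DiscriminatorSpec(**d)
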