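"""Generator and discriminator architectures for hyperspectral cubes.

The generator maps a standard-normal latent vector (optionally concatenated
with a smoothed class label for the conditional variant) through seven
transposed-convolution stages to an H x W x C cube in tanh range [-1, 1].
Stages 1-6 carry batch normalization + ReLU; stage 7 ends in tanh.  The
first stage is a 4 x 4 transposed convolution acting on the latent vector
viewed as a 1 x 1 image — i.e. a dense projection to a 4 x 4 feature map —
and subsequent stride-2 stages double the spatial size until the requested
output fits, followed by a center crop (50 is not reachable by clean
stride-2 arithmetic from 4, so the map grows to 64 and crops).

The discriminator is six convolution stages: leaky ReLU (slope 0.2) on the
first, batch norm + leaky ReLU on stages 2-5, and a final full-frame
convolution with sigmoid producing one real/fake probability.

When a spec enables the equalized learning rate, every convolutional and
dense weight is rescaled at run time by sqrt(2 / fan_in) so layers of
different width train at comparable effective rates.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn
from .hsi_data import HSCube, SmoothedLabel, SpectralAxis
from .nn import equalized_scale  # re-export

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "FakeSample", "Generator",
    "Discriminator", "build_generator", "build_discriminator",
    "sample_latent", "equalized_scale", "condition_inject", "to_reflectance",
    "save_checkpoint", "load_checkpoint", "SpecError", "CheckpointError",
]

CHECKPOINT_MAGIC = "hsigan-checkpoint-v1"


class SpecError(ValueError):
    """Architecture description is internally inconsistent."""


class CheckpointError(ValueError):
    """Checkpoint file is missing or corrupt."""


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    latent_dim: int = 100
    out_height: int = 50
    out_width: int = 50
    out_channels: int = 116
    base_channels: int = 512
    conditional: bool = False
    #: how many input channels the smoothed label is replicated over; >1
    #: strengthens the conditioning pathway on small models
    condition_channels: int = 1
    equalized_lr: bool = False

    N_STAGES = 7

    def __post_init__(self):
        if min(self.latent_dim, self.out_height, self.out_width,
               self.out_channels, self.base_channels,
               self.condition_channels) < 1:
            raise SpecError("all generator dimensions must be positive")
        self.stage_plan()  # validates reachability

    def stage_plan(self):
        """Strides per transposed-conv stage and the pre-crop spatial size.

        Stage 1 expands 1x1 -> 4x4; stride-2 stages among 2..6 double the
        size until it covers the output; remaining stages keep it.
        """
        target = max(self.out_height, self.out_width)
        size = 4
        n_double = 0
        while size < target:
            size *= 2
            n_double += 1
        if n_double > self.N_STAGES - 2:
            raise SpecError(
                f"spatial path cannot reach {self.out_height}x{self.out_width} "
                f"from 4x4 within {self.N_STAGES - 2} stride-2 stages"
            )
        strides = [2] * n_double + [1] * (self.N_STAGES - 2 - n_double)
        return strides, size

    def stage_channels(self):
        """Output channel width per stage (halved at each doubling, floor 16)."""
        c = self.base_channels
        widths = [max(c, 16)]
        for s in self.stage_plan()[0]:
            if s == 2:
                c //= 2
            widths.append(max(c, 16))
        widths.append(self.out_channels)
        return widths


@dataclasses.dataclass(frozen=True)
class DiscriminatorSpec:
    in_height: int = 50
    in_width: int = 50
    in_channels: int = 116
    base_channels: int = 64
    leaky_slope: float = 0.2
    conditional: bool = False
    equalized_lr: bool = False

    N_STAGES = 6

    def __post_init__(self):
        if min(self.in_height, self.in_width, self.in_channels,
               self.base_channels) < 1:
            raise SpecError("all discriminator dimensions must be positive")
        if min(self.in_height, self.in_width) < 2:
            raise SpecError("input must be at least 2x2")

    def stage_plan(self):
        """Strides for stages 1..5 (stride 2 while spatial > 4) and the
        final full-frame kernel size."""
        h = max(self.in_height, self.in_width)
        strides = []
        for _ in range(self.N_STAGES - 1):
            if h > 4:
                strides.append(2)
                h = (h - 1) // 2 + 1
            else:
                strides.append(1)
        return strides, h


class Generator:
    def __init__(self, spec: GeneratorSpec, rng_seed: int):
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        strides, size = spec.stage_plan()
        widths = spec.stage_channels()
        eq = spec.equalized_lr
        in_ch = spec.latent_dim + (spec.condition_channels if spec.conditional else 0)
        layers = [
            nn.Reshape((in_ch, 1, 1)),
            nn.ConvTranspose2d(in_ch, widths[0], kernel=4, stride=1, pad=0,
                               rng=rng, equalized=eq),
            nn.BatchNorm2d(widths[0]),
            nn.ReLU(),
        ]
        for i, s in enumerate(strides, start=1):
            k, p = (4, 1) if s == 2 else (3, 1)
            layers.append(nn.ConvTranspose2d(widths[i - 1], widths[i], kernel=k,
                                             stride=s, pad=p, rng=rng, equalized=eq))
            if i < spec.N_STAGES - 1:  # stages 1-6 get BN+ReLU
                layers += [nn.BatchNorm2d(widths[i]), nn.ReLU()]
        layers.append(nn.ConvTranspose2d(widths[-2], widths[-1], kernel=3,
                                         stride=1, pad=1, rng=rng, equalized=eq))
        layers.append(nn.Tanh())
        layers.append(nn.CenterCrop(spec.out_height, spec.out_width))
        self.net = nn.Sequential(layers)

    def forward(self, z: np.ndarray, labels: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        """(n, latent_dim) latent batch -> (n, C, H, W) cube batch in [-1,1]."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(f"latent dim {z.shape[1]} != spec {self.spec.latent_dim}")
        if self.spec.conditional:
            if labels is None:
                raise ValueError("conditional generator requires labels")
            z = condition_inject(z, labels)
            if self.spec.condition_channels > 1:
                z = np.concatenate(
                    [z] + [z[:, -1:]] * (self.spec.condition_channels - 1), axis=1)
        elif labels is not None:
            raise ValueError("labels passed to a non-conditional generator")
        return self.net.forward(z, train=train)

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()


class Discriminator:
    def __init__(self, spec: DiscriminatorSpec, rng_seed: int):
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        strides, final = spec.stage_plan()
        eq = spec.equalized_lr
        in_ch = spec.in_channels + (1 if spec.conditional else 0)
        widths = []
        c = spec.base_channels
        for s in strides:
            widths.append(min(c, 512))
            if s == 2:
                c *= 2
        layers = [
            nn.Conv2d(in_ch, widths[0], kernel=3, stride=strides[0], pad=1,
                      rng=rng, equalized=eq),
            nn.LeakyReLU(spec.leaky_slope),
        ]
        for i in range(1, len(strides)):
            layers.append(nn.Conv2d(widths[i - 1], widths[i], kernel=3,
                                    stride=strides[i], pad=1, rng=rng, equalized=eq))
            layers += [nn.BatchNorm2d(widths[i]), nn.LeakyReLU(spec.leaky_slope)]
        layers.append(nn.Conv2d(widths[-1], 1, kernel=final, stride=1, pad=0,
                                rng=rng, equalized=eq))
        layers.append(nn.Sigmoid())
        layers.append(nn.Flatten())
        self.net = nn.Sequential(layers)

    def forward(self, x: np.ndarray, labels: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        """(n, C, H, W) batch in [-1,1] -> (n,) probabilities in (0, 1)."""
        s = self.spec
        if x.ndim != 4 or x.shape[2] != s.in_height or x.shape[3] != s.in_width:
            raise ValueError(f"expected (n, {s.in_channels}, {s.in_height}, "
                             f"{s.in_width}) input, got {x.shape}")
        if s.conditional:
            if labels is None:
                raise ValueError("conditional discriminator requires labels")
            plane = np.broadcast_to(
                np.asarray(labels, dtype=float)[:, None, None, None],
                (x.shape[0], 1, s.in_height, s.in_width))
            x = np.concatenate([x, plane], axis=1)
        elif labels is not None:
            raise ValueError("labels passed to a non-conditional discriminator")
        return self.net.forward(x, train=train)[:, 0]

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        """grad w.r.t. the (n,) output -> grad w.r.t. the input cube batch."""
        dx = self.net.backward(grad[:, None])
        if self.spec.conditional:
            dx = dx[:, :-1]  # drop the label plane
        return dx

    def params(self):
        return self.net.params()

    def grads(self):
        return self.net.grads()


@dataclasses.dataclass
class FakeSample:
    """A generated cube in tanh range with its conditioning label, if any."""

    cube_scaled: np.ndarray  # (H, W, C) in [-1, 1]
    condition: SmoothedLabel | None = None

    def __post_init__(self):
        self.cube_scaled = np.asarray(self.cube_scaled, dtype=float)
        if self.cube_scaled.ndim != 3:
            raise ValueError("cube_scaled must be H x W x C")
        if np.abs(self.cube_scaled).max() > 1.0 + 1e-9:
            raise ValueError("cube_scaled must lie in [-1, 1]")


def build_generator(spec: GeneratorSpec, rng_seed: int) -> Generator:
    return Generator(spec, rng_seed)


def build_discriminator(spec: DiscriminatorSpec, rng_seed: int) -> Discriminator:
    return Discriminator(spec, rng_seed)


def sample_latent(n: int, latent_dim: int = 100, seed=None) -> np.ndarray:
    """n i.i.d. standard-normal latent vectors, reproducible under seed."""
    if n < 1 or latent_dim < 1:
        raise ValueError("n and latent_dim must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, latent_dim))


def condition_inject(z: np.ndarray, labels) -> np.ndarray:
    """Concatenate smoothed label values to latent vectors (batched)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if np.isscalar(labels) or isinstance(labels, SmoothedLabel):
        labels = [labels] * z.shape[0]
    vals = np.array([l.value if isinstance(l, SmoothedLabel) else float(l)
                     for l in labels])
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("label values must lie in [0, 1]")
    if vals.shape[0] != z.shape[0]:
        raise ValueError("one label per latent vector required")
    return np.concatenate([z, vals[:, None]], axis=1)


def to_reflectance(sample: FakeSample, axis: SpectralAxis,
                   id: str = "", label: str | None = None) -> HSCube:
    """Map a tanh-range sample to a reflectance cube.

    Band channels are mapped affinely [-1,1] -> [0,1]; a trailing mask
    channel (when the sample has bands+1 channels) is thresholded at the
    tanh midpoint 0.
    """
    c = sample.cube_scaled.shape[2]
    b = axis.band_count
    if c not in (b, b + 1):
        raise ValueError(f"sample has {c} channels; expected {b} or {b + 1}")
    data = (sample.cube_scaled[:, :, :b] + 1.0) / 2.0
    mask = (sample.cube_scaled[:, :, b] > 0).astype(np.uint8) if c == b + 1 else None
    return HSCube(data=data, axis=axis, mask=mask, label=label, id=id)


def _spec_to_json(spec) -> str:
    d = dataclasses.asdict(spec)
    d["__kind__"] = type(spec).__name__
    return json.dumps(d)


def _spec_from_json(s: str):
    d = json.loads(s)
    kind = d.pop("__kind__")
    cls = {"GeneratorSpec": GeneratorSpec, "DiscriminatorSpec": DiscriminatorSpec}[kind]
    return cls(**d)


def save_checkpoint(path, generator: Generator, discriminator: Discriminator,
                    meta: dict | None = None) -> None:
    """Single-file archive: magic string, specs as JSON, flat named arrays."""
    arrays = {"__magic__": np.array(CHECKPOINT_MAGIC),
              "__gspec__": np.array(_spec_to_json(generator.spec)),
              "__dspec__": np.array(_spec_to_json(discriminator.spec)),
              "__meta__": np.array(json.dumps(meta or {}))}
    for k, v in generator.params().items():
        arrays[f"G/{k}"] = v
    for k, v in discriminator.params().items():
        arrays[f"D/{k}"] = v
    np.savez(path, **arrays)


def load_checkpoint(path):
    """-> (Generator, Discriminator, meta dict) with parameters restored."""
    try:
        with np.load(path, allow_pickle=False) as f:
            if "__magic__" not in f or str(f["__magic__"]) != CHECKPOINT_MAGIC:
                raise CheckpointError(f"{path}: bad or missing magic string")
            gspec = _spec_from_json(str(f["__gspec__"]))
            dspec = _spec_from_json(str(f["__dspec__"]))
            meta = json.loads(str(f["__meta__"]))
            g = Generator(gspec, rng_seed=0)
            d = Discriminator(dspec, rng_seed=0)
            g.net.set_params({k[2:]: f[k] for k in f.files if k.startswith("G/")})
            d.net.set_params({k[2:]: f[k] for k in f.files if k.startswith("D/")})
    except (OSError, ValueError, KeyError) as e:
        if isinstance(e, CheckpointError):
            raise
        raise CheckpointError(f"cannot load checkpoint {path}: {e}") from e
    return g, d, meta
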