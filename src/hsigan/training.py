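"""Two-phase adversarial training.

Phase 1 (``rgb_pretrain``): the GAN pair is trained on ordinary RGB skin
images (50 x 50 x 3) with Adam at 0.0002 for both networks and batch 128.

Phase 2 (``hs_cgan``): the generator's output layer and the discriminator's
input layer are widened from 3 to the hyperspectral band count (plus one
mask channel on the generator side).  The RGB-trained parameter slices are
copied onto the bands nearest the red, green and blue wavelengths; every
other new-channel parameter is freshly initialized.  The conditional GAN is
then trained on the cube dataset with the stabilization recipe: smoothed
real/fake targets, a 5% label swap, the equalized learning rate, two
time-scale updates (generator slower than discriminator) and an L2 penalty
of 1e-5, at batch size 2 for 200 epochs.

Losses are binary cross-entropy; the generator uses the non-saturating
form (maximize log D(G(z))).
"""

from __future__ import annotations

import csv
import dataclasses
import pathlib
import sys

import numpy as np

from . import gan_core, hsi_data, nn
from .gan_core import Discriminator, DiscriminatorSpec, Generator, GeneratorSpec
from .hsi_data import HSCube, smooth_label
from .seeding import stream

RGB_PRETRAIN = "rgb_pretrain"
HS_CGAN = "hs_cgan"

_EPS = 1e-7


class TrainingDivergenceError(RuntimeError):
    """A loss became non-finite."""


@dataclasses.dataclass
class TrainConfig:
    phase: str
    epochs: int
    batch_size: int
    lr_g: float
    lr_d: float
    betas: tuple = (0.5, 0.999)
    label_swap_fraction: float = 0.05
    l2_coeff: float = 1e-5
    equalized_lr: bool = False
    target_smoothing: bool = True
    matching_aware: bool = True  # conditional D also rejects mismatched labels
    mask_aux_coeff: float = 0.0  # optional per-pixel BCE on the mask channel
    fid_every: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.phase not in (RGB_PRETRAIN, HS_CGAN):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not (0 <= self.label_swap_fraction < 0.5):
            raise ValueError("label_swap_fraction must be in [0, 0.5)")
        if self.lr_g < 0 or self.lr_d < 0:
            raise ValueError("learning rates must be nonnegative")

    @classmethod
    def rgb_pretrain(cls, **kw) -> "TrainConfig":
        """Pretraining defaults: 100 epochs, batch 128, lr 0.0002 both."""
        kw.setdefault("epochs", 100)
        kw.setdefault("batch_size", 128)
        kw.setdefault("lr_g", 2e-4)
        kw.setdefault("lr_d", 2e-4)
        kw.setdefault("equalized_lr", False)
        return cls(phase=RGB_PRETRAIN, **kw)

    @classmethod
    def hs_cgan(cls, **kw) -> "TrainConfig":
        """HS-phase defaults: 200 epochs, batch 2, TTUR lr_g 1e-4 < lr_d 4e-4."""
        kw.setdefault("epochs", 200)
        kw.setdefault("batch_size", 2)
        kw.setdefault("lr_g", 1e-4)
        kw.setdefault("lr_d", 4e-4)
        kw.setdefault("equalized_lr", True)
        return cls(phase=HS_CGAN, **kw)


@dataclasses.dataclass(frozen=True)
class BandMap:
    """Which trimmed-axis bands inherit the pretrained R, G, B channel weights."""

    rgb_to_band: dict  # {"red": i, "green": j, "blue": k}

    def __post_init__(self):
        keys = set(self.rgb_to_band)
        if keys != {"red", "green", "blue"}:
            raise ValueError("band map needs exactly red/green/blue entries")
        idx = list(self.rgb_to_band.values())
        if len(set(idx)) != 3 or any(i < 0 for i in idx):
            raise ValueError("band indices must be three distinct nonnegative ints")

    @classmethod
    def from_axis(cls, axis: hsi_data.SpectralAxis,
                  rgb_wavelengths_nm=(630.0, 532.0, 465.0)) -> "BandMap":
        r, g, b = (axis.nearest_band(w) for w in rgb_wavelengths_nm)
        # a short axis can collapse neighbours; nudge to keep indices distinct
        if len({r, g, b}) != 3:
            raise ValueError("axis too coarse to resolve distinct R/G/B bands")
        return cls({"red": r, "green": g, "blue": b})


def _bce(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. p."""
    p = np.clip(p, _EPS, 1 - _EPS)
    loss = float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))
    grad = (p - t) / (p * (1 - p)) / p.size
    return loss, grad


def swap_labels(targets: np.ndarray, fraction: float = 0.05,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Flip real/fake roles (t -> 1 - t) independently with the given probability."""
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    targets = np.asarray(targets, dtype=float)
    if fraction == 0:
        return targets.copy()
    if rng is None:
        rng = np.random.default_rng()
    flip = rng.random(targets.shape) < fraction
    return np.where(flip, 1.0 - targets, targets)


def _draw_targets(n: int, real: bool, config: TrainConfig,
                  rng: np.random.Generator) -> np.ndarray:
    if config.target_smoothing:
        lo, hi = (0.7, 1.0) if real else (0.0, 0.3)
        return rng.uniform(lo, hi, n)
    return np.full(n, 1.0 if real else 0.0)


def _sample_fake_conditions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smoothed condition values for generated samples, classes balanced."""
    cls = rng.random(n) < 0.5
    lo = np.where(cls, 0.7, 0.0)
    return lo + rng.uniform(0, 0.3, n)


def adversarial_step(G: Generator, D: Discriminator, real_batch: np.ndarray,
                     config: TrainConfig, rng: np.random.Generator,
                     opt_g: nn.Adam | None = None, opt_d: nn.Adam | None = None,
                     real_labels: np.ndarray | None = None,
                     mask_targets: np.ndarray | None = None,
                     step_index: int = 0) -> tuple[float, float]:
    """One discriminator update followed by one generator update.

    ``real_batch`` is (n, C, H, W) in [-1, 1].  ``real_labels`` carries the
    smoothed class values when the pair is conditional.  ``mask_targets``
    (n, H, W in {0,1}) activates the optional auxiliary mask-reconstruction
    term when ``config.mask_aux_coeff`` > 0.
    """
    if opt_g is None:
        opt_g = nn.Adam(config.lr_g, config.betas, l2=config.l2_coeff)
    if opt_d is None:
        opt_d = nn.Adam(config.lr_d, config.betas, l2=config.l2_coeff)
    n = real_batch.shape[0]
    conditional = G.spec.conditional

    z = gan_core.sample_latent(n, G.spec.latent_dim, rng)
    fake_labels = _sample_fake_conditions(n, rng) if conditional else None
    d_labels_real = real_labels if D.spec.conditional else None
    d_labels_fake = fake_labels if D.spec.conditional else None

    fake = G.forward(z, labels=fake_labels, train=True)

    # --- discriminator update -------------------------------------------
    t_real = swap_labels(_draw_targets(n, True, config, rng),
                         config.label_swap_fraction, rng)
    t_fake = swap_labels(_draw_targets(n, False, config, rng),
                         config.label_swap_fraction, rng)
    p_real = D.forward(real_batch, labels=d_labels_real, train=True)
    loss_real, g_real = _bce(p_real, t_real)
    D.backward(g_real)
    grads_real = {k: v.copy() for k, v in D.grads().items()}
    p_fake = D.forward(fake, labels=d_labels_fake, train=True)
    loss_fake, g_fake = _bce(p_fake, t_fake)
    D.backward(g_fake)
    d_grads = {k: grads_real[k] + v for k, v in D.grads().items()}
    loss_d = loss_real + loss_fake
    if (config.matching_aware and D.spec.conditional
            and real_labels is not None):
        # real cubes paired with the opposite class's label range are fakes:
        # the discriminator must consult the label, which is what transmits
        # class information to the generator
        t_mis = swap_labels(_draw_targets(n, False, config, rng),
                            config.label_swap_fraction, rng)
        p_mis = D.forward(real_batch, labels=1.0 - np.asarray(real_labels),
                          train=True)
        loss_mis, g_mis = _bce(p_mis, t_mis)
        D.backward(g_mis)
        d_grads = {k: d_grads[k] + v for k, v in D.grads().items()}
        loss_d += loss_mis
    if not np.isfinite(loss_d):
        raise TrainingDivergenceError(f"discriminator loss diverged at step {step_index}")
    opt_d.step(D.params(), d_grads)

    # --- generator update (non-saturating) ------------------------------
    z2 = gan_core.sample_latent(n, G.spec.latent_dim, rng)
    fake_labels2 = _sample_fake_conditions(n, rng) if conditional else None
    fake2 = G.forward(z2, labels=fake_labels2, train=True)
    p_gen = D.forward(fake2, labels=(fake_labels2 if D.spec.conditional else None),
                      train=True)
    loss_g, g_gen = _bce(p_gen, np.ones(n))
    dx = D.backward(g_gen)
    if config.mask_aux_coeff > 0 and mask_targets is not None:
        mch = fake2[:, -1]  # tanh-range mask channel
        pm = np.clip((mch + 1) / 2, _EPS, 1 - _EPS)
        tm = mask_targets.astype(float)
        loss_mask = float(-np.mean(tm * np.log(pm) + (1 - tm) * np.log(1 - pm)))
        loss_g += config.mask_aux_coeff * loss_mask
        dmask = config.mask_aux_coeff * (pm - tm) / (pm * (1 - pm)) / pm.size / 2.0
        dx[:, -1] += dmask
    if not np.isfinite(loss_g):
        raise TrainingDivergenceError(f"generator loss diverged at step {step_index}")
    G.backward(dx)
    opt_g.step(G.params(), G.grads())
    return loss_d, loss_g


class GANTrainer:
    """Owns the optimizer state across steps of one training phase."""

    def __init__(self, G: Generator, D: Discriminator, config: TrainConfig):
        self.G, self.D, self.config = G, D, config
        self.opt_g = nn.Adam(config.lr_g, config.betas, l2=config.l2_coeff)
        self.opt_d = nn.Adam(config.lr_d, config.betas, l2=config.l2_coeff)
        self.step_count = 0

    def step(self, real_batch, rng, real_labels=None, mask_targets=None):
        out = adversarial_step(
            self.G, self.D, real_batch, self.config, rng,
            opt_g=self.opt_g, opt_d=self.opt_d, real_labels=real_labels,
            mask_targets=mask_targets, step_index=self.step_count)
        self.step_count += 1
        return out


def _load_rgb_folder(folder, size: int) -> np.ndarray:
    """All images in a folder as an (n, 3, size, size) array in [-1, 1]."""
    from PIL import Image

    folder = pathlib.Path(folder)
    paths = sorted(p for p in folder.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".bmp"))
    if not paths:
        raise ValueError(f"no images found in {folder}")
    imgs = []
    for p in paths:
        with Image.open(p) as im:
            arr = np.asarray(im.convert("RGB").resize((size, size)), dtype=float)
        imgs.append(arr.transpose(2, 0, 1) / 127.5 - 1.0)
    return np.stack(imgs)


def pretrain_rgb(image_folder, config: TrainConfig,
                 gen_spec: GeneratorSpec | None = None,
                 disc_spec: DiscriminatorSpec | None = None,
                 checkpoint_path=None, log=None) -> tuple[Generator, Discriminator]:
    """Train a 3-channel GAN pair on an RGB image folder."""
    if config.phase != RGB_PRETRAIN:
        raise ValueError(f"config phase must be {RGB_PRETRAIN!r}, got {config.phase!r}")
    if gen_spec is None:
        gen_spec = GeneratorSpec(out_channels=3, equalized_lr=config.equalized_lr)
    if disc_spec is None:
        disc_spec = DiscriminatorSpec(in_channels=3, equalized_lr=config.equalized_lr)
    if gen_spec.out_channels != 3 or disc_spec.in_channels != 3:
        raise ValueError("RGB pretraining requires 3-channel specs")
    data = _load_rgb_folder(image_folder, gen_spec.out_height)
    G = Generator(gen_spec, rng_seed=stream(config.seed, "init_g").integers(2**31))
    D = Discriminator(disc_spec, rng_seed=stream(config.seed, "init_d").integers(2**31))
    trainer = GANTrainer(G, D, config)
    order_rng = stream(config.seed, "order")
    step_rng = stream(config.seed, "steps")
    for epoch in range(config.epochs):
        idx = order_rng.permutation(len(data))
        losses = []
        for start in range(0, len(data), config.batch_size):
            batch = data[idx[start : start + config.batch_size]]
            losses.append(trainer.step(batch, step_rng))
        if log is not None:
            ld, lg = np.mean(losses, axis=0)
            log.append({"epoch": epoch, "loss_d": float(ld), "loss_g": float(lg)})
    if checkpoint_path is not None:
        gan_core.save_checkpoint(checkpoint_path, G, D, {"phase": RGB_PRETRAIN})
    return G, D


def _conv_layers(model) -> list:
    return [l for l in model.net.layers
            if isinstance(l, (nn.Conv2d, nn.ConvTranspose2d))]


def transfer_weights(G_rgb: Generator, D_rgb: Discriminator,
                     hs_gen_spec: GeneratorSpec, hs_disc_spec: DiscriminatorSpec,
                     band_map: BandMap, rng_seed: int) -> tuple[Generator, Discriminator]:
    """Channel-mapped transfer from the RGB pair to a hyperspectral pair.

    Interior layers are copied verbatim.  In the generator's output layer the
    weight slices that produce the mapped red/green/blue bands are copied
    from the RGB model's 3 output channels; in the discriminator's input
    layer the slices consuming those bands are copied likewise.  All other
    new-channel parameters keep their fresh pseudorandom initialization.
    """
    if (G_rgb.spec.out_height, G_rgb.spec.out_width) != (
            hs_gen_spec.out_height, hs_gen_spec.out_width):
        raise ValueError("RGB and HS generator specs differ beyond the channel layers")
    if (D_rgb.spec.in_height, D_rgb.spec.in_width) != (
            hs_disc_spec.in_height, hs_disc_spec.in_width):
        raise ValueError("RGB and HS discriminator specs differ beyond the channel layers")

    G_hs = Generator(hs_gen_spec, rng_seed=rng_seed)
    D_hs = Discriminator(hs_disc_spec, rng_seed=rng_seed + 1)

    order = [band_map.rgb_to_band["red"], band_map.rgb_to_band["green"],
             band_map.rgb_to_band["blue"]]
    nb = max(order)
    if nb >= hs_gen_spec.out_channels or nb >= hs_disc_spec.in_channels:
        raise ValueError("band map index outside the HS channel range")

    # ---- generator: copy everything except the first and last stages ----
    g_src = _conv_layers(G_rgb)
    g_dst = _conv_layers(G_hs)
    if len(g_src) != len(g_dst):
        raise ValueError("generator stage counts differ")
    _copy_matching(G_rgb, G_hs, skip=(g_dst[0], g_dst[-1]),
                   skip_src=(g_src[0], g_src[-1]))
    # input stage: a conditional upgrade adds one latent channel; copy the
    # overlapping slice, leave the new label channel freshly initialized
    if g_src[0].w.shape[1:] != g_dst[0].w.shape[1:]:
        raise ValueError("generator first-stage widths differ beyond the latent dim")
    cin = min(g_src[0].w.shape[0], g_dst[0].w.shape[0])
    g_dst[0].w[:cin] = g_src[0].w[:cin]
    g_dst[0].b[...] = g_src[0].b
    # output layer: W is (cin, cout, k, k); slice the mapped output channels
    if g_src[-1].w.shape[0] != g_dst[-1].w.shape[0]:
        raise ValueError("generator output-stage input widths differ")
    for rgb_idx, band_idx in enumerate(order):
        g_dst[-1].w[:, band_idx] = g_src[-1].w[:, rgb_idx]
        g_dst[-1].b[band_idx] = g_src[-1].b[rgb_idx]

    # ---- discriminator: copy everything except the first conv -----------
    d_src = _conv_layers(D_rgb)
    d_dst = _conv_layers(D_hs)
    if len(d_src) != len(d_dst):
        raise ValueError("discriminator stage counts differ")
    _copy_matching(D_rgb, D_hs, skip=(d_dst[0],), skip_src=(d_src[0],))
    # input layer: W is (cout, cin, k, k); slice the mapped input channels
    for rgb_idx, band_idx in enumerate(order):
        d_dst[0].w[:, band_idx] = d_src[0].w[:, rgb_idx]
    d_dst[0].b[...] = d_src[0].b
    return G_hs, D_hs


def _copy_matching(src_model, dst_model, skip=(), skip_src=()):
    """Copy parameters of structurally matching layers (shapes must agree)."""
    src_layers = [l for l in src_model.net.layers if l.params()]
    dst_layers = [l for l in dst_model.net.layers if l.params()]
    if len(src_layers) != len(dst_layers):
        raise ValueError("models have different trainable-layer counts")
    for s, d in zip(src_layers, dst_layers):
        if d in skip or s in skip_src:
            continue
        sp, dp = s.params(), d.params()
        for k in dp:
            if sp[k].shape != dp[k].shape:
                raise ValueError(
                    f"interior layer parameter {k} differs in shape: "
                    f"{sp[k].shape} vs {dp[k].shape}")
            dp[k][...] = sp[k]


def cubes_to_batch(cubes: list[HSCube], with_mask: bool) -> np.ndarray:
    """Stack cubes as (n, C, H, W) in [-1, 1]; optional trailing mask channel."""
    arrs = []
    for c in cubes:
        x = np.moveaxis(c.data, 2, 0) * 2.0 - 1.0
        if with_mask:
            if c.mask is None:
                raise ValueError(f"cube {c.id!r} has no mask for the mask channel")
            x = np.concatenate([x, c.mask[None].astype(float) * 2.0 - 1.0], axis=0)
        arrs.append(x)
    return np.stack(arrs)


def train_hs(dataset: list[HSCube], config: TrainConfig, G: Generator,
             D: Discriminator, checkpoint_path=None, log_csv=None,
             verbose: bool = False) -> list[dict]:
    """Conditional-GAN training on a labeled cube dataset.

    Returns a per-epoch log of mean losses, with a deterministic-embedding
    FID against the training set every ``config.fid_every`` epochs.
    """
    from . import evaluation

    if config.phase != HS_CGAN:
        raise ValueError(f"config phase must be {HS_CGAN!r}, got {config.phase!r}")
    if not dataset:
        raise ValueError("empty dataset")
    shapes = {c.data.shape for c in dataset}
    if len(shapes) != 1:
        raise ValueError(f"cubes must share one shape, found {shapes}")
    if G.spec.conditional and any(c.label is None for c in dataset):
        raise ValueError("conditional training requires labels on every cube")

    bands = dataset[0].axis.band_count
    with_mask = G.spec.out_channels == bands + 1
    data = cubes_to_batch(dataset, with_mask)
    masks = (np.stack([c.mask for c in dataset]) if with_mask else None)
    classes = [c.label for c in dataset]

    trainer = GANTrainer(G, D, config)
    order_rng = stream(config.seed, "order")
    step_rng = stream(config.seed, "steps")
    label_rng = stream(config.seed, "labels")
    eval_rng_seed = int(stream(config.seed, "eval").integers(2**31))
    axis = dataset[0].axis
    logs = []
    for epoch in range(config.epochs):
        # smoothing targets are re-drawn every epoch
        label_vals = np.array([smooth_label(c, label_rng).value for c in classes])
        idx = order_rng.permutation(len(data))
        losses = []
        for start in range(0, len(data), config.batch_size):
            sel = idx[start : start + config.batch_size]
            losses.append(trainer.step(
                data[sel], step_rng,
                real_labels=label_vals[sel] if G.spec.conditional else None,
                mask_targets=masks[sel] if masks is not None else None))
        ld, lg = (float(v) for v in np.mean(losses, axis=0))
        entry = {"epoch": epoch, "steps": len(losses), "loss_d": ld,
                 "loss_g": lg, "fid": None}
        if config.fid_every and (epoch % config.fid_every == 0
                                 or epoch == config.epochs - 1):
            entry["fid"] = evaluation.fid_against_dataset(
                G, dataset, axis, seed=eval_rng_seed)
        logs.append(entry)
        if verbose:
            fid_s = f" fid={entry['fid']:.4g}" if entry["fid"] is not None else ""
            print(f"epoch {epoch}: loss_d={ld:.4f} loss_g={lg:.4f}{fid_s}",
                  file=sys.stderr)
    if log_csv is not None:
        with open(log_csv, "w", newline="") as f:
            writer = csv.DictWriter(
                f, fieldnames=["epoch", "steps", "loss_d", "loss_g", "fid"])
            writer.writeheader()
            writer.writerows(logs)
    if checkpoint_path is not None:
        gan_core.save_checkpoint(checkpoint_path, G, D, {"phase": HS_CGAN})
    return logs
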