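"""Compact residual CNN for benign/malignant cube classification.

Used by the fidelity protocol (train on synthetic, test on real).  The
network is trained from scratch — no pretrained weights — with a stem
convolution, four residual blocks (two of them downsampling), global
average pooling and a sigmoid head.  The pooled activations double as the
optional CNN feature embedding for FID.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .hsi_data import HSCube, MALIGNANT


class ResidualBlock(nn.Layer):
    """conv-BN-ReLU-conv-BN plus identity (or 1x1 projection) skip, ReLU."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.project = cin != cout or stride != 1
        if self.project:
            self.skip_conv = nn.Conv2d(cin, cout, 1, stride, 0, rng)
        self._sublayers = [self.conv1, self.bn1, self.conv2, self.bn2] + (
            [self.skip_conv] if self.project else [])

    def forward(self, x, train=True):
        f = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train)),
            train), train)
        s = self.skip_conv.forward(x, train) if self.project else x
        self._mask = (f + s) > 0
        return (f + s) * self._mask

    def backward(self, grad):
        grad = grad * self._mask
        df = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(grad)))))
        ds = self.skip_conv.backward(grad) if self.project else grad
        return df + ds

    def params(self):
        out = {}
        for i, l in enumerate(self._sublayers):
            for k, v in l.params().items():
                out[f"{i}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for i, l in enumerate(self._sublayers):
            for k, v in l.grads().items():
                out[f"{i}.{k}"] = v
        return out


@dataclasses.dataclass
class ClassifierConfig:
    width: int = 16
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    l2: float = 0.0
    seed: int = 0
    stop_at_full_train_accuracy: bool = True


class CompactResNet:
    """Stem + 4 residual blocks + global average pool + sigmoid head."""

    def __init__(self, in_channels: int, config: ClassifierConfig):
        w = config.width
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.body = nn.Sequential([
            nn.Conv2d(in_channels, w, 3, 1, 1, rng),
            nn.BatchNorm2d(w),
            nn.ReLU(),
            ResidualBlock(w, w, 1, rng),
            ResidualBlock(w, 2 * w, 2, rng),
            ResidualBlock(2 * w, 2 * w, 1, rng),
            ResidualBlock(2 * w, 4 * w, 2, rng),
            nn.GlobalAvgPool(),
        ])
        self.head = nn.Dense(4 * w, 1, rng)
        self.sigmoid = nn.Sigmoid()

    def forward(self, x, train=True):
        self._feat = self.body.forward(x, train=train)
        return self.sigmoid.forward(self.head.forward(self._feat, train), train)[:, 0]

    def features(self, x) -> np.ndarray:
        """Penultimate (pooled) activations, evaluation mode."""
        return self.body.forward(x, train=False)

    def backward(self, grad):
        g = self.head.backward(self.sigmoid.backward(grad[:, None]))
        return self.body.backward(g)

    def params(self):
        p = {f"body.{k}": v for k, v in self.body.params().items()}
        p.update({f"head.{k}": v for k, v in self.head.params().items()})
        return p

    def grads(self):
        g = {f"body.{k}": v for k, v in self.body.grads().items()}
        g.update({f"head.{k}": v for k, v in self.head.grads().items()})
        return g

    def predict_proba(self, x, batch_size: int = 64) -> np.ndarray:
        out = [self.forward(x[i : i + batch_size], train=False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out)


def cubes_to_xy(cubes: list[HSCube]) -> tuple[np.ndarray, np.ndarray]:
    """Cubes -> ((n, B, H, W) array in [-1, 1], 0/1 labels; malignant = 1)."""
    x = np.stack([np.moveaxis(c.data, 2, 0) for c in cubes]) * 2.0 - 1.0
    y = np.array([1.0 if c.label == MALIGNANT else 0.0 for c in cubes])
    return x, y


def train_classifier(cubes: list[HSCube], config: ClassifierConfig,
                     log: list | None = None) -> tuple[CompactResNet, float]:
    """Adam training on labeled cubes; returns (model, final train accuracy %).

    Training runs for up to ``config.epochs`` epochs and stops early once
    the training set is fit perfectly (the protocol's overfitting regime).
    """
    if any(c.label is None for c in cubes):
        raise ValueError("all training cubes must be labeled")
    x, y = cubes_to_xy(cubes)
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = CompactResNet(x.shape[1], config)
    opt = nn.Adam(config.lr, config.betas, l2=config.l2)
    rng = np.random.default_rng(config.seed + 1)
    eps = 1e-7
    train_acc = 0.0
    for epoch in range(config.epochs):
        idx = rng.permutation(len(x))
        losses = []
        for s in range(0, len(x), config.batch_size):
            sel = idx[s : s + config.batch_size]
            p = np.clip(model.forward(x[sel], train=True), eps, 1 - eps)
            t = y[sel]
            losses.append(float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p))))
            model.backward((p - t) / (p * (1 - p)) / p.size)
            opt.step(model.params(), model.grads())
        pred = model.predict_proba(x) > 0.5
        train_acc = float(np.mean(pred == (y > 0.5)) * 100.0)
        if log is not None:
            log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "train_accuracy": train_acc})
        if config.stop_at_full_train_accuracy and train_acc >= 100.0:
            break
    return model, train_acc
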