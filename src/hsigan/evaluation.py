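"""Evaluation suite: FID, confusion-matrix metrics, Jensen-Shannon spectral
divergence, signature summaries, and the train-on-synthetic/test-on-real
fidelity protocol.

FID between two image sets fits a Gaussian (mu, Sigma) to a feature
embedding of each set and reports

    ||mu1 - mu2||^2 + Tr(Sigma1 + Sigma2 - 2 (Sigma1 Sigma2)^{1/2}).

The canonical embedding for RGB images is an Inception network; no such
standard exists for 116-band cubes and no pretrained weights are shipped,
so the default embedding here is a deterministic spectral-statistics vector
(per-band spatial mean, spatial sd, and lesion/background contrast — 3B
features, bit-reproducible).  Absolute values are therefore not comparable
across embeddings; only FIDs computed with the same embedding compare.

The Jensen-Shannon divergence uses base-2 logarithms so it is bounded by 1;
spectral signatures are L1-normalized into distributions before comparison.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import gan_core
from .classifier import ClassifierConfig, CompactResNet, cubes_to_xy, train_classifier
from .hsi_data import CLASSES, HSCube, SpectralAxis

DETERMINISTIC_STATS = "deterministic_stats"
CNN = "cnn"


class NumericalError(ArithmeticError):
    """A matrix was indefinite beyond tolerance."""


@dataclasses.dataclass
class FeatureMoments:
    """Gaussian fit (mean, covariance) to a feature embedding of an image set."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.ndim != 1 or self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("inconsistent moment dimensions")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @classmethod
    def from_features(cls, feats: np.ndarray) -> "FeatureMoments":
        feats = np.asarray(feats, dtype=float)
        if feats.ndim != 2 or feats.shape[0] < 2:
            raise ValueError("need a (n >= 2) x d feature matrix")
        mu = feats.mean(axis=0)
        sigma = np.cov(feats, rowvar=False)
        sigma = np.atleast_2d(sigma)
        return cls(mu=mu, sigma=(sigma + sigma.T) / 2, n=feats.shape[0])


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true, bool)
        p = np.asarray(y_pred, bool)
        if t.shape != p.shape:
            raise ValueError("prediction/label lengths differ")
        return cls(tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
                   fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)))


@dataclasses.dataclass(frozen=True)
class SpectralDistribution:
    """Per-band nonnegative vector summing to one."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("distribution must be a non-empty vector")
        if (v < 0).any():
            raise ValueError("distribution has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"distribution sums to {v.sum()!r}, not 1")

    @classmethod
    def from_signature(cls, signature: np.ndarray) -> "SpectralDistribution":
        """L1-normalize a nonnegative spectral signature into a distribution."""
        s = np.asarray(signature, dtype=float)
        total = s.sum()
        if total <= 0:
            raise ValueError("signature must have positive mass")
        return cls(s / total)


def embed(cubes: list[HSCube], extractor: str = DETERMINISTIC_STATS,
          model: CompactResNet | None = None) -> np.ndarray:
    """Feature matrix (one row per cube).

    ``deterministic_stats``: per-band spatial mean, spatial sd and
    lesion/background contrast (zero when no mask), 3B features,
    bit-reproducible.  ``cnn``: pooled penultimate activations of a trained
    fidelity classifier (pass ``model``).
    """
    if not cubes:
        raise ValueError("empty cube list")
    shapes = {c.data.shape for c in cubes}
    if len(shapes) != 1:
        raise ValueError(f"cubes must share one shape, found {shapes}")
    if extractor == DETERMINISTIC_STATS:
        rows = []
        for c in cubes:
            mean = c.data.mean(axis=(0, 1))
            sd = c.data.std(axis=(0, 1))
            if c.mask is not None and 0 < c.mask.sum() < c.mask.size:
                inside = c.data[c.mask == 1].mean(axis=0)
                outside = c.data[c.mask == 0].mean(axis=0)
                contrast = inside - outside
            else:
                contrast = np.zeros_like(mean)
            rows.append(np.concatenate([mean, sd, contrast]))
        return np.stack(rows)
    if extractor == CNN:
        if model is None:
            raise ValueError("cnn embedding requires a trained classifier model")
        x, _ = cubes_to_xy(cubes)
        return model.features(x)
    raise ValueError(f"unknown extractor {extractor!r}")


def _sqrtm_psd(mat: np.ndarray, tol: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2)
    if vals.min() < -tol:
        raise NumericalError(
            f"matrix indefinite beyond tolerance (min eigenvalue {vals.min():.3e})")
    vals = np.clip(vals, 0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(a: FeatureMoments, b: FeatureMoments) -> float:
    """Frechet distance between the two Gaussian moment fits."""
    if a.mu.size != b.mu.size:
        raise ValueError("feature dimensions differ")
    if a.n < 2 or b.n < 2:
        raise ValueError("need at least 2 samples per set")
    scale = max(1.0, float(np.trace(a.sigma) + np.trace(b.sigma)))
    tol = 1e-8 * scale
    s1 = _sqrtm_psd(a.sigma, tol)
    inner = s1 @ b.sigma @ s1
    vals = np.linalg.eigvalsh((inner + inner.T) / 2)
    if vals.min() < -tol * scale:
        raise NumericalError(
            f"covariance product indefinite (min eigenvalue {vals.min():.3e})")
    tr_sqrt = np.sqrt(np.clip(vals, 0, None)).sum()
    diff = a.mu - b.mu
    val = float(diff @ diff + np.trace(a.sigma) + np.trace(b.sigma) - 2 * tr_sqrt)
    return max(val, 0.0)


def metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall and F1 in percent (2 decimals).

    A metric whose denominator vanishes is reported as None and listed
    under ``undefined`` instead of raising.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    out: dict = {"undefined": []}

    def pct(num, den, name):
        if den == 0:
            out["undefined"].append(name)
            return None
        return round(100.0 * num / den, 2)

    out["accuracy"] = pct(cm.tp + cm.tn, cm.total, "accuracy")
    out["precision"] = pct(cm.tp, cm.tp + cm.fp, "precision")
    out["recall"] = pct(cm.tp, cm.tp + cm.fn, "recall")
    if out["precision"] is None or out["recall"] is None or \
            (out["precision"] + out["recall"]) == 0:
        out["undefined"].append("f1")
        out["f1"] = None
    else:
        p, r = cm.tp / (cm.tp + cm.fp), cm.tp / (cm.tp + cm.fn)
        out["f1"] = round(100.0 * 2 * p * r / (p + r), 2)
    return out


def js_divergence(v, w) -> float:
    """Base-2 Jensen-Shannon divergence between two distributions, in [0, 1]."""
    if not isinstance(v, SpectralDistribution):
        v = SpectralDistribution(np.asarray(v, dtype=float))
    if not isinstance(w, SpectralDistribution):
        w = SpectralDistribution(np.asarray(w, dtype=float))
    a, b = v.values, w.values
    if a.size != b.size:
        raise ValueError("distributions must share length")

    def xlogx(x):
        out = np.zeros_like(x)
        nz = x > 0
        out[nz] = x[nz] * np.log2(x[nz])
        return out

    val = 0.5 * np.sum(xlogx(a) + xlogx(b) - xlogx(a + b) - (a + b) * np.log2(0.5))
    # identity: xlogx(a+b) + (a+b)log2(1/2) == (a+b) log2((a+b)/2)
    return float(min(max(val, 0.0), 1.0))


def spectral_signature(cubes: list[HSCube], region: str = "lesion",
                       class_filter: str | None = None):
    """Pixel-pooled per-band (mean, sd, mean-2sd, mean+2sd) over a region.

    ``region`` is "lesion" (mask == 1), "skin" (mask == 0) or "all".
    """
    if class_filter is not None:
        cubes = [c for c in cubes if c.label == class_filter]
    if region not in ("lesion", "skin", "all"):
        raise ValueError(f"unknown region {region!r}")
    pixels = []
    for c in cubes:
        if region == "all":
            pixels.append(c.data.reshape(-1, c.data.shape[2]))
            continue
        if c.mask is None:
            raise ValueError(f"cube {c.id!r} has no mask; cannot select {region}")
        sel = c.mask == (1 if region == "lesion" else 0)
        if sel.any():
            pixels.append(c.data[sel])
    if not pixels:
        raise ValueError("empty region selection")
    pooled = np.concatenate(pixels, axis=0)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    return mean, sd, mean - 2 * sd, mean + 2 * sd


def fidelity_protocol(synthetic_train: list[HSCube], real_test: list[HSCube],
                      classifier_config: ClassifierConfig | None = None) -> dict:
    """Train a compact residual CNN on synthetic cubes only; score real ones.

    The real set never enters optimization — the trainer receives only the
    synthetic set.  Overfitting the synthetic set while classifying the real
    set well indicates the two distributions overlap.
    """
    if classifier_config is None:
        classifier_config = ClassifierConfig()
    labels_train = {c.label for c in synthetic_train}
    labels_test = {c.label for c in real_test}
    if not set(CLASSES) <= labels_train or not set(CLASSES) <= labels_test:
        raise ValueError("both sets must contain benign and malignant cubes")
    log: list = []
    model, train_acc = train_classifier(synthetic_train, classifier_config, log=log)
    x_test, y_test = cubes_to_xy(real_test)
    pred = model.predict_proba(x_test) > 0.5
    cm = ConfusionMatrix.from_predictions(y_test > 0.5, pred)
    return {
        "train_accuracy": train_acc,
        "confusion_matrix": cm,
        "metrics": metrics(cm),
        "model": model,
        "log": log,
    }


def generate_cubes(G: gan_core.Generator, n: int, axis: SpectralAxis,
                   seed, class_balance: float = 0.5) -> list[HSCube]:
    """Sample n cubes from a generator, conditioned per the class balance.

    The first floor(n * class_balance) cubes are benign-conditioned.  For a
    non-conditional generator the cubes carry no label.
    """
    if not (0 <= class_balance <= 1):
        raise ValueError("class_balance must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_benign = int(np.floor(n * class_balance))
    cubes = []
    for i in range(n):
        z = gan_core.sample_latent(1, G.spec.latent_dim, rng)
        if G.spec.conditional:
            cls = "benign" if i < n_benign else "malignant"
            lo = 0.0 if cls == "benign" else 0.7
            label_val = float(lo + rng.uniform(0, 0.3))
            out = G.forward(z, labels=np.array([label_val]), train=False)
        else:
            cls = None
            out = G.forward(z, train=False)
        sample = gan_core.FakeSample(np.moveaxis(out[0], 0, 2))
        cubes.append(gan_core.to_reflectance(sample, axis, id=f"gen_{i:04d}",
                                             label=cls))
    return cubes


def fid_against_dataset(G: gan_core.Generator, dataset: list[HSCube],
                        axis: SpectralAxis, seed,
                        extractor: str = DETERMINISTIC_STATS) -> float:
    """Deterministic-embedding FID between generated samples and a dataset."""
    fake = generate_cubes(G, len(dataset), axis, seed)
    m_real = FeatureMoments.from_features(embed(dataset, extractor))
    m_fake = FeatureMoments.from_features(embed(fake, extractor))
    return fid(m_real, m_fake)
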