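"""Parametric hyperspectral skin-lesion phantoms with known ground truth.

The clinical dataset the framework targets (76 cubes of 50 x 50 x 116,
40 benign / 36 malignant) is private; this module emulates its statistical
structure so every pipeline stage can be exercised with a known answer:

* three smooth spectral signatures (healthy skin, benign lesion, malignant
  lesion) qualitatively shaped like melanin/hemoglobin reflectance curves —
  lesions darker than skin below ~600 nm, the malignant class with a deeper
  540–580 nm trough.  The control points are package fixtures, not values
  from any measured dataset;
* blob-shaped lesion masks (perturbed ellipses) emulating manual
  segmentation;
* per-image multiplicative amplitude jitter (illumination variability,
  mean-one log-normal) and i.i.d. Gaussian band noise, followed by slight
  spatial smoothing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .hsi_data import BENIGN, MALIGNANT, CLASSES, HSCube, SpectralAxis, default_axis

SKIN = "skin"


@dataclasses.dataclass(frozen=True)
class SignatureModel:
    """Smooth per-class reflectance curve defined by control points."""

    cls: str
    control_points: tuple  # ((wavelength_nm, reflectance), ...)
    amplitude_jitter_sd: float = 0.0
    notes: str = ""

    def __post_init__(self):
        pts = tuple((float(w), float(r)) for w, r in self.control_points)
        object.__setattr__(self, "control_points", pts)
        if len(pts) < 4:
            raise ValueError("a signature needs at least 4 control points")
        wl = [w for w, _ in pts]
        if sorted(wl) != wl or len(set(wl)) != len(wl):
            raise ValueError("control wavelengths must be strictly increasing")
        if any(not (0.0 <= r <= 1.0) for _, r in pts):
            raise ValueError("control reflectances must lie in [0, 1]")
        if self.amplitude_jitter_sd < 0:
            raise ValueError("amplitude_jitter_sd must be nonnegative")


# Fixture curves (NOT digitized from any measured dataset): melanin makes
# lesions darker than skin in the blue-green, oxyhemoglobin absorption cuts a
# 540-580 nm trough that is deepest for the malignant class, and all three
# rise toward the near-infrared.
DEFAULT_SIGNATURES = {
    SKIN: SignatureModel(SKIN, (
        (440, 0.22), (500, 0.30), (540, 0.28), (560, 0.27), (580, 0.30),
        (620, 0.45), (700, 0.55), (800, 0.60), (900, 0.62), (960, 0.62),
    ), notes="healthy skin background"),
    BENIGN: SignatureModel(BENIGN, (
        (440, 0.10), (500, 0.13), (540, 0.12), (560, 0.12), (580, 0.14),
        (620, 0.24), (700, 0.38), (800, 0.46), (900, 0.50), (960, 0.51),
    ), notes="benign nevus: darker than skin, shallow green trough"),
    MALIGNANT: SignatureModel(MALIGNANT, (
        (440, 0.08), (500, 0.10), (540, 0.065), (560, 0.06), (580, 0.07),
        (620, 0.16), (700, 0.30), (800, 0.42), (900, 0.48), (960, 0.50),
    ), notes="malignant lesion: deep 540-580 nm trough"),
}


def eval_signature(model: SignatureModel, axis: SpectralAxis) -> np.ndarray:
    """Evaluate the signature on a wavelength axis (monotone-segment spline).

    PCHIP interpolation is used so the curve never overshoots the control
    values; the result therefore stays in [0, 1].
    """
    wl = np.array([w for w, _ in model.control_points])
    rf = np.array([r for _, r in model.control_points])
    ax = axis.wavelengths_nm
    if ax[0] < wl[0] or ax[-1] > wl[-1]:
        raise ValueError(
            f"axis [{ax[0]:.1f}, {ax[-1]:.1f}] nm outside control span "
            f"[{wl[0]:.1f}, {wl[-1]:.1f}]"
        )
    return PchipInterpolator(wl, rf)(ax)


@dataclasses.dataclass
class PhantomParams:
    """Geometry, signatures and noise levels of the phantom generator.

    Defaults mirror the emulated acquisition: 50 x 50 pixels, 116 bands
    (the 125-band axis with 5 + 4 noisy edge bands removed).
    """

    height: int = 50
    width: int = 50
    bands: int = 116
    axis: SpectralAxis | None = None
    signatures: dict = None
    lesion_radius_range: tuple = None  # pixels; default scales with frame
    lesion_eccentricity_range: tuple = (0.0, 0.6)
    boundary_perturbation: float = 0.15
    noise_sd: float = 0.02
    smoothness_sigma_px: float = 0.5
    amplitude_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.axis is None:
            if self.bands == 116:
                # the trimmed default camera axis (bands 5..120 of 125)
                self.axis = SpectralAxis(default_axis().wavelengths_nm[5:121])
            else:
                self.axis = SpectralAxis(np.linspace(470.0, 930.0, self.bands))
        if self.axis.band_count != self.bands:
            raise ValueError("axis band count must equal bands")
        if self.signatures is None:
            self.signatures = dict(DEFAULT_SIGNATURES)
        if self.lesion_radius_range is None:
            r = min(self.height, self.width)
            self.lesion_radius_range = (0.16 * r, 0.32 * r)
        if self.lesion_radius_range[1] >= min(self.height, self.width) / 2:
            raise ValueError("max lesion radius must be < min(height, width)/2")
        if not (0 <= self.noise_sd < 0.5):
            raise ValueError("noise_sd must be in [0, 0.5)")


def make_mask(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Single connected blob: a rotated ellipse with perturbed boundary.

    The center falls in the middle third of the frame and the lesion covers
    between 5% and 60% of the pixels (re-drawn if a perturbation ever lands
    outside that band).
    """
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(20):
        cy = rng.uniform(h / 3, 2 * h / 3)
        cx = rng.uniform(w / 3, 2 * w / 3)
        r = rng.uniform(*params.lesion_radius_range)
        ecc = rng.uniform(*params.lesion_eccentricity_range)
        theta0 = rng.uniform(0, np.pi)
        # semi-axes with equal area pi*r^2
        b_ax = r * (1 - ecc * ecc) ** 0.25
        a_ax = r / (1 - ecc * ecc) ** 0.25
        dy, dx = yy - cy, xx - cx
        u = np.cos(theta0) * dx + np.sin(theta0) * dy
        v = -np.sin(theta0) * dx + np.cos(theta0) * dy
        rad = np.sqrt((u / a_ax) ** 2 + (v / b_ax) ** 2)
        if params.boundary_perturbation > 0:
            ang = np.arctan2(v, u)
            wobble = np.zeros_like(ang)
            for k in (2, 3, 5):
                wobble += rng.normal(0, 1) * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
            rad = rad * (1 + params.boundary_perturbation * wobble / 3.0)
        mask = (rad <= 1.0).astype(np.uint8)
        frac = mask.mean()
        if 0.05 <= frac <= 0.6 and _connected(mask):
            return mask
    # fall back to the unperturbed ellipse, which satisfies the bounds
    return (np.sqrt((u / a_ax) ** 2 + (v / b_ax) ** 2) <= 1.0).astype(np.uint8)


def _connected(mask: np.ndarray) -> bool:
    from scipy.ndimage import label

    _, n = label(mask)
    return n == 1


def make_cube(params: PhantomParams, cls: str, rng: np.random.Generator,
              id: str = "") -> HSCube:
    """One labeled phantom cube.

    Pixel spectra are a mask-weighted mix of the lesion and skin signatures,
    scaled by a mean-one log-normal per-image jitter, plus i.i.d. Gaussian
    band noise and slight spatial smoothing; values clipped to [0, 1].
    """
    if cls not in CLASSES:
        raise ValueError(f"class must be one of {CLASSES}")
    if cls not in params.signatures:
        raise ValueError(f"no signature model for class {cls!r}")
    lesion_sig = eval_signature(params.signatures[cls], params.axis)
    skin_sig = eval_signature(params.signatures[SKIN], params.axis)
    mask = make_mask(params, rng)
    m3 = mask[:, :, None].astype(float)
    sd = params.amplitude_jitter_sd
    jitter = float(np.exp(rng.normal(-0.5 * sd * sd, sd))) if sd > 0 else 1.0
    data = jitter * (m3 * lesion_sig + (1.0 - m3) * skin_sig)
    if params.noise_sd > 0:
        data = data + rng.normal(0, params.noise_sd, data.shape)
    if params.smoothness_sigma_px > 0:
        data = gaussian_filter(data, (params.smoothness_sigma_px,
                                      params.smoothness_sigma_px, 0))
    return HSCube(data=np.clip(data, 0.0, 1.0), axis=params.axis,
                  mask=mask, label=cls, id=id)


def make_dataset(params: PhantomParams, n_benign: int = 40,
                 n_malignant: int = 36) -> list[HSCube]:
    """Reproducible labeled phantom dataset (defaults emulate 40 + 36)."""
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be nonnegative")
    seq = np.random.SeedSequence(params.seed)
    children = seq.spawn(n_benign + n_malignant)
    cubes = []
    for i in range(n_benign):
        rng = np.random.default_rng(children[i])
        cubes.append(make_cube(params, BENIGN, rng, id=f"benign_{i:04d}"))
    for j in range(n_malignant):
        rng = np.random.default_rng(children[n_benign + j])
        cubes.append(make_cube(params, MALIGNANT, rng, id=f"malignant_{j:04d}"))
    return cubes


def contrast_bands(params: PhantomParams, top_k: int = 10) -> np.ndarray:
    """Band indices where the two lesion classes differ most (ground truth)."""
    b = eval_signature(params.signatures[BENIGN], params.axis)
    m = eval_signature(params.signatures[MALIGNANT], params.axis)
    return np.argsort(np.abs(b - m))[::-1][:top_k]
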