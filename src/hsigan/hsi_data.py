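"""Hyperspectral lesion-cube data model, calibration and I/O.

A cube is a ``height x width x bands`` reflectance array with a wavelength
axis, an optional binary lesion mask and an optional benign/malignant label.
The acquisition emulated here is a VNIR snapshot camera: 125 bands over
450-950 nm at 50 x 50 pixels, with the first five and last four bands
dropped as noise, leaving 116 usable bands.

Reflectance is obtained from raw sensor counts by flat-field calibration
against a white reference (reflectance standard) and a dark reference
(closed shutter):  R = (raw - dark) / (white - dark).
"""

from __future__ import annotations

import dataclasses
import pathlib

import h5py
import numpy as np

BENIGN = "benign"
MALIGNANT = "malignant"
CLASSES = (BENIGN, MALIGNANT)

#: smoothed-label target intervals per class
LABEL_RANGES = {BENIGN: (0.0, 0.3), MALIGNANT: (0.7, 1.0)}


class DimensionError(ValueError):
    """Array shapes are inconsistent."""


class DegenerateReferenceError(ValueError):
    """white - dark vanishes somewhere; calibration undefined there."""


class EmptyCubeError(ValueError):
    """A band trim would remove every band."""


class FormatError(ValueError):
    """A file on disk does not match the expected layout."""


@dataclasses.dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing band-center wavelengths in nm."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise DimensionError("wavelengths must be a non-empty 1-D sequence")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl.min() <= 300 or wl.max() >= 1100:
            raise ValueError("wavelengths must lie in (300, 1100) nm")

    @property
    def band_count(self) -> int:
        return int(self.wavelengths_nm.size)

    def nearest_band(self, wavelength_nm: float) -> int:
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside axis range "
                f"[{wl[0]:.1f}, {wl[-1]:.1f}]"
            )
        return int(np.argmin(np.abs(wl - wavelength_nm)))

    def __eq__(self, other):
        return isinstance(other, SpectralAxis) and np.array_equal(
            self.wavelengths_nm, other.wavelengths_nm
        )


def default_axis(bands: int = 125, lo_nm: float = 450.0, hi_nm: float = 950.0) -> SpectralAxis:
    """Linear wavelength grid emulating the snapshot camera (125 bands, 450-950 nm)."""
    return SpectralAxis(np.linspace(lo_nm, hi_nm, bands))


@dataclasses.dataclass
class HSCube:
    """Calibrated reflectance cube with optional mask and class label."""

    data: np.ndarray  # (H, W, B) float
    axis: SpectralAxis
    mask: np.ndarray | None = None  # (H, W) in {0,1}
    label: str | None = None
    id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != self.axis.band_count:
            raise DimensionError(
                f"band dimension {self.data.shape[2]} != axis band count "
                f"{self.axis.band_count}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains NaN/Inf")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape[:2]:
                raise DimensionError("mask shape does not match spatial dims")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask must be binary")
            self.mask = self.mask.astype(np.uint8)
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def shape(self):
        return self.data.shape


@dataclasses.dataclass(frozen=True)
class SmoothedLabel:
    """Class label smoothed into [0,0.3] (benign) or [0.7,1] (malignant)."""

    value: float
    class_of_origin: str

    def __post_init__(self):
        if self.class_of_origin not in CLASSES:
            raise ValueError(f"unknown class {self.class_of_origin!r}")
        lo, hi = LABEL_RANGES[self.class_of_origin]
        if not (lo <= self.value <= hi):
            raise ValueError(
                f"{self.class_of_origin} label {self.value} outside [{lo}, {hi}]"
            )


def calibrate(raw: np.ndarray, white: np.ndarray, dark: np.ndarray,
              axis: SpectralAxis | None = None, clip_max: float = 2.0) -> HSCube:
    """Flat-field calibration (raw - dark) / (white - dark).

    Values are clipped to [0, clip_max] to bound specular artifacts; the
    default cap of 2 keeps the later tanh scaling well-defined.
    """
    raw = np.asarray(raw, dtype=float)
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if not (raw.shape == white.shape == dark.shape):
        raise DimensionError(
            f"raw {raw.shape}, white {white.shape}, dark {dark.shape} differ"
        )
    denom = white - dark
    zeros = np.argwhere(denom == 0)
    if zeros.size:
        voxel = tuple(int(v) for v in zeros[0])
        raise DegenerateReferenceError(
            f"white - dark is zero at voxel {voxel} ({zeros.shape[0]} voxels total)"
        )
    refl = np.clip((raw - dark) / denom, 0.0, clip_max)
    if axis is None:
        axis = default_axis(raw.shape[2])
    return HSCube(data=refl, axis=axis)


def trim_bands(cube: HSCube, head: int = 5, tail: int = 4) -> HSCube:
    """Drop noisy leading/trailing bands (default 5 + 4: 125 -> 116)."""
    b = cube.axis.band_count
    if head < 0 or tail < 0:
        raise ValueError("head and tail must be nonnegative")
    if head + tail >= b:
        raise EmptyCubeError(f"trimming {head}+{tail} bands of {b} leaves nothing")
    stop = b - tail
    return HSCube(
        data=cube.data[:, :, head:stop],
        axis=SpectralAxis(cube.axis.wavelengths_nm[head:stop]),
        mask=None if cube.mask is None else cube.mask.copy(),
        label=cube.label,
        id=cube.id,
    )


def smooth_label(cls: str, rng: np.random.Generator | int) -> SmoothedLabel:
    """Draw a smoothed target uniformly within the class interval."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = LABEL_RANGES[cls]
    return SmoothedLabel(value=float(rng.uniform(lo, hi)), class_of_origin=cls)


def pseudo_rgb(cube: HSCube, rgb_wavelengths_nm=(630.0, 532.0, 465.0)) -> np.ndarray:
    """Render the cube as an RGB image from the bands nearest three wavelengths.

    The three channels are min-max scaled jointly so relative brightness
    between channels is preserved.
    """
    idx = [cube.axis.nearest_band(w) for w in rgb_wavelengths_nm]
    img = cube.data[:, :, idx]
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.full_like(img, 0.5)
    return img


# ---------------------------------------------------------------------------
# I/O: one HDF5 container per dataset; ENVI header + BSQ raw file per cube.

def write_hdf5(cubes: list[HSCube], path) -> None:
    path = pathlib.Path(path)
    if cubes:
        axis = cubes[0].axis
        for c in cubes[1:]:
            if c.axis != axis:
                raise DimensionError("all cubes in a dataset must share a spectral axis")
    with h5py.File(path, "w") as f:
        grp = f.create_group("cubes")
        for i, c in enumerate(cubes):
            cid = c.id or f"cube_{i:04d}"
            g = grp.create_group(cid)
            g.create_dataset("data", data=c.data)
            if c.mask is not None:
                g.create_dataset("mask", data=c.mask)
            if c.label is not None:
                g.attrs["label"] = c.label
            g.attrs["wavelengths_nm"] = c.axis.wavelengths_nm


def read_hdf5(path) -> list[HSCube]:
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cubes = []
    with h5py.File(path, "r") as f:
        if "cubes" not in f:
            raise FormatError(f"{path.name}: missing /cubes group")
        for cid in sorted(f["cubes"]):
            g = f["cubes"][cid]
            if "data" not in g:
                raise FormatError(f"{path.name}: /cubes/{cid} missing data array")
            data = g["data"][...]
            wl = g.attrs.get("wavelengths_nm")
            if wl is None:
                raise FormatError(f"{path.name}: /cubes/{cid} missing wavelengths_nm")
            mask = g["mask"][...] if "mask" in g else None
            label = g.attrs.get("label")
            if isinstance(label, bytes):
                label = label.decode()
            cubes.append(HSCube(data=data, axis=SpectralAxis(np.asarray(wl)),
                                mask=mask, label=label, id=cid))
    return cubes


def _envi_paths(path):
    path = pathlib.Path(path)
    if path.suffix == ".hdr":
        return path, path.with_suffix(".raw")
    return path.with_suffix(".hdr"), path


def write_envi(cube: HSCube, path) -> None:
    """Write one cube as an ENVI header + band-sequential float32 raw file.

    Mask (if any) is stored as an extra trailing band flagged in the header;
    the label and id go into header metadata lines.
    """
    hdr_path, raw_path = _envi_paths(path)
    h, w, b = cube.data.shape
    planes = [cube.data[:, :, i] for i in range(b)]
    has_mask = cube.mask is not None
    if has_mask:
        planes.append(cube.mask.astype(float))
    arr = np.stack(planes, axis=0).astype("<f4")  # BSQ: band, row, col
    arr.tofile(raw_path)
    wl = ", ".join(f"{v:.4f}" for v in cube.axis.wavelengths_nm)
    lines = [
        "ENVI",
        "description = {hsigan lesion cube}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        f"wavelength units = nm",
        f"wavelength = {{{wl}}}",
        f"mask band = {1 if has_mask else 0}",
        f"cube id = {{{cube.id}}}",
    ]
    if cube.label is not None:
        lines.append(f"class label = {{{cube.label}}}")
    hdr_path.write_text("\n".join(lines) + "\n")


def _parse_envi_header(text: str, name: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError(f"{name}: not an ENVI header")
    fields = {}
    key, buf = None, ""
    for line in text.splitlines()[1:]:
        if key is None:
            if "=" not in line:
                continue
            key, buf = (s.strip() for s in line.split("=", 1))
        else:
            buf += " " + line.strip()
        if buf.count("{") == buf.count("}"):
            fields[key.lower()] = buf.strip().strip("{}").strip()
            key, buf = None, ""
    return fields


def read_envi(path) -> HSCube:
    hdr_path, raw_path = _envi_paths(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text(), hdr_path.name)
    try:
        h = int(fields["lines"])
        w = int(fields["samples"])
        b = int(fields["bands"])
    except KeyError as e:
        raise FormatError(f"{hdr_path.name}: missing header field {e}") from e
    has_mask = int(fields.get("mask band", "0")) == 1
    n_planes = b + (1 if has_mask else 0)
    raw = np.fromfile(raw_path, dtype="<f4")
    if raw.size != n_planes * h * w:
        raise FormatError(
            f"{raw_path.name}: {raw.size} values, expected {n_planes}x{h}x{w}"
        )
    arr = raw.reshape(n_planes, h, w)
    wl = np.array([float(v) for v in fields["wavelength"].split(",")])
    if wl.size != b:
        raise FormatError(f"{hdr_path.name}: wavelength list length != bands")
    mask = arr[b].round().astype(np.uint8) if has_mask else None
    label = fields.get("class label")
    return HSCube(
        data=np.moveaxis(arr[:b], 0, 2).astype(float),
        axis=SpectralAxis(wl),
        mask=mask,
        label=label,
        id=fields.get("cube id", ""),
    )


def write_dataset(cubes: list[HSCube], path, format: str = "HDF5") -> None:
    fmt = format.upper()
    if fmt == "HDF5":
        write_hdf5(cubes, path)
    elif fmt == "ENVI":
        path = pathlib.Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, c in enumerate(cubes):
            cid = c.id or f"cube_{i:04d}"
            write_envi(c, path / f"{cid}.hdr")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path, format: str = "HDF5") -> list[HSCube]:
    fmt = format.upper()
    if fmt == "HDF5":
        return read_hdf5(path)
    if fmt == "ENVI":
        path = pathlib.Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return [read_envi(p) for p in sorted(path.glob("*.hdr"))]
    raise ValueError(f"unknown format {format!r}")
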