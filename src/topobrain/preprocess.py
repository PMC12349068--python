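"""Image preprocessing: from raw volumes or rasters to standardized scalar fields.

The pipeline mirrors a common workflow for slice-based topological analysis
of FLAIR brain MRI:

1. take the central axial slice of the volume,
2. convert it to a single-channel 256x256 grayscale grid,
3. obtain an in-brain mask (user-supplied, or a threshold fallback),
4. z-score the in-brain intensities and shift so the in-brain minimum is 0,
   with everything outside the brain pinned to 0.

The result is a :class:`ScalarField2D`, the input of the persistence stage:
a dimensionless intensity field whose sublevel sets start at the background
level and grow upward through the brain tissue into the bright lesions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters, measure, transform

__all__ = [
    "ImageVolume",
    "ScalarField2D",
    "extract_central_slice",
    "to_grayscale_256",
    "fallback_brain_mask",
    "standardize",
    "load_slice",
    "load_mask",
    "field_to_text",
    "field_from_text",
]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D image stack with a designated axis of axial slices."""

    voxels: np.ndarray
    slice_axis: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={v.ndim}")
        if v.shape[self.slice_axis] < 1 or v.size == 0:
            raise ValueError("volume contains no image data")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume intensities must be finite")
        object.__setattr__(self, "voxels", v)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]


@dataclass(frozen=True)
class ScalarField2D:
    """Standardized intensity grid with a binary in-brain mask.

    Invariants: values are finite; out-of-mask pixels are exactly 0; the
    in-mask minimum is exactly 0; the mask is nonempty.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if v.ndim != 2 or v.shape != m.shape:
            raise ValueError("values and mask must be matching 2D arrays")
        if not m.any():
            raise ValueError("mask is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("field values must be finite")
        if np.any(v[~m] != 0):
            raise ValueError("out-of-mask values must be exactly 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def extract_central_slice(volume: ImageVolume) -> np.ndarray:
    """Return the central axial slice, index ``floor(n_slices / 2)`` (0-based)."""
    idx = volume.n_slices // 2
    return np.take(volume.voxels, idx, axis=volume.slice_axis)


def to_grayscale_256(slice_: np.ndarray, size: int = 256) -> np.ndarray:
    """Resample a 2D (or multichannel 2D) grid to ``size x size`` by bilinear
    interpolation, averaging channels first if present."""
    arr = np.asarray(slice_, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input grid")
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grid, got ndim={arr.ndim}")
    if arr.shape == (size, size):
        return arr.copy()
    out = transform.resize(
        arr, (size, size), order=1, mode="edge", anti_aliasing=False,
        preserve_range=True,
    )
    # bilinear output is a convex combination of inputs; clip guards rounding
    return np.clip(out, arr.min(), arr.max())


def fallback_brain_mask(slice_: np.ndarray) -> np.ndarray:
    """Threshold stand-in for skull stripping.

    Binarize by Otsu's between-class-variance threshold, keep the largest
    connected foreground component, and fill its interior holes.  Intended
    for phantoms and quick looks; real analyses should supply a proper
    brain mask.
    """
    arr = np.asarray(slice_, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input grid")
    if np.all(arr == arr.flat[0]):
        raise ValueError("no foreground: image is constant")
    thr = filters.threshold_otsu(arr)
    fg = arr > thr
    if not fg.any():
        raise ValueError("no foreground above threshold")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    return ndimage.binary_fill_holes(mask)


def standardize(slice_: np.ndarray, mask: np.ndarray) -> ScalarField2D:
    """Z-score the in-mask intensities and shift the in-mask minimum to 0.

    Uses the population (divide-by-N) standard deviation.  Out-of-mask
    pixels are set to 0, placing the background at the filtration floor.
    """
    arr = np.asarray(slice_, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if arr.shape != m.shape:
        raise ValueError("slice and mask shapes differ")
    if m.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    vals = arr[m]
    mu = vals.mean()
    sigma = vals.std()  # population SD
    if sigma == 0:
        raise ValueError("constant brain region: standard deviation is zero")
    z = (vals - mu) / sigma
    z -= z.min()
    out = np.zeros_like(arr, dtype=float)
    out[m] = z
    return ScalarField2D(values=out, mask=m)


# ---------------------------------------------------------------------------
# Readers / writers


_RASTER_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def _load_dicom(path: Path) -> ImageVolume | np.ndarray:
    import pydicom

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
        if not files:
            raise ValueError(f"no DICOM files in {path}")
        dsets = [pydicom.dcmread(str(p)) for p in files]
        dsets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        return ImageVolume(
            np.stack([d.pixel_array.astype(float) for d in dsets]), slice_axis=0
        )
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    if arr.ndim == 3:
        return ImageVolume(arr, slice_axis=0)
    return arr


def _load_nifti(path: Path) -> ImageVolume | np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 4:
        arr = arr[..., 0]
    # NIfTI axial slices index the last axis by convention
    return ImageVolume(arr, slice_axis=2)


def load_slice(path: str | os.PathLike) -> np.ndarray:
    """Load an image file (DICOM, NIfTI, or 2D raster) and return a 2D grid,
    taking the central slice when the input is a volume."""
    p = Path(path)
    name = p.name.lower()
    if p.is_dir() or name.endswith(".dcm"):
        obj = _load_dicom(p)
    elif name.endswith((".nii", ".nii.gz")):
        obj = _load_nifti(p)
    elif p.suffix.lower() in _RASTER_SUFFIXES:
        import imageio.v3 as iio

        obj = np.asarray(iio.imread(str(p)), dtype=float)
    else:
        raise ValueError(f"unrecognized image format: {p}")
    if isinstance(obj, ImageVolume):
        return extract_central_slice(obj)
    return obj


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Load a binary mask (PNG/NIfTI; nonzero = brain)."""
    arr = load_slice(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return arr != 0


def field_to_text(field: ScalarField2D, path: str | os.PathLike) -> None:
    """Serialize a field as a plain-text grid (values block then mask block)."""
    h, w = field.shape
    with open(path, "w") as fh:
        fh.write(f"{h} {w}\n")
        np.savetxt(fh, field.values, fmt="%.17g")
        np.savetxt(fh, field.mask.astype(int), fmt="%d")


def field_from_text(path: str | os.PathLike) -> ScalarField2D:
    with open(path) as fh:
        h, w = (int(t) for t in fh.readline().split())
        data = np.loadtxt(fh)
    values = data[:h].reshape(h, w)
    mask = data[h:].reshape(h, w).astype(bool)
    return ScalarField2D(values=values, mask=mask)
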