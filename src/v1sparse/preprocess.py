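"""Image preprocessing: rescale, standardize, whiten, variance-0.1 rescale, patches.

The pipeline applied to every training image, in order:

1. min-max rescale to [0, 1];
2. subtract the image mean and divide by the image standard deviation;
3. multiply the 2-D Fourier transform by the radial whitening filter
   W(f) = f * exp(-(f/f0)^4) with the DC component set to zero — the
   standard filter used in this modelling lineage to emulate the bandpass
   response of retinal ganglion cells;
4. rescale pixels so the image variance is exactly ``target_variance``
   (default 0.1).

The target variance doubles as the baseline reconstruction error: the mean
squared error of a preprocessed image against the all-zero image (every unit
silent) equals the variance, 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreprocessedImage",
    "PatchBatch",
    "preprocess_image",
    "mse_to_zero",
    "extract_patches",
    "whitening_gain",
    "read_van_hateren",
    "read_grayscale",
]

DEFAULT_TARGET_VARIANCE = 0.1
DEFAULT_WHITENING_CUTOFF = 200.0  # cycles per image


@dataclass
class PreprocessedImage:
    """Whitened, variance-rescaled luminance grid."""

    pixels: np.ndarray
    target_variance: float = DEFAULT_TARGET_VARIANCE

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PatchBatch:
    """B x M matrix of row-major-flattened P x P windows plus their origins.

    ``source_coords`` holds (image_index, row, col) with 0-based top-left
    corners.
    """

    patches: np.ndarray
    source_coords: list[tuple[int, int, int]]
    seed: int
    patch_size: int

    def __len__(self) -> int:
        return self.patches.shape[0]


def whitening_gain(height: int, width: int, cutoff: float) -> np.ndarray:
    """Radial filter W(f) = f * exp(-(f/f0)^4) on the FFT grid, zero at DC."""
    fy = np.fft.fftfreq(height)[:, None] * height
    fx = np.fft.fftfreq(width)[None, :] * width
    f = np.hypot(fy, fx)
    return f * np.exp(-((f / cutoff) ** 4))


def preprocess_image(
    img: np.ndarray,
    whitening_cutoff: float = DEFAULT_WHITENING_CUTOFF,
    target_variance: float = DEFAULT_TARGET_VARIANCE,
) -> PreprocessedImage:
    """Run the full preprocessing pipeline on one raw luminance image."""
    pixels = np.asarray(img, dtype=float)
    if pixels.ndim != 2 or min(pixels.shape) < 16:
        raise ValueError(f"expected a 2-D image of at least 16x16 pixels, got shape {pixels.shape}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite values")
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        raise ValueError("constant image: standard deviation is zero, cannot standardize")
    scaled = (pixels - lo) / (hi - lo)
    standardized = (scaled - scaled.mean()) / scaled.std()
    gain = whitening_gain(*standardized.shape, cutoff=whitening_cutoff)
    whitened = np.fft.ifft2(np.fft.fft2(standardized) * gain).real
    var = whitened.var()
    out = whitened * np.sqrt(target_variance / var)
    return PreprocessedImage(out, target_variance)


def mse_to_zero(img: PreprocessedImage | np.ndarray) -> float:
    """Mean of squared pixel values: the reconstruction error of the zero code."""
    pixels = img.pixels if isinstance(img, PreprocessedImage) else np.asarray(img, dtype=float)
    return float(np.mean(pixels**2))


def extract_patches(
    images: list[PreprocessedImage],
    patch_size: int,
    count: int,
    seed: int,
) -> PatchBatch:
    """Uniform random P x P windows from uniformly chosen images, flattened row-major."""
    if len(images) == 0:
        raise ValueError("empty image list")
    for im in images:
        if min(im.shape) < patch_size:
            raise ValueError(
                f"patch_size {patch_size} exceeds smallest image dimension {min(im.shape)}"
            )
    rng = np.random.default_rng(seed)
    m = patch_size * patch_size
    patches = np.empty((count, m))
    coords: list[tuple[int, int, int]] = []
    for b in range(count):
        idx = int(rng.integers(len(images)))
        h, w = images[idx].shape
        row = int(rng.integers(h - patch_size + 1))
        col = int(rng.integers(w - patch_size + 1))
        patches[b] = images[idx].pixels[row : row + patch_size, col : col + patch_size].ravel()
        coords.append((idx, row, col))
    return PatchBatch(patches, coords, seed, patch_size)


def read_van_hateren(path, height: int = 1024, width: int = 1536) -> np.ndarray:
    """Read a van Hateren ``.iml``/``.imc`` raw image.

    Dialect: headerless 16-bit unsigned big-endian, row-major, 1536x1024
    (width x height) by default.
    """
    data = np.fromfile(path, dtype=">u2")
    if data.size != height * width:
        raise ValueError(
            f"{path}: expected {height * width} pixels ({height}x{width}), found {data.size}"
        )
    return data.reshape(height, width).astype(float)


def read_grayscale(path) -> np.ndarray:
    """Read a PNG/TIFF/PGM image as a 2-D float luminance array."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # average channels of an RGB(A) file
        arr = arr[..., :3].mean(axis=-1)
    return arr
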