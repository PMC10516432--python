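"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators:

* pink-noise images — white Gaussian noise shaped in the frequency domain to
  an amplitude spectrum proportional to 1/f^exponent (exponent 1 is the
  natural-image convention), mapped to nonnegative luminance.  A stand-in
  for a natural-image corpus: it reproduces the second-order (spectral)
  statistics the whitening stage targets, not the higher-order structure
  (edges, occlusions) of real scenes.

* planted sparse model — patches I = Phi r + nu with exactly k nonzero
  coefficients per sample, heavy-tailed (Laplace) amplitudes and Gaussian
  noise, returning the ground-truth codes for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PinkNoiseSpec",
    "PlantedModel",
    "generate_pink_noise_images",
    "sample_planted_patches",
    "random_unit_dictionary",
]


@dataclass
class PinkNoiseSpec:
    """Size, spectral exponent (amplitude ~ 1/f^exponent) and seed."""

    height: int = 512
    width: int = 512
    spectral_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError(f"image dimensions must be >= 16, got {self.height}x{self.width}")
        if not (0.0 <= self.spectral_exponent <= 2.0):
            raise ValueError(f"spectral_exponent must lie in [0, 2], got {self.spectral_exponent}")


@dataclass
class PlantedModel:
    """Ground-truth dictionary and code distribution of the linear generative model.

    Samples obey I = Phi r + nu: r has ``sparsity_k`` nonzero entries at
    uniformly random positions with Laplace(0, amplitude_scale) amplitudes,
    and nu is isotropic Gaussian with sd ``noise_sigma``.
    """

    true_dictionary: np.ndarray
    sparsity_k: int
    amplitude_scale: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_dictionary = np.asarray(self.true_dictionary, dtype=float)
        if self.true_dictionary.ndim != 2:
            raise ValueError("true_dictionary must be an M x N matrix")
        norms = np.linalg.norm(self.true_dictionary, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("true_dictionary columns must have unit norm (tol 1e-12)")
        n = self.true_dictionary.shape[1]
        if not (1 <= self.sparsity_k <= n):
            raise ValueError(f"sparsity_k must be in [1, N={n}], got {self.sparsity_k}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def m(self) -> int:
        return self.true_dictionary.shape[0]

    @property
    def n(self) -> int:
        return self.true_dictionary.shape[1]


def random_unit_dictionary(m: int, n: int, seed: int = 0) -> np.ndarray:
    """M x N matrix of i.i.d. Gaussian columns rescaled to unit norm."""
    rng = np.random.default_rng(seed)
    phi = rng.standard_normal((m, n))
    return phi / np.linalg.norm(phi, axis=0, keepdims=True)


def _radial_frequency(height: int, width: int) -> np.ndarray:
    fy = np.fft.fftfreq(height)[:, None] * height
    fx = np.fft.fftfreq(width)[None, :] * width
    return np.hypot(fy, fx)


def generate_pink_noise_images(spec: PinkNoiseSpec, count: int) -> list[np.ndarray]:
    """Draw ``count`` images with amplitude spectrum ~ 1/f^exponent, zero DC.

    White Gaussian noise is transformed to the frequency domain, its
    amplitudes multiplied by 1/f^exponent (DC removed), and the result is
    min-max mapped to nonnegative luminance in [0, 1].  Bit-identical output
    for identical spec + seed.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    f = _radial_frequency(spec.height, spec.width)
    gain = np.zeros_like(f)
    nonzero = f > 0
    gain[nonzero] = f[nonzero] ** (-spec.spectral_exponent)
    seeds = np.random.SeedSequence(spec.seed).spawn(count)
    images = []
    for child in seeds:
        rng = np.random.default_rng(child)
        white = rng.standard_normal((spec.height, spec.width))
        shaped = np.fft.ifft2(np.fft.fft2(white) * gain).real
        lo, hi = shaped.min(), shaped.max()
        images.append((shaped - lo) / (hi - lo))
    return images


def radial_log_slope(images: list[np.ndarray]) -> float:
    """Slope of log amplitude vs log frequency, radially averaged over images.

    Diagnostic companion to :func:`generate_pink_noise_images`: estimates the
    realized spectral exponent (negated) by least squares on the radially
    binned mean amplitude spectrum, ignoring the highest octave where the
    square frequency grid is incompletely sampled.
    """
    h, w = images[0].shape
    f = _radial_frequency(h, w)
    amp = np.zeros_like(f)
    for img in images:
        amp += np.abs(np.fft.fft2(img - img.mean()))
    amp /= len(images)
    fmax = min(h, w) / 2.0
    rbin = np.rint(f).astype(int)
    mask = (rbin >= 1) & (f <= fmax / 2)  # drop DC and the corner-undersampled octave
    sums = np.bincount(rbin[mask], weights=amp[mask])
    counts = np.bincount(rbin[mask])
    valid = counts > 0
    radial = sums[valid] / counts[valid]
    freqs = np.nonzero(valid)[0]
    keep = freqs >= 1
    coeffs = np.polyfit(np.log(freqs[keep]), np.log(radial[keep]), 1)
    return float(coeffs[0])


def sample_planted_patches(model: PlantedModel, count: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``count`` patches from the planted model; returns (patches, codes).

    patches: count x M rows I = Phi r + nu; codes: count x N ground truth with
    exactly ``sparsity_k`` nonzeros each.  Deterministic for a given model.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(model.seed)
    codes = np.zeros((count, model.n))
    for b in range(count):
        support = rng.choice(model.n, size=model.sparsity_k, replace=False)
        amps = rng.laplace(0.0, model.amplitude_scale, size=model.sparsity_k)
        while np.any(amps == 0.0):  # keep the support size exact
            amps[amps == 0.0] = rng.laplace(0.0, model.amplitude_scale, size=np.sum(amps == 0.0))
        codes[b, support] = amps
    patches = codes @ model.true_dictionary.T
    if model.noise_sigma > 0:
        patches += rng.normal(0.0, model.noise_sigma, size=patches.shape)
    return patches, codes
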