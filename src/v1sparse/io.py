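"""Persistence: HDF5 for dictionaries, batches, models; 16-bit PNG for images."""

from __future__ import annotations

import numpy as np

from .learning import Dictionary
from .preprocess import PatchBatch, PreprocessedImage
from .synthetic import PlantedModel

__all__ = [
    "save_dictionary",
    "load_dictionary",
    "save_patch_batch",
    "load_patch_batch",
    "save_planted_model",
    "load_planted_model",
    "save_preprocessed_images",
    "load_preprocessed_images",
    "write_png16",
]


def save_dictionary(path, dictionary: Dictionary) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=dictionary.phi)
        f.attrs["created_by"] = dictionary.created_by


def load_dictionary(path) -> Dictionary:
    import h5py

    with h5py.File(path, "r") as f:
        return Dictionary(f["phi"][...], created_by=str(f.attrs.get("created_by", "")))


def save_patch_batch(path, batch: PatchBatch) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=batch.patches)
        f.create_dataset("source_coords", data=np.asarray(batch.source_coords, dtype=np.int64))
        f.attrs["seed"] = batch.seed
        f.attrs["patch_size"] = batch.patch_size


def load_patch_batch(path) -> PatchBatch:
    import h5py

    with h5py.File(path, "r") as f:
        coords = [tuple(int(v) for v in row) for row in f["source_coords"][...]]
        return PatchBatch(
            f["patches"][...], coords, int(f.attrs["seed"]), int(f.attrs["patch_size"])
        )


def save_preprocessed_images(path, images: list[PreprocessedImage]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for i, im in enumerate(images):
            ds = f.create_dataset(f"image_{i:04d}", data=im.pixels)
            ds.attrs["target_variance"] = im.target_variance


def load_preprocessed_images(path) -> list[PreprocessedImage]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            out.append(PreprocessedImage(f[key][...], float(f[key].attrs["target_variance"])))
    return out


def write_png16(path, image: np.ndarray) -> None:
    """Write a luminance image as 16-bit grayscale PNG (min-max scaled to full range)."""
    import imageio.v3 as iio

    arr = np.asarray(image, dtype=float)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(path, (scaled * 65535).astype(np.uint16))


def save_planted_model(path, model: PlantedModel) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("dictionary", data=model.true_dictionary)
        f.attrs["sparsity_k"] = model.sparsity_k
        f.attrs["amplitude_scale"] = model.amplitude_scale
        f.attrs["noise_sigma"] = model.noise_sigma
        f.attrs["seed"] = model.seed


def load_planted_model(path) -> PlantedModel:
    import h5py

    with h5py.File(path, "r") as f:
        return PlantedModel(
            f["dictionary"][...],
            sparsity_k=int(f.attrs["sparsity_k"]),
            amplitude_scale=float(f.attrs["amplitude_scale"]),
            noise_sigma=float(f.attrs["noise_sigma"]),
            seed=int(f.attrs["seed"]),
        )
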