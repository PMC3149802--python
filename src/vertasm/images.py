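"""Grey-level image loading (PNG/TIFF, 8- or 16-bit) to float [0, 255]."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["load_image", "save_image"]


def load_image(path) -> np.ndarray:
    """Load a grey image as float intensities in [0, 255].

    Multichannel inputs are averaged to grey; 16-bit inputs are
    rescaled to the 0-255 range.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if arr.max() > 255.0:  # 16-bit source
        arr = arr / 257.0
    return arr


def save_image(image: np.ndarray, path) -> None:
    """Write a float [0, 255] image as 8-bit PNG/TIFF."""
    iio.imwrite(path, np.clip(np.asarray(image), 0, 255).astype(np.uint8))
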