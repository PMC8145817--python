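"""Review-image preprocessing for the classifier.

The plot text and axes are cropped away using the margins of the render
style that produced the image (exact by construction, no pixel
heuristics), then both dimensions are reduced eightfold by block-mean
pooling (floor division; trailing rows/columns that do not fill a block
are discarded) and normalized to [0, 1].
"""

from __future__ import annotations

import numpy as np
from PIL import Image

DOWNSCALE = 8


def block_mean(img: np.ndarray, factor: int = DOWNSCALE) -> np.ndarray:
    """Mean-pool ``factor``x``factor`` blocks; output dims are floor(dim/factor)."""
    h, w = img.shape[:2]
    hb, wb = h // factor, w // factor
    if hb == 0 or wb == 0:
        raise ValueError(f"image {h}x{w} smaller than one {factor}x{factor} block")
    img = img[: hb * factor, : wb * factor]
    return img.reshape(hb, factor, wb, factor, -1).mean(axis=(1, 3))


def preprocess_image(
    path_or_array, crop_box: tuple[int, int, int, int] | None = None
) -> np.ndarray:
    """Load, crop, 8x block-mean downscale and normalize one plot image.

    ``crop_box`` is (x0, y0, x1, y1) in pixels with origin at the top left
    — use :meth:`svreview.render.PlotStyle.crop_box` for images this
    package rendered.  Returns float array (h, w, 3) in [0, 1].
    """
    if isinstance(path_or_array, np.ndarray):
        arr = path_or_array.astype(np.float64)
        if arr.max() > 1.0:
            arr = arr / 255.0
    else:
        with Image.open(path_or_array) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    if crop_box is not None:
        x0, y0, x1, y1 = crop_box
        if x1 > arr.shape[1] or y1 > arr.shape[0] or x0 < 0 or y0 < 0 or x0 >= x1 or y0 >= y1:
            raise ValueError(
                f"crop box {crop_box} incompatible with image {arr.shape[1]}x{arr.shape[0]}"
            )
        arr = arr[y0:y1, x0:x1]
    if arr.ndim == 2:
        arr = arr[:, :, None].repeat(3, axis=2)
    return block_mean(arr, DOWNSCALE)
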