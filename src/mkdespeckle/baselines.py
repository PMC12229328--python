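"""Classical despeckling baselines: average, median, Gaussian, bilateral.

All four are neighborhood filters with reflected borders, deterministic and
shape-preserving, provided for side-by-side evaluation against the learned
denoisers.  Multichannel images are filtered per channel.

The bilateral filter is implemented directly (a vectorized sum over window
offsets with spatial and range Gaussian weights) rather than through an
image-restoration library call, because the unclipped speckle model can
produce negative intensities, which bilateral implementations restricted
to nonnegative input reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class FilterParams:
    """Configuration of one classical filter.

    ``window`` is the odd side length of the square neighborhood.
    ``gaussian_sigma`` applies to the Gaussian filter; ``spatial_sigma``
    and ``range_sigma`` to the bilateral filter.
    """

    kind: str                      # "average" | "median" | "gaussian" | "bilateral"
    window: int = 5
    gaussian_sigma: float = 1.0
    spatial_sigma: float = 2.0
    range_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("average", "median", "gaussian", "bilateral"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.kind == "gaussian" and self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.kind == "bilateral" and (self.spatial_sigma <= 0 or self.range_sigma <= 0):
            raise ValueError("bilateral sigmas must be positive")


def _bilateral2d(img: np.ndarray, window: int, spatial_sigma: float,
                 range_sigma: float) -> np.ndarray:
    radius = window // 2
    padded = np.pad(img, radius, mode="symmetric")   # scipy's edge-inclusive "reflect"
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    h, w = img.shape
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            shifted = padded[radius + dy:radius + dy + h, radius + dx:radius + dx + w]
            ws = np.exp(-(dy * dy + dx * dx) / (2.0 * spatial_sigma ** 2))
            wr = np.exp(-((shifted - img) ** 2) / (2.0 * range_sigma ** 2))
            weight = ws * wr
            num += weight * shifted
            den += weight
    return num / den


def _filter2d(img: np.ndarray, params: FilterParams) -> np.ndarray:
    if params.kind == "average":
        return ndimage.uniform_filter(img, size=params.window, mode="reflect")
    if params.kind == "median":
        return ndimage.median_filter(img, size=params.window, mode="reflect")
    if params.kind == "gaussian":
        truncate = (params.window // 2) / params.gaussian_sigma
        return ndimage.gaussian_filter(img, sigma=params.gaussian_sigma,
                                       mode="reflect", truncate=truncate)
    return _bilateral2d(img, params.window, params.spatial_sigma, params.range_sigma)


def apply_filter(image: np.ndarray, params: FilterParams) -> np.ndarray:
    """Apply one classical filter with reflected borders.

    ``image`` is ``(H, W)`` or ``(H, W, C)``; the output has the same shape.
    """
    image = np.asarray(image, dtype=np.float64)
    if params.window > min(image.shape[:2]):
        raise ValueError(f"window {params.window} exceeds image sides {image.shape[:2]}")
    if image.ndim == 2:
        return _filter2d(image, params)
    return np.stack([_filter2d(image[..., c], params)
                     for c in range(image.shape[2])], axis=2)
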