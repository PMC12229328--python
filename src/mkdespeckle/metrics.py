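"""Full-reference and no-reference despeckling quality metrics.

Implements the evaluation suite used to compare denoisers: MSE, RMSE, MAE,
PSNR (dB), SSIM (Gaussian-weighted sliding window), ENL (equivalent number
of looks, over a homogeneous ROI) and Pratt's figure of merit for edge
preservation, plus table-style aggregation over an image set.

Conventions
-----------
* Images are ``(H, W)`` or ``(H, W, C)`` arrays; multichannel metrics are
  computed per channel and averaged, so replicated-grayscale 3-channel
  images score identically to their single-channel originals.
* PSNR defaults to the standard ``10·log10(peak²/MSE)`` with ``peak`` the
  span of the declared value range.  When MSE is exactly zero a sentinel
  (default 0 dB) is returned rather than infinity.  A ``peak_over_mse``
  convention computing ``10·log10(peak/MSE)`` is available for comparison
  with sources that print that form.
* ENL uses the population variance (divide by ``n``); a zero-variance ROI
  raises :class:`DegenerateRegionError` instead of returning infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import feature


class DegenerateRegionError(ValueError):
    """Raised when ENL is requested over a zero-variance (degenerate) ROI."""


# ---------------------------------------------------------------------------
# Pixelwise error metrics
# ---------------------------------------------------------------------------

def _check_shapes(g: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(g, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    return g, p


def mse(g: np.ndarray, p: np.ndarray) -> float:
    """Mean squared error over all pixels and channels."""
    g, p = _check_shapes(g, p)
    return float(np.mean((g - p) ** 2))


def rmse(g: np.ndarray, p: np.ndarray) -> float:
    """Root mean squared error, ``sqrt(mse)``."""
    return float(np.sqrt(mse(g, p)))


def mae(g: np.ndarray, p: np.ndarray) -> float:
    """Mean absolute error over all pixels and channels."""
    g, p = _check_shapes(g, p)
    return float(np.mean(np.abs(g - p)))


def psnr(g: np.ndarray, p: np.ndarray, peak: float = 1.0,
         mse_zero_sentinel: float = 0.0,
         convention: str = "standard") -> float:
    """Peak signal-to-noise ratio in dB.

    ``convention='standard'`` computes ``10·log10(peak²/MSE)``;
    ``convention='peak_over_mse'`` computes ``10·log10(peak/MSE)``, a form
    some published tables print.
    When MSE is exactly zero, ``mse_zero_sentinel`` is returned.
    """
    if peak <= 0:
        raise ValueError(f"peak must be positive, got {peak}")
    err = mse(g, p)
    if err == 0.0:
        return float(mse_zero_sentinel)
    if convention == "standard":
        return float(10.0 * np.log10(peak ** 2 / err))
    if convention == "peak_over_mse":
        return float(10.0 * np.log10(peak / err))
    raise ValueError(f"unknown PSNR convention {convention!r}")


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

@dataclass
class SSIMParams:
    """Sliding-window SSIM settings (Gaussian-weighted 11×11 by default)."""

    window: int = 11
    dynamic_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    gaussian_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian weighting window."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def _filter_valid(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlate and keep only fully-supported (valid) windows."""
    half = kernel.shape[0] // 2
    out = ndimage.correlate(x, kernel, mode="constant")
    return out[half:-half, half:-half]


def _ssim_single(g: np.ndarray, p: np.ndarray, params: SSIMParams) -> float:
    win = gaussian_window(params.window, params.gaussian_sigma)
    mu_x = _filter_valid(g, win)
    mu_y = _filter_valid(p, win)
    sxx = _filter_valid(g * g, win) - mu_x * mu_x
    syy = _filter_valid(p * p, win) - mu_y * mu_y
    sxy = _filter_valid(g * p, win) - mu_x * mu_y
    c1, c2 = params.c1, params.c2
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def ssim(g: np.ndarray, p: np.ndarray, params: SSIMParams | None = None) -> float:
    """Mean structural similarity over Gaussian-weighted sliding windows.

    Weighted local moments follow the original formulation (no sample-size
    correction); only fully-supported windows contribute.
    """
    g, p = _check_shapes(g, p)
    params = params or SSIMParams()
    if min(g.shape[0], g.shape[1]) < params.window:
        raise ValueError(f"image sides {g.shape[:2]} smaller than window {params.window}")
    if g.ndim == 2:
        return _ssim_single(g, p, params)
    return float(np.mean([_ssim_single(g[..., c], p[..., c], params)
                          for c in range(g.shape[2])]))


# ---------------------------------------------------------------------------
# ENL
# ---------------------------------------------------------------------------

def enl(image: np.ndarray, roi: tuple[int, int, int, int]) -> float:
    """Equivalent number of looks, mean²/variance over a homogeneous ROI.

    ``roi`` is ``(row0, col0, row1, col1)``, 0-based and half-open.  Higher
    values indicate stronger speckle suppression in the region.
    """
    image = np.asarray(image, dtype=np.float64)
    r0, c0, r1, c1 = roi
    h, w = image.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} not inside image of shape {image.shape}")
    region = image[r0:r1, c0:c1]
    if region.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    if image.ndim == 3:
        return float(np.mean([_enl_region(region[..., c]) for c in range(image.shape[2])]))
    return _enl_region(region)


def _enl_region(region: np.ndarray) -> float:
    var = float(np.var(region))          # population convention
    if var == 0.0:
        raise DegenerateRegionError("ROI has zero variance; ENL is undefined")
    mean = float(np.mean(region))
    return mean ** 2 / var


# ---------------------------------------------------------------------------
# Pratt's figure of merit
# ---------------------------------------------------------------------------

@dataclass
class FOMParams:
    """Edge detection and scaling settings for Pratt's figure of merit."""

    alpha_scale: float = 1.0 / 9.0
    edge_sigma: float = 1.5
    low_threshold: float = 0.10
    high_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.alpha_scale <= 0:
            raise ValueError("alpha_scale must be positive")


def pratt_fom(detected: np.ndarray, reference: np.ndarray,
              alpha_scale: float = 1.0 / 9.0) -> float:
    """Pratt's figure of merit on boolean edge maps.

    ``(1/max(N_d, N_r)) · Σ_detected 1/(1 + alpha·d²)`` where ``d`` is the
    Euclidean distance from each detected edge pixel to the nearest
    reference edge pixel.  Returns a value in [0, 1]; 1 means the detected
    map coincides with the reference.
    """
    detected = np.asarray(detected, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if detected.shape != reference.shape:
        raise ValueError(f"shape mismatch: {detected.shape} vs {reference.shape}")
    n_ref = int(reference.sum())
    if n_ref == 0:
        raise ValueError("reference edge map contains no edge pixels")
    n_det = int(detected.sum())
    if n_det == 0:
        return 0.0
    dist = ndimage.distance_transform_edt(~reference)
    d = dist[detected]
    return float(np.sum(1.0 / (1.0 + alpha_scale * d ** 2)) / max(n_det, n_ref))


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    return image.mean(axis=2) if image.ndim == 3 else image


def edge_map(image: np.ndarray, params: FOMParams | None = None) -> np.ndarray:
    """Canny edge map with the fixed thresholds recorded in ``FOMParams``."""
    params = params or FOMParams()
    return feature.canny(_to_gray(image), sigma=params.edge_sigma,
                         low_threshold=params.low_threshold,
                         high_threshold=params.high_threshold)


def fom(denoised: np.ndarray, reference: np.ndarray,
        params: FOMParams | None = None) -> float:
    """Edge-preservation score of ``denoised`` against a clean reference.

    The same edge detector (Canny, fixed thresholds) is applied to both
    images; the detected map is scored against the reference map with
    Pratt's formula.
    """
    params = params or FOMParams()
    det = edge_map(denoised, params)
    ref = edge_map(reference, params)
    return pratt_fom(det, ref, params.alpha_scale)


# ---------------------------------------------------------------------------
# Suite evaluation / report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-image metric records plus per-group (e.g. noise level) means."""

    records: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def evaluate_suite(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                   rois: Sequence[tuple[int, int, int, int]] | None = None,
                   groups: Sequence | None = None,
                   peak: float = 1.0,
                   ssim_params: SSIMParams | None = None,
                   fom_params: FOMParams | None = None) -> MetricReport:
    """Evaluate (clean, denoised) pairs and aggregate per group.

    ``rois`` supplies the per-image homogeneous region for ENL (optional:
    without it ENL is reported as NaN).  ``groups`` labels each pair (for
    example with its noise variance); aggregates are the arithmetic means
    of each metric within a group, ENL averaged over the images where it is
    defined (degenerate ROIs are recorded as NaN and flagged).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_suite requires at least one image pair")
    ssim_params = ssim_params or SSIMParams()
    fom_params = fom_params or FOMParams()
    records: list[dict] = []
    for i, (clean, den) in enumerate(pairs):
        rec: dict = {"image": i}
        if groups is not None:
            rec["group"] = groups[i]
        rec["psnr"] = psnr(clean, den, peak=peak)
        rec["ssim"] = ssim(clean, den, ssim_params)
        rec["rmse"] = rmse(clean, den)
        if rois is not None:
            try:
                rec["enl"] = enl(den, rois[i])
            except DegenerateRegionError:
                rec["enl"] = float("nan")
                rec["enl_degenerate"] = True
        else:
            rec["enl"] = float("nan")
        try:
            rec["fom"] = fom(den, clean, fom_params)
        except ValueError:
            rec["fom"] = float("nan")
        records.append(rec)

    def summarize(recs: list[dict]) -> dict:
        out = {}
        for key in ("psnr", "ssim", "rmse", "enl", "fom"):
            vals = np.asarray([r[key] for r in recs], dtype=float)
            with np.errstate(invalid="ignore"):
                out[key] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
        out["n_images"] = len(recs)
        return out

    aggregates = {"overall": summarize(records)}
    if groups is not None:
        for gval in sorted(set(groups), key=str):
            aggregates[str(gval)] = summarize([r for r in records if r["group"] == gval])

    params = {
        "peak": peak,
        "ssim": vars(ssim_params).copy(),
        "fom": vars(fom_params).copy(),
    }
    return MetricReport(records=records, aggregates=aggregates, params=params)
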