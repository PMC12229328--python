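"""Image I/O, run configuration, and whole-image inference by tiling.

The networks operate on fixed-size patches (64×64 by default); full images
are denoised by covering the image with a tile grid (the final row/column
of tiles is shifted flush with the border when the size is not an exact
multiple, so no padding artifacts enter), running every tile through the
network in batches, and stitching the outputs — overlapping regions are
blended with feathered weights normalized to sum to one per pixel.

Pixel intensities on disk (8- or 16-bit PNG/TIFF) are mapped to the
declared ``[0, 1]`` range on load and back on save.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .losses import LossWeights
from .metrics import MetricReport
from .models import NetworkHandle, StudentSpec, TeacherSpec
from .training import PlateauPolicy, TrainingConfig


# ---------------------------------------------------------------------------
# Image files
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as float64 scaled to [0, 1].

    8-bit data is divided by 255, 16-bit by 65535; float data is passed
    through unchanged.  Unreadable files raise ``OSError`` naming the path.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    if np.issubdtype(raw.dtype, np.floating):
        return raw.astype(np.float64)
    raise OSError(f"unsupported bit depth {raw.dtype} in {path}")


def save_image(image: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Save a [0, 1] image as 8- or 16-bit PNG/TIFF (values are clipped)."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(image * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(image * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, data)


# ---------------------------------------------------------------------------
# Normalization (recorded and inverted around inference)
# ---------------------------------------------------------------------------

def normalize_image(image: np.ndarray, mode: str = "none"
                    ) -> tuple[np.ndarray, dict]:
    """Apply a recorded, invertible per-image affine transform.

    ``zscore`` maps to zero mean / unit variance, ``minmax`` to [0, 1];
    the returned transform dict feeds :func:`denormalize_image` so metrics
    are always computed in the original intensity range.
    """
    image = np.asarray(image, dtype=np.float64)
    if mode == "none":
        return image, {"mode": "none", "scale": 1.0, "offset": 0.0}
    if mode == "zscore":
        mu, sd = float(image.mean()), float(image.std())
        sd = sd if sd > 0 else 1.0
        return (image - mu) / sd, {"mode": "zscore", "scale": sd, "offset": mu}
    if mode == "minmax":
        lo, hi = float(image.min()), float(image.max())
        span = (hi - lo) if hi > lo else 1.0
        return (image - lo) / span, {"mode": "minmax", "scale": span, "offset": lo}
    raise ValueError(f"unknown normalization mode {mode!r}")


def denormalize_image(image: np.ndarray, transform: dict) -> np.ndarray:
    return image * transform["scale"] + transform["offset"]


# ---------------------------------------------------------------------------
# Tiled whole-image inference
# ---------------------------------------------------------------------------

@dataclass
class TileLayout:
    """Tiling geometry for whole-image inference."""

    tile: int = 64
    overlap: int = 0
    blend: str = "feather"          # "none" | "feather"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.tile):
            raise ValueError("need 0 <= overlap < tile")
        if self.blend not in ("none", "feather"):
            raise ValueError("blend must be 'none' or 'feather'")


def _tile_positions(length: int, tile: int, step: int) -> list[int]:
    """Start offsets covering [0, length) with the final tile flush-right."""
    positions = list(range(0, max(length - tile, 0) + 1, step))
    if positions[-1] + tile < length:
        positions.append(length - tile)
    return positions


def _feather_profile(tile: int, overlap: int) -> np.ndarray:
    if overlap == 0:
        return np.ones(tile)
    ramp = np.arange(1, tile + 1, dtype=np.float64)
    prof = np.minimum(np.minimum(ramp, ramp[::-1]), overlap + 1.0)
    return prof


def denoise_image(image: np.ndarray, model: NetworkHandle,
                  layout: TileLayout | None = None,
                  normalize: str = "none",
                  batch_size: int = 32) -> np.ndarray:
    """Denoise a whole image by tiling it through a patch network.

    Every pixel is covered by at least one tile (the last tile of each
    row/column sits flush with the border), tiles run in inference mode in
    batches, and outputs are blended with per-pixel weights normalized to
    sum to 1.  An optional recorded normalization is applied before and
    inverted after inference, so the result is in the input's range.
    """
    layout = layout or TileLayout()
    image = np.asarray(image, dtype=np.float64)
    squeeze = image.ndim == 2
    h, w = image.shape[:2]
    if h < layout.tile or w < layout.tile:
        raise ValueError(f"image {image.shape} smaller than tile {layout.tile}")

    work, transform = normalize_image(image, normalize)
    if squeeze:
        work = work[:, :, None]
    channels = model.spec.input_size[2]
    if work.shape[2] == 1 and channels == 3:
        work = np.repeat(work, 3, axis=2)
    elif work.shape[2] != channels:
        raise ValueError(f"image has {work.shape[2]} channels, model expects {channels}")

    step = layout.tile - layout.overlap
    rows = _tile_positions(h, layout.tile, step)
    cols = _tile_positions(w, layout.tile, step)

    prof = _feather_profile(layout.tile, layout.overlap) if layout.blend == "feather" \
        else np.ones(layout.tile)
    weight2d = np.outer(prof, prof)

    tiles = np.stack([work[r:r + layout.tile, c:c + layout.tile]
                      for r in rows for c in cols])
    outs = []
    for i in range(0, tiles.shape[0], batch_size):
        outs.append(model.forward(tiles[i:i + batch_size]))
    outs = np.concatenate(outs, axis=0)

    acc = np.zeros_like(work)
    wacc = np.zeros((h, w, 1))
    k = 0
    for r in rows:
        for c in cols:
            acc[r:r + layout.tile, c:c + layout.tile] += outs[k] * weight2d[:, :, None]
            wacc[r:r + layout.tile, c:c + layout.tile, 0] += weight2d
            k += 1
    result = acc / wacc

    if image.ndim == 3 and image.shape[2] == 1 and channels == 3:
        result = result.mean(axis=2, keepdims=True)
    elif squeeze and channels == 3:
        result = result.mean(axis=2)
    elif squeeze:
        result = result[:, :, 0]
    return denormalize_image(result, transform)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

_REQUIRED_METRICS = ("psnr", "ssim", "rmse", "enl", "fom")


def format_report_table(report: MetricReport) -> str:
    """Aligned text table of the per-group aggregates."""
    header = f"{'group':>12} {'n':>4} {'PSNR (dB)':>10} {'SSIM':>8} {'RMSE':>8} {'ENL':>8} {'FOM':>8}"
    lines = [header, "-" * len(header)]
    for group, agg in report.aggregates.items():
        lines.append(
            f"{group:>12} {agg['n_images']:>4d} {agg['psnr']:>10.3f} "
            f"{agg['ssim']:>8.4f} {agg['rmse']:>8.4f} {agg['enl']:>8.3f} {agg['fom']:>8.4f}")
    return "\n".join(lines)


def write_report(report: MetricReport | dict, path: str | Path) -> None:
    """Write a metric or ablation report as deterministic JSON.

    Records are validated before anything is written; identical reports
    produce identical bytes.
    """
    path = Path(path)
    if isinstance(report, MetricReport):
        for rec in report.records:
            missing = [k for k in _REQUIRED_METRICS if k not in rec]
            if missing:
                raise ValueError(f"record {rec.get('image')} missing metrics: {missing}")
        payload = {"records": report.records, "aggregates": report.aggregates,
                   "params": report.params}
    else:
        payload = report
    text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
    path.write_text(text + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One experiment: data, model, loss, training and I/O settings."""

    seed: int = 0
    data: dict = field(default_factory=lambda: {
        "n_images": 12, "height": 128, "width": 128, "n_lesions": 3,
        "noise_variances": [0.01, 0.09, 0.25], "split": [0.8, 0.1, 0.1],
        "patch": 64, "stride": 64, "sigma_semantics": "variance",
    })
    teacher: TeacherSpec = field(default_factory=TeacherSpec)
    student: StudentSpec = field(default_factory=StudentSpec)
    loss: LossWeights = field(default_factory=LossWeights)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    io: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config, validating every block's invariants."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {"seed": int(raw.get("seed", 0))}
    if "data" in raw:
        base = RunConfig().data
        base.update(raw["data"])
        kwargs["data"] = base
    if "teacher" in raw:
        kwargs["teacher"] = TeacherSpec(**{**raw["teacher"], "input_size":
                                           tuple(raw["teacher"].get("input_size", (64, 64, 3)))})
    if "student" in raw:
        kwargs["student"] = StudentSpec(**{**raw["student"], "input_size":
                                           tuple(raw["student"].get("input_size", (64, 64, 3)))})
    if "loss" in raw:
        kwargs["loss"] = LossWeights(**raw["loss"])
    if "training" in raw:
        tr = dict(raw["training"])
        if "plateau" in tr:
            tr["plateau"] = PlateauPolicy(**tr["plateau"])
        if "loss" in tr:
            tr["loss"] = LossWeights(**tr["loss"])
        kwargs["training"] = TrainingConfig(**tr)
    if "io" in raw:
        kwargs["io"] = dict(raw["io"])
    cfg = RunConfig(**kwargs)
    if "loss" in raw and "training" not in raw:
        cfg.training.loss = cfg.loss
    return cfg
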