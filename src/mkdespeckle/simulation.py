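"""Synthetic ultrasound-like phantoms and the multiplicative speckle model.

Images throughout the package are plain numpy arrays — ``(H, W)`` or
``(H, W, C)`` with ``C ∈ {1, 3}`` — holding intensities in a declared range,
``[0, 1]`` unless stated otherwise.

The speckle model is

    I_n(x, y) = I(x, y) + I(x, y)**gamma * mu(x, y)

with ``mu`` i.i.d. zero-mean Gaussian of variance sigma (or standard
deviation sigma, selectable) and ``gamma = 1`` by default, the standard
signal-dependent model for coherent imaging.  The noisy image is *not*
clipped to the value range by default so that the stated noise moments are
preserved exactly; clipping is an explicit option for display/export.

Phantoms are piecewise-smooth anatomy-like images: a smooth textured
background, elliptical bright/dark lesions with sharp boundaries, and a
straight-edged bright band (so that edge-preservation metrics have reference
edges).  A rectangle in the upper-left corner is kept free of structures and
is exposed via :func:`phantom_background_roi` as the default homogeneous
region for ENL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# Speckle model
# ---------------------------------------------------------------------------

@dataclass
class SpeckleParams:
    """Parameters of the multiplicative speckle model.

    ``sigma`` is interpreted per ``sigma_semantics``: as the *variance* of
    the Gaussian noise field (the default) or as its standard deviation.
    ``gamma_exponent`` is the signal exponent (1 = fully multiplicative,
    0 = additive).
    """

    sigma: float
    sigma_semantics: str = "variance"
    gamma_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")
        if self.sigma_semantics not in ("variance", "std"):
            raise ValueError("sigma_semantics must be 'variance' or 'std'")

    @property
    def noise_std(self) -> float:
        return float(np.sqrt(self.sigma)) if self.sigma_semantics == "variance" \
            else float(self.sigma)


def add_speckle(image: np.ndarray, params: SpeckleParams,
                clip: bool = False) -> np.ndarray:
    """Corrupt ``image`` with signal-dependent multiplicative speckle.

    With ``sigma == 0`` the input is returned unchanged (bit-exact copy).
    The same ``params.seed`` always produces the same noise field.
    """
    image = np.asarray(image, dtype=np.float64)
    if params.sigma == 0:
        return image.copy()
    rng = np.random.default_rng(params.seed)
    mu = rng.normal(0.0, params.noise_std, size=image.shape)
    if params.gamma_exponent == 1.0:
        gain = image
    elif params.gamma_exponent == 0.0:
        gain = np.ones_like(image)
    else:
        gain = np.power(np.abs(image), params.gamma_exponent)
    noisy = image + gain * mu
    if clip:
        noisy = np.clip(noisy, 0.0, 1.0)
    return noisy


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def phantom_background_roi(height: int, width: int) -> tuple[int, int, int, int]:
    """Structure-free rectangle ``(row0, col0, row1, col1)`` (half-open).

    The generator never places lesions or the bright band inside it, so it
    is a suitable homogeneous region for ENL.
    """
    return (height // 16, width // 16, height // 4, width // 4)


def generate_phantom(seed: int, height: int = 256, width: int = 256,
                     n_lesions: int = 3) -> np.ndarray:
    """Generate a piecewise-smooth anatomy-like test image in [0, 1].

    The image contains a smooth textured background, ``n_lesions``
    elliptical bright/dark lesions with sharp boundaries, and one bright
    straight-edged band.  Identical seeds give bitwise-identical images.
    """
    if height < 1 or width < 1:
        raise ValueError(f"dimensions must be positive, got {height}x{width}")
    if n_lesions < 0:
        raise ValueError(f"n_lesions must be nonnegative, got {n_lesions}")
    rng = np.random.default_rng(seed)

    # Smooth background: a gentle diagonal ramp plus band-limited texture.
    rows = np.linspace(0.0, 1.0, height)[:, None]
    cols = np.linspace(0.0, 1.0, width)[None, :]
    img = 0.40 + 0.10 * rows + 0.05 * cols
    texture = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma=6.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    img = img + 0.06 * texture

    yy, xx = np.mgrid[0:height, 0:width]

    # Straight-edged bright band near the bottom (reference edges for FOM).
    r0 = int(0.78 * height)
    r1 = int(0.86 * height)
    img[r0:r1, int(0.10 * width):int(0.90 * width)] += 0.25

    # Elliptical lesions with sharp boundaries, alternating bright/dark,
    # kept clear of the homogeneous ENL rectangle.
    roi = phantom_background_roi(height, width)
    for k in range(n_lesions):
        for _ in range(50):
            cy = rng.uniform(0.15 * height, 0.70 * height)
            cx = rng.uniform(0.15 * width, 0.85 * width)
            if not (roi[0] - 12 <= cy <= roi[2] + 12 and roi[1] - 12 <= cx <= roi[3] + 12):
                break
        a = rng.uniform(0.05, 0.14) * height
        b = rng.uniform(0.05, 0.14) * width
        theta = rng.uniform(0.0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        contrast = 0.30 if k % 2 == 0 else -0.28
        img[mask] += contrast

    return np.clip(img, 0.0, 1.0)


def replicate_channels(image: np.ndarray, channels: int) -> np.ndarray:
    """Replicate a single-channel image to ``(H, W, channels)``."""
    if channels == 1:
        return image if image.ndim == 2 else image[..., 0]
    if image.ndim == 2:
        return np.repeat(image[:, :, None], channels, axis=2)
    if image.shape[2] == channels:
        return image
    raise ValueError(f"cannot map shape {image.shape} to {channels} channels")


# ---------------------------------------------------------------------------
# Augmentation and patch extraction
# ---------------------------------------------------------------------------

def augment(images: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Deterministic 4-variant augmentation: original, rot90, h-flip, v-flip.

    The enumeration is deterministic (rather than sampled) so corpus counts
    are exactly reproducible: ``n`` images in, ``4 n`` out.
    """
    images = list(images)
    if not images:
        raise ValueError("augment requires a nonempty sequence of images")
    out: list[np.ndarray] = []
    for img in images:
        img = np.asarray(img)
        out.extend([img, np.rot90(img), np.fliplr(img), np.flipud(img)])
    return out


def extract_patches(image: np.ndarray, patch: int = 64, stride: int = 64
                    ) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Tile ``image`` into ``patch``×``patch`` windows in raster order.

    Windows are half-open ``[r, r+patch) × [c, c+patch)``, 0-based; windows
    that would overrun the border are discarded (no padding).  Returned
    patches are views into the source.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if patch > min(h, w):
        raise ValueError(f"patch size {patch} exceeds image side {min(h, w)}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = []
    for r in range(0, h - patch + 1, stride):
        for c in range(0, w - patch + 1, stride):
            out.append((image[r:r + patch, c:c + patch], (r, c)))
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class PatchPair:
    """A clean/noisy 64×64 (by default) training pair with its origin."""

    clean: np.ndarray
    noisy: np.ndarray
    origin: tuple[int, int, int]      # (image id, row, col)
    noise: SpeckleParams | None = None

    def __post_init__(self) -> None:
        if self.clean.shape != self.noisy.shape:
            raise ValueError("clean and noisy patches must have identical shapes")


@dataclass
class DatasetSplit:
    """Image-level-disjoint train/val/test patch pairs plus provenance."""

    train: list[PatchPair]
    val: list[PatchPair]
    test: list[PatchPair]
    provenance: dict = field(default_factory=dict)

    def source_ids(self, part: str) -> set[int]:
        return {p.origin[0] for p in getattr(self, part)}


def _partition_counts(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = np.argsort([-(q - c) for q, c in zip(quotas, counts)], kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def make_dataset(n_images: int, seed: int,
                 noise_variances: Sequence[float] = (0.01, 0.09, 0.25),
                 split: Sequence[float] = (0.8, 0.1, 0.1),
                 height: int = 256, width: int = 256,
                 patch: int = 64, stride: int = 64,
                 n_lesions: int = 3,
                 augment_train: bool = True,
                 sigma_semantics: str = "variance",
                 images: Sequence[np.ndarray] | None = None) -> DatasetSplit:
    """Generate phantoms, split them at image level, speckle and patch them.

    Augmentation is applied to the training partition only (after the
    split), so no source image leaks across partitions.  The provenance
    dict records every parameter, including the sigma semantics in force.
    A user-supplied clean-image corpus can be passed via ``images`` in
    place of generated phantoms.
    """
    if images is not None:
        images = [np.asarray(im, dtype=np.float64) for im in images]
        n_images = len(images)
    if n_images < 3:
        raise ValueError("need at least 3 images to populate three partitions")
    fr = np.asarray(split, dtype=float)
    if np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"split fractions must be positive and sum to 1, got {tuple(split)}")

    rng = np.random.default_rng(seed)
    image_seeds = rng.integers(0, 2 ** 31 - 1, size=n_images)
    noise_seeds = rng.integers(0, 2 ** 31 - 1, size=10 * n_images * max(len(noise_variances), 1))
    order = rng.permutation(n_images)
    n_tr, n_va, n_te = _partition_counts(n_images, fr)
    parts = {
        "train": order[:n_tr],
        "val": order[n_tr:n_tr + n_va],
        "test": order[n_tr + n_va:],
    }

    pairs: dict[str, list[PatchPair]] = {"train": [], "val": [], "test": []}
    noise_idx = 0
    for part, ids in parts.items():
        for img_id in ids:
            clean = images[img_id] if images is not None else \
                generate_phantom(int(image_seeds[img_id]), height, width, n_lesions)
            variants = augment([clean]) if (augment_train and part == "train") else [clean]
            for variant in variants:
                for var in noise_variances:
                    params = SpeckleParams(
                        sigma=float(var), sigma_semantics=sigma_semantics,
                        seed=int(noise_seeds[noise_idx % len(noise_seeds)]))
                    noise_idx += 1
                    noisy = add_speckle(variant, params)
                    clean_patches = extract_patches(variant, patch, stride)
                    noisy_patches = extract_patches(noisy, patch, stride)
                    for (cp, (r, c)), (np_, _) in zip(clean_patches, noisy_patches):
                        pairs[part].append(PatchPair(cp, np_, (int(img_id), r, c), params))

    provenance = {
        "n_images": n_images, "seed": seed,
        "noise_variances": [float(v) for v in noise_variances],
        "sigma_semantics": sigma_semantics,
        "split": [float(f) for f in fr], "height": height, "width": width,
        "patch": patch, "stride": stride, "n_lesions": n_lesions,
        "augment_train": augment_train,
        "augmentation": "deterministic x4 (original, rot90, hflip, vflip)",
        "clipping": "none",
    }
    return DatasetSplit(pairs["train"], pairs["val"], pairs["test"], provenance)
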