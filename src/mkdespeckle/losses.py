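"""The composite training objective: (MSE + α·KD + β·SSIM + γ·L1) / PSNR.

The student objective combines four terms:

* **MSE** — pixelwise reconstruction accuracy;
* **KD** — temperature-scaled Kullback–Leibler distillation between the
  teacher's and student's per-patch pixel distributions (softmax over the
  flattened patch at temperature T, KL(teacher ∥ student) in nats);
* **SSIM** — the structural dissimilarity ``1 − SSIM`` so that minimizing
  the loss raises structural similarity (a ``plus_ssim`` switch adds
  ``+SSIM`` instead, kept for ablation);
* **L1** — mean absolute error, favouring sparsity of residuals and edge
  preservation.

The sum is divided by the PSNR of the current batch: when output quality is
poor the effective loss is inflated (stronger gradients); as PSNR rises the
loss deflates, encouraging finer corrections.  The divisor is treated as a
detached scale factor — no gradient flows through it — and is floored at
``epsilon`` so a perfect batch (sentinel PSNR 0) cannot divide by zero.
The teacher is pretrained with the same objective minus the distillation
term.

All functions accept numpy or ``Tensor`` batches, ``(N, H, W)`` or
channels-last ``(N, H, W, C)``; with Tensor inputs the result carries the
differentiable graph.  Plain numpy inputs are computed in float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import SSIMParams, gaussian_window
from .nn.autodiff import Tensor, conv2d, softmax


@dataclass
class LossWeights:
    """Weights and switches of the composite objective.

    ``alpha`` scales distillation, ``beta`` the SSIM term, ``gamma_l1`` the
    L1 term; ``temperature`` softens the softmax in the KD term;
    ``epsilon`` guards the KD logarithms and floors the PSNR divisor.
    ``mse_weight`` exists for ablations that drop the MSE term;
    ``psnr_divisor=False`` reproduces the standard weighted-sum loss.
    """

    alpha: float = 0.3
    beta: float = 1.0
    gamma_l1: float = 1.0
    temperature: float = 0.8
    epsilon: float = 1e-10
    mse_weight: float = 1.0
    ssim_sign: str = "dissim"          # "dissim" (1 - SSIM) or "plus_ssim" (+SSIM)
    psnr_divisor: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if min(self.alpha, self.beta, self.gamma_l1, self.mse_weight) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.ssim_sign not in ("dissim", "plus_ssim"):
            raise ValueError("ssim_sign must be 'dissim' or 'plus_ssim'")


@dataclass
class LossBreakdown:
    """The individual contributions and the assembled total.

    ``total = (mse_term + alpha·kd_term + beta·ssim_term + gamma_l1·l1_term)
    / psnr_divisor``; ``mse_term`` already includes ``mse_weight`` so the
    identity holds under every ablation switch.  ``graph`` holds the
    differentiable total when the inputs were Tensors.
    """

    mse_term: float
    kd_term: float
    ssim_term: float
    l1_term: float
    psnr_divisor: float
    total: float
    graph: Tensor | None = None


def _as_batch(x) -> Tensor:
    """Coerce a batch to a channels-last ``(N, H, W, C)`` Tensor."""
    if isinstance(x, Tensor):
        if x.ndim == 3:
            n, h, w = x.shape
            return x.reshape(n, h, w, 1)
        if x.ndim == 4:
            return x
        raise ValueError(f"expected a 3-D or 4-D batch, got shape {x.shape}")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:                       # (N, H, W)
        return Tensor(x[..., None])
    if x.ndim == 4:                       # (N, H, W, C)
        return Tensor(x)
    raise ValueError(f"expected a 3-D or 4-D batch, got shape {x.shape}")


def _result(value: Tensor, *inputs) -> "Tensor | float":
    if any(isinstance(i, Tensor) for i in inputs):
        return value
    return value.item()


# ---------------------------------------------------------------------------
# Individual terms
# ---------------------------------------------------------------------------

def l1_term(g, p_s):
    """Mean absolute difference over the batch."""
    gt, ps = _as_batch(g), _as_batch(p_s)
    if gt.shape != ps.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {ps.shape}")
    return _result((gt - ps).abs().mean(), g, p_s)


def mse_term(g, p_s):
    """Mean squared difference over the batch."""
    gt, ps = _as_batch(g), _as_batch(p_s)
    if gt.shape != ps.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {ps.shape}")
    return _result(((gt - ps) ** 2).mean(), g, p_s)


def distillation_term(p_t, p_s, temperature: float = 0.8, epsilon: float = 1e-10):
    """Temperature-scaled KL(teacher ∥ student) over flattened patches.

    Each sample's output is flattened to a vector of pixel logits; both
    vectors pass through a softmax at temperature T, and the divergence
    ``Σ q_t · log((q_t + ε)/(q_s + ε))`` is averaged over the batch (nats).
    The teacher side is detached: distillation shapes the student only.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    pt, ps = _as_batch(p_t), _as_batch(p_s)
    if pt.shape != ps.shape:
        raise ValueError(f"shape mismatch: {pt.shape} vs {ps.shape}")
    n = pt.shape[0]
    qt = softmax(pt.detach().reshape(n, -1) * (1.0 / temperature), axis=1)
    qs = softmax(ps.reshape(n, -1) * (1.0 / temperature), axis=1)
    kl = (qt * ((qt + epsilon).log() - (qs + epsilon).log())).sum(axis=1).mean()
    return _result(kl, p_t, p_s)


def ssim_term(g, p_s, params: SSIMParams | None = None, sign: str = "dissim"):
    """Structural term of the objective: ``1 − SSIM`` (or ``+SSIM``).

    Differentiable SSIM with the same convention as :func:`.metrics.ssim`
    (Gaussian-weighted window, valid windows only, per-channel mean).
    """
    params = params or SSIMParams()
    gt, ps = _as_batch(g), _as_batch(p_s)
    if gt.shape != ps.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {ps.shape}")
    s = _ssim_batch(gt, ps, params)
    out = (1.0 - s) if sign == "dissim" else s
    return _result(out, g, p_s)


def _ssim_batch(gt: Tensor, ps: Tensor, params: SSIMParams) -> Tensor:
    n, h, w, c = gt.shape
    if min(h, w) < params.window:
        raise ValueError(f"patch sides ({h}, {w}) smaller than SSIM window {params.window}")
    win = Tensor(gaussian_window(params.window, params.gaussian_sigma)
                 .astype(gt.data.dtype)[:, :, None, None])

    def filt(x: Tensor) -> Tensor:
        # per-channel filtering: fold channels into the batch axis
        xc = x.transpose((0, 3, 1, 2)).reshape(n * c, h, w, 1)
        return conv2d(xc, win)

    x, y = gt, ps
    mu_x = filt(x)
    mu_y = filt(y)
    sxx = filt(x * x) - mu_x * mu_x
    syy = filt(y * y) - mu_y * mu_y
    sxy = filt(x * y) - mu_x * mu_y
    c1, c2 = params.c1, params.c2
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * sxy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)
    return (num / den).mean()


# ---------------------------------------------------------------------------
# Assembled objectives
# ---------------------------------------------------------------------------

def total_loss(g, p_s, p_t, w: LossWeights | None = None, peak: float = 1.0,
               ssim_params: SSIMParams | None = None) -> LossBreakdown:
    """The full student objective with its breakdown.

    The PSNR divisor is computed from the batch MSE outside the graph
    (detached), floored at ``w.epsilon``; with a perfect batch the
    numerator is 0 and the total is 0 regardless of the sentinel PSNR.
    """
    w = w or LossWeights()
    gt, ps = _as_batch(g), _as_batch(p_s)
    if gt.shape != ps.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {ps.shape}")

    mse_t = ((gt - ps) ** 2).mean() * w.mse_weight
    if w.alpha > 0 and p_t is not None:
        kd_t = distillation_term(_as_batch(p_t), ps, w.temperature, w.epsilon)
    else:
        kd_t = Tensor(0.0)
    ssim_t = ssim_term(gt, ps, ssim_params, sign=w.ssim_sign) if w.beta > 0 else Tensor(0.0)
    l1_t = (gt - ps).abs().mean() if w.gamma_l1 > 0 else Tensor(0.0)

    numerator = mse_t + w.alpha * kd_t + w.beta * ssim_t + w.gamma_l1 * l1_t

    if w.psnr_divisor:
        batch_mse = float(((gt.data - ps.data) ** 2).mean())
        psnr_val = 0.0 if batch_mse == 0.0 else 10.0 * np.log10(peak ** 2 / batch_mse)
        divisor = max(psnr_val, w.epsilon)
    else:
        divisor = 1.0
    total = numerator * (1.0 / divisor)

    breakdown = LossBreakdown(
        mse_term=float(mse_t.data),
        kd_term=float(kd_t.data),
        ssim_term=float(ssim_t.data),
        l1_term=float(l1_t.data),
        psnr_divisor=float(divisor),
        total=float(total.data),
        graph=total if total.requires_grad else None,
    )
    return breakdown


def teacher_loss(g, p_t, w: LossWeights | None = None, peak: float = 1.0,
                 ssim_params: SSIMParams | None = None) -> LossBreakdown:
    """The teacher's pretraining objective: the total with distillation off."""
    w = w or LossWeights()
    w_t = LossWeights(alpha=0.0, beta=w.beta, gamma_l1=w.gamma_l1,
                      temperature=w.temperature, epsilon=w.epsilon,
                      mse_weight=w.mse_weight, ssim_sign=w.ssim_sign,
                      psnr_divisor=w.psnr_divisor)
    return total_loss(g, p_t, None, w_t, peak=peak, ssim_params=ssim_params)
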