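"""Differentiable segmentation losses: soft Dice, cross-entropy, Focal, TopK,
and weighted compounds of them.

All losses accept either a :class:`~tunet.autodiff.Tensor` probability map or
a plain numpy array (wrapped as a constant) of shape (H, W), (1, H, W) or
(B, 1, H, W), together with a binary ground-truth mask of the same spatial
shape.  Per-image losses are averaged over the batch, matching per-image
metric reporting.  Probabilities are clamped to [eps, 1-eps] before any log.

The TopK loss is an online-hard-example-mining variant of cross-entropy: the
per-pixel two-class cross-entropy is computed, the k% highest-loss pixels are
selected per image, and their losses averaged.  The default normalizes by the
number of selected pixels |K| (preserving the cross-entropy scale, so
k=100% reduces exactly to the mean CE); ``literal_n_norm=True`` divides by
the total pixel count N instead — the two differ by the constant factor
|K|/N, so gradient directions are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossConfig", "soft_dice", "dice_loss", "ce_loss", "focal_loss",
    "topk_loss", "joint_loss", "JointLossResult", "EPS",
]

EPS = 1e-7
_COMPONENTS = ("dice", "ce", "focal", "topk")


@dataclass
class LossConfig:
    """Which loss components to combine, and how.

    The default (dice + topk, unit weights, k = 10%) is the joint loss used
    for training; other subsets reproduce the loss-ablation arms
    (Dice, Dice & CE, Dice & Focal, Dice & CE & TopK, Dice & TopK).
    """

    components: tuple = ("dice", "topk")
    k_percent: float = 10.0
    focal_gamma: float = 2.0
    weights: dict = field(default_factory=dict)
    smooth: float = 1e-6
    literal_n_norm: bool = False

    def validate(self) -> None:
        if not self.components:
            raise ValueError("components: at least one loss component required")
        for c in self.components:
            if c not in _COMPONENTS:
                raise ValueError(f"components: unknown component {c!r}")
        if not 0.0 < self.k_percent <= 100.0:
            raise ValueError(f"k_percent: {self.k_percent} not in (0, 100]")
        if self.focal_gamma < 0:
            raise ValueError(f"focal_gamma: {self.focal_gamma} must be >= 0")
        for c, w in self.weights.items():
            if w < 0:
                raise ValueError(f"weights: negative weight for {c!r}")

    def weight(self, component: str) -> float:
        return float(self.weights.get(component, 1.0))


def _as_batch(probs, gt):
    """Coerce inputs to (B, P) flattened per-image arrays/tensors."""
    if not isinstance(probs, Tensor):
        probs = Tensor(np.asarray(probs))
    g = np.asarray(gt)
    if probs.shape != g.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs gt {g.shape}")
    if not np.isin(g, (0, 1)).all():
        raise ValueError("ground-truth mask must be binary")
    if probs.ndim == 2:
        b = 1
    elif probs.ndim == 3:
        b = probs.shape[0]
    elif probs.ndim == 4:
        b = probs.shape[0]
    else:
        raise ValueError(f"unsupported input rank {probs.ndim}")
    npix = probs.size // b
    return probs.reshape(b, npix), g.reshape(b, npix).astype(probs.dtype)


def soft_dice(probs, gt, smooth: float = 1e-6):
    """Soft Dice coefficient 2|X∩Y|/(|X|+|Y|), per image, batch-averaged.

    With binary ``probs`` this equals the set-based Dice; the ``smooth`` term
    defines the both-empty case as 1 (perfect agreement).
    """
    p, g = _as_batch(probs, gt)
    gt_t = Tensor(g)
    inter = (p * gt_t).sum(axis=1)
    denom = p.sum(axis=1) + gt_t.sum(axis=1)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return dice.mean()


def dice_loss(probs, gt, smooth: float = 1e-6):
    """1 - soft Dice."""
    return 1.0 - soft_dice(probs, gt, smooth=smooth)


def _pixel_ce(p: Tensor, g: np.ndarray) -> Tensor:
    """Per-pixel two-class cross-entropy -[g log p + (1-g) log(1-p)]."""
    pc = p.clip(EPS, 1.0 - EPS)
    gt_t = Tensor(g)
    return -(gt_t * pc.log() + (1.0 - gt_t) * (1.0 - pc).log())


def ce_loss(probs, gt):
    """Mean pixel-wise binary cross-entropy."""
    p, g = _as_batch(probs, gt)
    return _pixel_ce(p, g).mean(axis=1).mean()


def focal_loss(probs, gt, gamma: float = 2.0):
    """Focal loss: per-pixel CE scaled by (1 - p_true)^gamma; gamma=0 is CE."""
    p, g = _as_batch(probs, gt)
    ce = _pixel_ce(p, g)
    pc = p.clip(EPS, 1.0 - EPS)
    gt_t = Tensor(g)
    pt = pc * gt_t + (1.0 - pc) * (1.0 - gt_t)
    mod = (1.0 - pt) ** gamma if gamma != 0 else 1.0
    return (ce * mod).mean(axis=1).mean()


def topk_loss(probs, gt, k_percent: float = 10.0, literal_n_norm: bool = False):
    """Mean cross-entropy over the ceil(k% * N) worst pixels of each image."""
    if not 0.0 < k_percent <= 100.0:
        raise ValueError(f"k_percent {k_percent} not in (0, 100]")
    p, g = _as_batch(probs, gt)
    b, npix = p.shape
    kcount = int(np.ceil(k_percent / 100.0 * npix))
    ce = _pixel_ce(p, g)
    if kcount >= npix:
        sel = ce
    else:
        # selection is made on detached values; gradients flow only through
        # the gathered entries (standard OHEM practice)
        idx = np.argpartition(ce.data, npix - kcount, axis=1)[:, npix - kcount:]
        rows = np.arange(b)[:, None]
        sel = ce[rows, idx]
    denom = npix if literal_n_norm else kcount
    return sel.sum(axis=1).mean() * (1.0 / denom)


@dataclass
class JointLossResult:
    total: Tensor
    components: dict  # name -> Tensor (unweighted component values)
    weights: dict     # name -> float

    def breakdown(self) -> dict:
        """Weighted per-component values as floats."""
        return {c: self.weights[c] * t.item() for c, t in self.components.items()}


def joint_loss(probs, gt, cfg: LossConfig | None = None) -> JointLossResult:
    """Weighted sum of the configured components (default: Dice + TopK)."""
    cfg = cfg or LossConfig()
    cfg.validate()
    fns = {
        "dice": lambda: dice_loss(probs, gt, smooth=cfg.smooth),
        "ce": lambda: ce_loss(probs, gt),
        "focal": lambda: focal_loss(probs, gt, gamma=cfg.focal_gamma),
        "topk": lambda: topk_loss(probs, gt, k_percent=cfg.k_percent,
                                  literal_n_norm=cfg.literal_n_norm),
    }
    comps = {c: fns[c]() for c in cfg.components}
    weights = {c: cfg.weight(c) for c in cfg.components}
    total = None
    for c, t in comps.items():
        term = t * weights[c]
        total = term if total is None else total + term
    return JointLossResult(total=total, components=comps, weights=weights)
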