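"""Tversky index, focal Tversky loss (FTL), and the combined dual-task loss.

The Tversky index generalizes Dice by weighting false negatives (alpha)
and false positives (beta) asymmetrically::

    TI_c = (sum_i p_ic g_ic + eps)
         / (sum_i p_ic g_ic + alpha sum_i (1-p_ic) g_ic
            + beta sum_i p_ic (1-g_ic) + eps)

The focal Tversky loss focuses training on hard classes::

    FTL = sum_c (1 - TI_c) ** gamma

The combined loss adds, to the three-class tissue FTL (loss 1), an FTL over
the binary air/tissue split (loss 2), which targets the breast-outline
(convex hull) errors specifically::

    L = FTL({air, adipose, dense}) + lambda_outline * FTL({air, tissue})

Probability maps are arrays of shape ``(C, ...)`` with per-voxel class
probabilities summing to 1; targets are one-hot arrays of the same shape.
Analytic gradients with respect to the probabilities are provided for the
numpy trainer in :mod:`vctdbt.segmenter`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AIR, ADIPOSE, DENSE = 0, 1, 2


@dataclass(frozen=True)
class LossConfig:
    """FTL hyperparameters; defaults follow the training protocol
    (alpha=0.7, beta=0.3, gamma=3/4)."""

    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 0.75
    epsilon: float = 1e-6
    lambda_outline: float = 1.0
    tissue_classes_only: bool = False   # restrict loss 1 to {adipose, dense}

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lambda_outline < 0:
            raise ValueError("lambda_outline must be >= 0")

    @property
    def loss1_classes(self) -> tuple[int, ...]:
        return (ADIPOSE, DENSE) if self.tissue_classes_only else (AIR, ADIPOSE, DENSE)


def _check_maps(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")


def one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """One-hot target map (C, ...) from an integer label volume."""
    g = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        g[c] = labels == c
    return g


def tversky_index(p: np.ndarray, g: np.ndarray, c: int,
                  cfg: LossConfig | None = None) -> float:
    """Tversky index of class ``c`` between probability and target maps."""
    cfg = cfg or LossConfig()
    _check_maps(p, g)
    pc, gc = p[c].astype(np.float64), g[c].astype(np.float64)
    tp = float((pc * gc).sum())
    fn = float(((1.0 - pc) * gc).sum())
    fp = float((pc * (1.0 - gc)).sum())
    return (tp + cfg.epsilon) / (tp + cfg.alpha * fn + cfg.beta * fp + cfg.epsilon)


def focal_tversky_loss(p: np.ndarray, g: np.ndarray,
                       classes=None, cfg: LossConfig | None = None) -> float:
    """Sum over classes of (1 - TI_c) ** gamma."""
    cfg = cfg or LossConfig()
    if classes is None:
        classes = range(p.shape[0])
    classes = tuple(classes)
    if not classes:
        raise ValueError("class set must be non-empty")
    return float(sum((1.0 - tversky_index(p, g, c, cfg)) ** cfg.gamma
                     for c in classes))


def to_outline_targets(g: np.ndarray) -> np.ndarray:
    """Merge three-class maps to binary {air, tissue} by channel summation.

    Works on targets and probability maps alike: tissue = adipose + dense,
    air unchanged.
    """
    if g.shape[0] != 3:
        raise ValueError("expected a three-class map")
    return np.stack([g[AIR], g[ADIPOSE] + g[DENSE]])


def combined_loss(p: np.ndarray, g: np.ndarray,
                  cfg: LossConfig | None = None) -> float:
    """Loss (1) over tissue classes + lambda_outline * loss (2) over
    the binary air/tissue split."""
    cfg = cfg or LossConfig()
    if p.shape[0] != 3:
        raise ValueError("expected three-class maps")
    total = focal_tversky_loss(p, g, cfg.loss1_classes, cfg)
    if cfg.lambda_outline > 0:
        total += cfg.lambda_outline * focal_tversky_loss(
            to_outline_targets(p), to_outline_targets(g), (0, 1), cfg)
    return float(total)


# ---------------------------------------------------------------------------
# analytic gradients (trainer support)
# ---------------------------------------------------------------------------

def _ftl_grad_into(p: np.ndarray, g: np.ndarray, classes, cfg: LossConfig,
                   out: np.ndarray, weight: float,
                   channel_map=None) -> float:
    """Accumulate weight * dFTL/dp into ``out``; returns the FTL value.

    ``channel_map`` maps merged-channel index -> tuple of original channels
    (used for the binary outline loss, whose tissue channel is the sum of
    adipose and dense probabilities).
    """
    value = 0.0
    for c in classes:
        pc, gc = p[c].astype(np.float64), g[c].astype(np.float64)
        tp = (pc * gc).sum()
        fn = ((1.0 - pc) * gc).sum()
        fp = (pc * (1.0 - gc)).sum()
        num = tp + cfg.epsilon
        den = tp + cfg.alpha * fn + cfg.beta * fp + cfg.epsilon
        ti = num / den
        value += (1.0 - ti) ** cfg.gamma
        # dTI/dp_ic = [g*den - num*(g - alpha*g + beta*(1-g))] / den^2
        dti = (gc * den - num * (gc * (1.0 - cfg.alpha) + cfg.beta * (1.0 - gc))) / den**2
        dloss = -cfg.gamma * max(1.0 - ti, 1e-12) ** (cfg.gamma - 1.0) * dti
        targets = channel_map[c] if channel_map is not None else (c,)
        for t in targets:
            out[t] += weight * dloss
    return float(value)


def combined_loss_grad(p: np.ndarray, g: np.ndarray,
                       cfg: LossConfig | None = None) -> tuple[float, np.ndarray]:
    """Combined loss value and its gradient with respect to ``p``."""
    cfg = cfg or LossConfig()
    _check_maps(p, g)
    grad = np.zeros(p.shape, dtype=np.float64)
    value = _ftl_grad_into(p, g, cfg.loss1_classes, cfg, grad, 1.0)
    if cfg.lambda_outline > 0:
        pb, gb = to_outline_targets(p), to_outline_targets(g)
        value += cfg.lambda_outline * _ftl_grad_into(
            pb, gb, (0, 1), cfg, grad, cfg.lambda_outline,
            channel_map={0: (AIR,), 1: (ADIPOSE, DENSE)})
    return value, grad
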