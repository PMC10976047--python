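"""Loss functions for heavily imbalanced binary segmentation.

All losses operate on a binary target mask ``y`` (1 = lesion/foreground) and
either a probability map ``p`` in [0, 1] or a logit map ``f`` (pre-sigmoid
network output, ``p = sigmoid(f)``).  Scalar losses use mean-over-voxels
reduction so that values are comparable across patch and batch sizes.

Besides the classical value-defined losses (cross-entropy, focal,
generalised Dice, binary Dice and a Dice+cross-entropy mix), the module
implements a *gradient-defined* weighted loss: instead of weighting the loss
value, the class weights and the focal-style modulating factor are applied
directly to the gradient of sigmoid + cross-entropy with respect to the
logits,

    dL/df_i = -alpha * (1 - p_i)^gamma          for foreground voxels,
    dL/df_i = +(1 - alpha) * p_i^gamma          for background voxels,

scaled by 1/N to match the mean reduction of the other losses.  This
gradient has no closed-form antiderivative, so the loss is specified by a
custom backward contract: the training engine must use
:func:`weighted_gradient_backward` verbatim, and the forward value (an
alpha-weighted cross-entropy) is for monitoring only.

The sign convention makes the update direction consistent with the
sigmoid + cross-entropy gradient ``(p - y)/N``: with ``gamma=1, alpha=0.5``
the gradient reduces exactly to half of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "ClassCounts",
    "LossConfig",
    "PRESETS",
    "preset",
    "class_counts",
    "sigmoid",
    "cross_entropy",
    "focal",
    "generalized_dice",
    "binary_dice",
    "mixed",
    "weighted_gradient_backward",
    "weighted_gradient_loss",
    "loss_gradient_wrt_logits",
    "LogitLoss",
    "make_logit_loss",
]

# Probabilities are clipped away from exact 0/1 before any logarithm; the
# cross-entropy diverges at the boundary.
PROB_CLIP = 1e-7


# ---------------------------------------------------------------------------
# class counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassCounts:
    """Voxel counts of a binary mask: total N, foreground N_fg, background N_bg."""

    n_total: int
    n_fg: int
    n_bg: int

    def __post_init__(self) -> None:
        if self.n_fg + self.n_bg != self.n_total or min(self.n_fg, self.n_bg) < 0:
            raise ValueError("inconsistent class counts")

    @property
    def fg_fraction(self) -> float:
        return self.n_fg / self.n_total if self.n_total else 0.0


def _check_binary(target: np.ndarray) -> np.ndarray:
    t = np.asarray(target)
    if not np.isin(t, (0, 1)).all():
        raise ValueError("target mask must contain only 0/1 labels")
    return t.astype(np.float64)


def _check_pair(pred, target) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=np.float64)
    t = _check_binary(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    return p, t


def class_counts(target) -> ClassCounts:
    """Count total, foreground and background voxels of a binary mask."""
    t = _check_binary(target)
    n = t.size
    n_fg = int(round(float(t.sum())))
    return ClassCounts(n_total=n, n_fg=n_fg, n_bg=n - n_fg)


# ---------------------------------------------------------------------------
# configuration and presets
# ---------------------------------------------------------------------------

BATCH_ADAPTIVE = "batch"  # alpha / Dice weights recomputed from each target
_VALID_NAMES = ("xent", "focal1", "focal2", "gdsc", "dsc", "mixed", "new")


@dataclass(frozen=True)
class LossConfig:
    """Which loss to use and its parameters.

    ``alpha`` and the generalised-Dice weights may be the string ``"batch"``,
    meaning they are recomputed from the class counts of every target they
    are applied to (``alpha = N_bg / N``; ``w_c = 1 / N_c^2``).
    """

    name: str
    alpha: Union[float, str, None] = None
    gamma: float = 0.0
    w_fg: Union[float, str, None] = None
    w_bg: Union[float, str, None] = None
    epsilon: float = 1e-6
    mix_weights: Tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.name not in _VALID_NAMES and self.name != "focal":
            raise ValueError(f"unknown loss name {self.name!r}")
        if isinstance(self.alpha, float) and not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


PRESETS = {
    "xent": LossConfig("xent"),
    "focal1": LossConfig("focal1", alpha=0.25, gamma=2.0),
    "focal2": LossConfig("focal2", alpha=0.75, gamma=2.0),
    "gdsc": LossConfig("gdsc", w_fg=BATCH_ADAPTIVE, w_bg=BATCH_ADAPTIVE),
    "dsc": LossConfig("dsc", w_fg=1.0, w_bg=0.0),
    "mixed": LossConfig("mixed", mix_weights=(1.0, 1.0)),
    "new": LossConfig("new", alpha=BATCH_ADAPTIVE, gamma=2.0),
}


def preset(name: str) -> LossConfig:
    """Return the named loss preset (xent, focal1, focal2, gdsc, dsc, mixed, new)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown loss preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# scalar losses on probabilities
# ---------------------------------------------------------------------------

def sigmoid(f) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("logits must be finite")
    out = np.empty_like(f)
    pos = f >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-f[pos]))
    ef = np.exp(f[~pos])
    out[~pos] = ef / (1.0 + ef)
    return out


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)


def cross_entropy(pred, target) -> float:
    """Mean binary cross-entropy: -log p on foreground, -log(1-p) on background."""
    p, t = _check_pair(pred, target)
    pc = _clip(p)
    per_voxel = -(t * np.log(pc) + (1.0 - t) * np.log1p(-pc))
    return float(per_voxel.mean())


def focal(pred, target, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Focal loss: cross-entropy with class weight alpha and modulating factor
    (1-p)^gamma that down-weights confidently correct voxels."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p, t = _check_pair(pred, target)
    pc = _clip(p)
    fg = -alpha * (1.0 - pc) ** gamma * np.log(pc)
    bg = -(1.0 - alpha) * pc**gamma * np.log1p(-pc)
    return float((t * fg + (1.0 - t) * bg).mean())


def generalized_dice(pred, target, w_fg: float, w_bg: float) -> float:
    """Generalised Dice loss with explicit foreground/background class weights.

    With ``w_bg=0, w_fg=1`` this reduces to the binary Dice loss with
    ``epsilon=0``.
    """
    if w_fg < 0 or w_bg < 0 or (w_fg == 0 and w_bg == 0):
        raise ValueError("weights must be >= 0 and not both zero")
    p, t = _check_pair(pred, target)
    n = p.size
    s_xy = float((p * t).sum())
    s_sum = float((p + t).sum())
    num = 2.0 * ((w_fg + w_bg) * s_xy + w_bg * (n - s_sum))
    den = (w_fg - w_bg) * s_sum + 2.0 * n * w_bg
    if den <= 0:
        raise ZeroDivisionError("degenerate generalised Dice denominator <= 0")
    return float(1.0 - num / den)


def _gdsc_weights(counts: ClassCounts) -> Tuple[float, float]:
    """Inverse-squared-volume class weights; an empty class gets weight 0."""
    if counts.n_fg == 0:
        warnings.warn(
            "generalised Dice weights on a batch without foreground voxels; "
            "setting w_fg = 0",
            RuntimeWarning,
            stacklevel=3,
        )
    w_fg = 1.0 / counts.n_fg**2 if counts.n_fg else 0.0
    w_bg = 1.0 / counts.n_bg**2 if counts.n_bg else 0.0
    return w_fg, w_bg


def binary_dice(pred, target, epsilon: float = 1e-6) -> float:
    """Soft binary Dice loss ``1 - (2 sum(p*y) + eps) / (sum(p+y) + eps)``."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    p, t = _check_pair(pred, target)
    s_xy = float((p * t).sum())
    s_sum = float((p + t).sum())
    if epsilon == 0.0 and s_sum == 0.0:
        raise ZeroDivisionError("binary Dice with epsilon=0 on empty pred and target")
    return float(1.0 - (2.0 * s_xy + epsilon) / (s_sum + epsilon))


def mixed(pred, target, epsilon: float = 1e-6,
          mix_weights: Sequence[float] = (1.0, 1.0)) -> float:
    """Equal-weight combination of the binary Dice loss and cross-entropy."""
    w_d, w_c = mix_weights
    if w_d != w_c:
        raise ValueError("mixed loss uses equal weights for its two terms")
    return w_d * binary_dice(pred, target, epsilon) + w_c * cross_entropy(pred, target)


# ---------------------------------------------------------------------------
# gradients with respect to logits
# ---------------------------------------------------------------------------

def weighted_gradient_backward(logits, target, alpha: float, gamma: float) -> np.ndarray:
    """Closed-form logit gradient of the gradient-defined weighted loss.

    Returns ``-alpha (1-p)^gamma / N`` on foreground voxels and
    ``+(1-alpha) p^gamma / N`` on background voxels, with ``p = sigmoid(f)``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    f = np.asarray(logits, dtype=np.float64)
    t = _check_binary(target)
    if f.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {f.shape} vs target {t.shape}")
    p = sigmoid(f)
    n = p.size
    grad = np.where(
        t == 1.0,
        -alpha * (1.0 - p) ** gamma,
        (1.0 - alpha) * p**gamma,
    )
    return grad / n


def _dloss_dprob(name: str, p: np.ndarray, t: np.ndarray,
                 config: LossConfig) -> np.ndarray:
    """Analytic derivative of the scalar (mean-reduced) loss w.r.t. p."""
    n = p.size
    if name == "xent":
        pc = _clip(p)
        return (t * (-1.0 / pc) + (1.0 - t) * (1.0 / (1.0 - pc))) / n
    if name == "focal":
        alpha, gamma = config.alpha, config.gamma
        pc = _clip(p)
        # fg: d/dp [-a (1-p)^g log p] = a g (1-p)^(g-1) log p - a (1-p)^g / p
        fg = alpha * (
            gamma * (1.0 - pc) ** (gamma - 1.0) * np.log(pc) if gamma > 0 else 0.0
        ) - alpha * (1.0 - pc) ** gamma / pc
        bg = -(1.0 - alpha) * (
            gamma * pc ** (gamma - 1.0) * np.log1p(-pc) if gamma > 0 else 0.0
        ) + (1.0 - alpha) * pc**gamma / (1.0 - pc)
        return (t * fg + (1.0 - t) * bg) / n
    if name == "gdsc":
        w_fg, w_bg = _resolve_gdsc_weights(config, t)
        s_xy = float((p * t).sum())
        s_sum = float((p + t).sum())
        num = 2.0 * ((w_fg + w_bg) * s_xy + w_bg * (n - s_sum))
        den = (w_fg - w_bg) * s_sum + 2.0 * n * w_bg
        dnum = 2.0 * ((w_fg + w_bg) * t - w_bg)
        dden = w_fg - w_bg
        return -(dnum * den - num * dden) / den**2
    if name == "dsc":
        eps = config.epsilon
        s_xy = float((p * t).sum())
        s_sum = float((p + t).sum())
        num = 2.0 * s_xy + eps
        den = s_sum + eps
        return -(2.0 * t * den - num) / den**2
    if name == "mixed":
        w_d, w_c = config.mix_weights
        return w_d * _dloss_dprob("dsc", p, t, config) + w_c * _dloss_dprob(
            "xent", p, t, config
        )
    raise ValueError(f"unknown loss name {name!r}")


def _resolve_gdsc_weights(config: LossConfig, t: np.ndarray) -> Tuple[float, float]:
    if config.w_fg == BATCH_ADAPTIVE or config.w_bg == BATCH_ADAPTIVE:
        return _gdsc_weights(class_counts(t))
    return float(config.w_fg), float(config.w_bg)


_CANONICAL = {
    "xent": "xent", "focal": "focal", "focal1": "focal", "focal2": "focal",
    "gdsc": "gdsc", "dsc": "dsc", "mixed": "mixed",
}


def loss_gradient_wrt_logits(loss_name: str, logits, target,
                             config: Optional[LossConfig] = None) -> np.ndarray:
    """Analytic gradient of a value-defined loss composed with sigmoid.

    Chain rule through the sigmoid: ``dL/df_i = dL/dp_i * p_i (1 - p_i)``.
    Accepts the canonical names {xent, focal, gdsc, dsc, mixed} as well as
    the presets focal1/focal2.
    """
    if loss_name not in _CANONICAL:
        raise ValueError(f"unknown loss name {loss_name!r}")
    if config is None:
        config = PRESETS[loss_name if loss_name in PRESETS else "focal1"]
    f = np.asarray(logits, dtype=np.float64)
    t = _check_binary(target)
    if f.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {f.shape} vs target {t.shape}")
    p = sigmoid(f)
    return _dloss_dprob(_CANONICAL[loss_name], p, t, config) * p * (1.0 - p)


def _batch_alpha(t: np.ndarray) -> float:
    counts = class_counts(t)
    if counts.n_fg == 0:
        warnings.warn(
            "gradient-defined loss on a batch without foreground voxels: "
            "alpha = 1, gradient is foreground-silent",
            RuntimeWarning,
            stacklevel=3,
        )
    return counts.n_bg / counts.n_total


def weighted_gradient_loss(logits, target, gamma: float = 2.0,
                           alpha: Optional[float] = None) -> float:
    """Monitoring value of the gradient-defined loss: alpha-weighted
    cross-entropy with per-batch ``alpha = N_bg / N`` unless given.

    The value is informational; only :func:`weighted_gradient_backward`
    defines the optimisation behaviour.
    """
    p, t = _check_pair(sigmoid(logits), target)
    if alpha is None:
        alpha = _batch_alpha(t)
    pc = _clip(p)
    per_voxel = -(alpha * t * np.log(pc) + (1.0 - alpha) * (1.0 - t) * np.log1p(-pc))
    return float(per_voxel.mean())


# ---------------------------------------------------------------------------
# the training-engine loss interface (the custom-backward boundary)
# ---------------------------------------------------------------------------

@dataclass
class LogitLoss:
    """A loss as the training engine sees it: a scalar ``value`` for logging
    and the authoritative ``grad`` with respect to the logits.

    For value-defined losses ``grad`` is the analytic derivative of ``value``;
    for the gradient-defined loss (``new``) ``grad`` *is* the definition and
    ``value`` is a monitoring quantity (alpha-weighted cross-entropy).
    """

    config: LossConfig

    @property
    def name(self) -> str:
        return self.config.name

    def value(self, logits, target) -> float:
        c = self.config
        if c.name == "new":
            return weighted_gradient_loss(logits, target, gamma=c.gamma)
        p = sigmoid(logits)
        if c.name == "xent":
            return cross_entropy(p, target)
        if c.name in ("focal", "focal1", "focal2"):
            return focal(p, target, alpha=c.alpha, gamma=c.gamma)
        if c.name == "gdsc":
            t = _check_binary(target)
            w_fg, w_bg = _resolve_gdsc_weights(c, t)
            return generalized_dice(p, target, w_fg=w_fg, w_bg=w_bg)
        if c.name == "dsc":
            return binary_dice(p, target, epsilon=c.epsilon)
        if c.name == "mixed":
            return mixed(p, target, epsilon=c.epsilon, mix_weights=c.mix_weights)
        raise ValueError(f"unknown loss name {c.name!r}")

    def grad(self, logits, target) -> np.ndarray:
        c = self.config
        if c.name == "new":
            t = _check_binary(target)
            alpha = _batch_alpha(t)
            return weighted_gradient_backward(logits, target, alpha=alpha,
                                              gamma=c.gamma)
        name = "focal" if c.name in ("focal1", "focal2") else c.name
        return loss_gradient_wrt_logits(name, logits, target, config=c)


def make_logit_loss(config: Union[str, LossConfig]) -> LogitLoss:
    """Build the training-engine loss from a preset name or a LossConfig."""
    if isinstance(config, str):
        config = preset(config)
    return LogitLoss(config)
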