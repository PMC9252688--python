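"""Training losses: binary cross-entropy, soft Dice, and their weighted
composite.

Lesions typically occupy a small fraction of an ultrasound frame, so plain
BCE is dominated by the background class while the Dice loss is scale-free
in the foreground size but has a rougher optimisation landscape.  The
composite ``tau * BCE + Dice`` keeps Dice's imbalance robustness and uses a
small BCE term (default tau = 1.5e-3) to smooth optimisation.

All losses micro-average over every pixel passed in (one batch = one ``N``),
accept either numpy arrays (returning a float) or autograd tensors
(returning a scalar tensor on the tape), and are finite for saturated
predictions thanks to probability clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .errors import ConfigError

__all__ = ["LossConfig", "bce_loss", "dice_loss", "composite_loss"]


@dataclass(frozen=True)
class LossConfig:
    """tau: BCE weight in the composite; smooth: Dice smoothing constant;
    clamp_eps: probability clamp applied before logarithms."""

    tau: float = 1.5e-3
    smooth: float = 1.0
    clamp_eps: float = 1e-7

    def __post_init__(self):
        if self.tau < 0:
            raise ConfigError(f"tau must be >= 0, got {self.tau}")
        if self.smooth <= 0:
            raise ConfigError(f"smooth must be > 0, got {self.smooth}")
        if not 0.0 < self.clamp_eps < 0.5:
            raise ConfigError(
                f"clamp_eps must be in (0, 0.5), got {self.clamp_eps}"
            )


def _prepare(p, t) -> tuple[Tensor, np.ndarray, bool]:
    """Validate inputs; returns (p tensor, t array, want_float)."""
    want_float = not isinstance(p, Tensor)
    pt = Tensor(p) if want_float else p
    ta = t.data if isinstance(t, Tensor) else np.asarray(t, dtype=np.float64)
    if pt.shape != ta.shape:
        raise ValueError(f"shape mismatch: p {pt.shape} vs t {ta.shape}")
    if np.any(pt.data < 0.0) or np.any(pt.data > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return pt, ta, want_float


def bce_loss(p, t, cfg: LossConfig = LossConfig()):
    """Binary cross-entropy, averaged over all pixels.

    -(1/N) sum_j [ t_j log p_j + (1 - t_j) log(1 - p_j) ], with p clamped to
    [clamp_eps, 1 - clamp_eps] so the loss stays finite at p in {0, 1}.
    """
    pt, ta, want_float = _prepare(p, t)
    pc = pt.clip(cfg.clamp_eps, 1.0 - cfg.clamp_eps)
    loss = -(ta * pc.log() + (1.0 - ta) * (1.0 - pc).log()).mean()
    return loss.item() if want_float else loss


def dice_loss(p, t, cfg: LossConfig = LossConfig()):
    """Soft Dice loss: 1 - (2 sum(p t) + s) / (sum(p^2) + sum(t^2) + s).

    The smoothing constant keeps the ratio defined when both prediction and
    truth are empty (the loss is then exactly 0).
    """
    pt, ta, want_float = _prepare(p, t)
    num = 2.0 * (pt * ta).sum() + cfg.smooth
    den = (pt**2).sum() + float((ta**2).sum()) + cfg.smooth
    loss = 1.0 - num / den
    return loss.item() if want_float else loss


def composite_loss(p, t, cfg: LossConfig = LossConfig()):
    """Weighted composite: tau * BCE + Dice (tau defaults to 1.5e-3)."""
    pt, ta, want_float = _prepare(p, t)
    loss = cfg.tau * bce_loss(pt, ta, cfg) + dice_loss(pt, ta, cfg)
    return loss.item() if want_float else loss
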