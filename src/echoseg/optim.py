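"""Weight initialisation, Adam, and the training loop.

Initialisation draws convolution weights from a zero-mean Gaussian with
standard deviation sqrt(2 / fan_in), fan_in = k^2 * (input channels) --
the scaling that keeps ReLU activations' variance constant across layers.
Biases start at zero.

The optimiser is Adam with first/second-moment decay (beta1, beta2),
bias-corrected moments, and update theta <- theta - lr * m_hat /
(sqrt(v_hat) + stabilizer).  Defaults are beta1 = 0.95, lr = 1.5e-4,
stabilizer = 1.5e-8, beta2 = 0.999.  A ``literal_correction`` switch
replaces the standard 1/(1 - beta^t) bias corrections with plain division
by beta (and permits beta2 = 1.0, which freezes the second moment at its
initial value); it exists for side-by-side comparison and is not the
default because it is not a convergent Adam variant.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Parameter, Tensor
from .errors import ConfigError
from .losses import LossConfig, bce_loss, composite_loss, dice_loss
from .metrics import dice_score
from .phantom import SegmentationPair

__all__ = [
    "init_weights",
    "AdamConfig",
    "AdamState",
    "adam_step",
    "Adam",
    "TrainConfig",
    "EpochRecord",
    "FitResult",
    "fit",
]

_LOSS_FNS = {"composite": composite_loss, "bce": bce_loss, "dice": dice_loss}


def init_weights(shape, rng: np.random.Generator,
                 fan_in: int | None = None) -> np.ndarray:
    """Scaled-Gaussian weight draw: N(0, 2 / fan_in).

    For a (out, in, kh, kw) convolution kernel fan_in = in * kh * kw; for a
    (out, in) dense matrix fan_in = in.  Pass ``fan_in`` explicitly for
    other shapes.
    """
    shape = tuple(int(s) for s in shape)
    if fan_in is None:
        if len(shape) == 4:
            fan_in = shape[1] * shape[2] * shape[3]
        elif len(shape) == 2:
            fan_in = shape[1]
        else:
            raise ConfigError(
                f"cannot infer fan_in for shape {shape}; pass fan_in explicitly"
            )
    if fan_in < 1:
        raise ConfigError(f"fan_in must be >= 1, got {fan_in}")
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


@dataclass(frozen=True)
class AdamConfig:
    lr: float = 1.5e-4
    beta1: float = 0.95
    beta2: float = 0.999
    stabilizer: float = 1.5e-8
    literal_correction: bool = False

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigError(f"lr must be > 0, got {self.lr}")
        if not 0.0 <= self.beta1 < 1.0:
            raise ConfigError(f"beta1 must be in [0, 1), got {self.beta1}")
        upper_ok = self.beta2 <= 1.0 if self.literal_correction else self.beta2 < 1.0
        if not (0.0 <= self.beta2 and upper_ok):
            raise ConfigError(f"beta2 out of range: {self.beta2}")
        if self.stabilizer <= 0:
            raise ConfigError(f"stabilizer must be > 0, got {self.stabilizer}")


@dataclass
class AdamState:
    """Per-parameter Adam accumulators (first moment m, second moment v)."""

    theta: np.ndarray
    config: AdamConfig = field(default_factory=AdamConfig)
    t: int = 0
    m: np.ndarray = None
    v: np.ndarray = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.m is None:
            self.m = np.zeros_like(self.theta)
        if self.v is None:
            self.v = np.zeros_like(self.theta)


def adam_step(state: AdamState, grad: np.ndarray) -> AdamState:
    """One Adam update; mutates and returns ``state``.

    m <- beta1 m + (1-beta1) g;  v <- beta2 v + (1-beta2) g^2;
    m_hat = m / (1 - beta1^t);   v_hat = v / (1 - beta2^t);
    theta <- theta - lr * m_hat / (sqrt(v_hat) + stabilizer).

    With ``literal_correction`` the corrections become m/beta1 and v/beta2.
    """
    grad = np.asarray(grad, dtype=np.float64)
    if grad.shape != state.theta.shape:
        raise ValueError(
            f"gradient shape {grad.shape} != parameter shape {state.theta.shape}"
        )
    cfg = state.config
    state.t += 1
    state.m = cfg.beta1 * state.m + (1.0 - cfg.beta1) * grad
    state.v = cfg.beta2 * state.v + (1.0 - cfg.beta2) * grad**2
    if cfg.literal_correction:
        m_hat = state.m / cfg.beta1
        v_hat = state.v / cfg.beta2
    else:
        m_hat = state.m / (1.0 - cfg.beta1**state.t)
        v_hat = state.v / (1.0 - cfg.beta2**state.t)
    state.theta = state.theta - cfg.lr * m_hat / (np.sqrt(v_hat) + cfg.stabilizer)
    return state


class Adam:
    """Adam over a list of :class:`Parameter`, updating in place."""

    def __init__(self, params: list[Parameter], config: AdamConfig = AdamConfig()):
        self.params = list(params)
        self.config = config
        self.states = [AdamState(p.data, config=config) for p in self.params]

    def step(self) -> None:
        for p, s in zip(self.params, self.states):
            if p.grad is None:
                continue
            s.theta = p.data
            adam_step(s, p.grad)
            p.data = s.theta

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    loss: str = "composite"
    optimizer: AdamConfig = field(default_factory=AdamConfig)

    def __post_init__(self):
        if self.epochs < 0:
            raise ConfigError(f"epochs must be >= 0, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.loss not in _LOSS_FNS:
            raise ConfigError(
                f"loss must be one of {sorted(_LOSS_FNS)}, got {self.loss!r}"
            )


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    val_dice: float


@dataclass
class FitResult:
    history: list[EpochRecord]
    best_state: dict
    best_epoch: int
    best_val_dice: float


def _stack(pairs: list[SegmentationPair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([p.image for p in pairs])[:, None, :, :]
    masks = np.stack([p.mask for p in pairs]).astype(np.float64)[:, None, :, :]
    return images, masks


def validation_dice(model, pairs: list[SegmentationPair],
                    threshold: float = 0.5, batch_size: int = 8) -> float:
    """Mean per-image Dice of thresholded predictions against ground truth."""
    from .network import predict_probs

    images = np.stack([p.image for p in pairs])
    probs = predict_probs(model, images, batch_size=batch_size)
    scores = []
    for prob, pair in zip(probs, pairs):
        pred = prob >= threshold
        scores.append(dice_score(pred, pair.mask.astype(bool)))
    return float(np.mean(scores))


def fit(model, train: list[SegmentationPair], val: list[SegmentationPair],
        loss_cfg: LossConfig = LossConfig(),
        train_cfg: TrainConfig = TrainConfig(),
        seed: int = 0) -> FitResult:
    """Mini-batch training with per-epoch validation Dice tracking.

    Deterministic given (model weights, data, seed): batch order is drawn
    from a dedicated generator seeded by ``seed``.  Returns the loss/Dice
    history and the state dict of the best-validation-Dice epoch.
    """
    if not train or not val:
        raise ValueError("train and val datasets must be nonempty")
    loss_fn = _LOSS_FNS[train_cfg.loss]
    optimizer = Adam(model.parameters(), train_cfg.optimizer)
    rng = np.random.default_rng(seed)

    history: list[EpochRecord] = []
    best_state = copy.deepcopy(model.state_dict())
    best_epoch = -1
    best_val = -1.0

    n = len(train)
    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            batch = [train[i] for i in order[start:start + train_cfg.batch_size]]
            images, masks = _stack(batch)
            optimizer.zero_grad()
            out = model(Tensor(images))
            loss = loss_fn(out, masks, loss_cfg)
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        val_dice = validation_dice(model, val, batch_size=train_cfg.batch_size)
        history.append(EpochRecord(epoch, float(np.mean(epoch_losses)), val_dice))
        if val_dice > best_val:
            best_val = val_dice
            best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
    return FitResult(history, best_state, best_epoch, best_val)
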