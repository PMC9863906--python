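"""Composite adversarial + overlap objectives.

Generator loss::

    GL = L1(D(x, ŷ), 1) + α · GDL(y, ŷ)

Discriminator loss::

    DL = L1(D(x, y), 1) + L1(D(x, ŷ), 0)

where L1 against a constant is the *mean* absolute deviation of the
critic's realness field from that constant (mean, not sum, so losses are
invariant to patch size), and GDL is the generalized dice loss with
inverse-square-volume class weights — the weighting that counteracts the
extreme background/tumour class imbalance of brain MRI.

Each loss function also returns the analytic gradient its caller needs,
so the training loop composes them with network backprop directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WEIGHTING_CHOICES = ("inverse-square-volume", "uniform")


@dataclass
class LossConfig:
    """Weights and numerical guards for the composite losses.

    alpha
        Non-negative weight on the dice term of the generator loss.
    dice_class_weighting
        ``"inverse-square-volume"`` (w_c = 1/(V_c + ε)²) or ``"uniform"``.
    epsilon
        Smoothing constant protecting empty-class denominators.
    """

    alpha: float = 5.0
    dice_class_weighting: str = "inverse-square-volume"
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dice_class_weighting not in WEIGHTING_CHOICES:
            raise ValueError(
                f"dice_class_weighting must be one of {WEIGHTING_CHOICES}")


def l1_to_constant(d_output: np.ndarray, target_constant: float,
                   with_grad: bool = False):
    """Mean absolute deviation of a realness field from a constant target."""
    diff = d_output - target_constant
    value = float(np.abs(diff).mean())
    if not with_grad:
        return value
    grad = np.sign(diff) / d_output.size
    return value, grad


def _class_axes(y: np.ndarray) -> tuple[int, ...]:
    # channels-first (N, C, ...) or channels-last cube (..., C): the loss is
    # computed on channels-first batches internally.
    return tuple(i for i in range(y.ndim) if i != 1)


def generalized_dice_loss(y_true_onehot: np.ndarray, y_pred_soft: np.ndarray,
                          config: LossConfig | None = None,
                          with_grad: bool = False):
    """Generalized dice loss between one-hot truth and soft predictions.

    GDL = 1 − 2 (Σ_c w_c Σ_v y ŷ) / (Σ_c w_c Σ_v (y + ŷ)), with
    w_c = 1/(Σ_v y + ε)² under inverse-square-volume weighting.
    Inputs are channels-first ``(N, C, D, H, W)`` (or any layout with the
    class axis second).
    """
    config = config or LossConfig()
    if y_true_onehot.shape != y_pred_soft.shape:
        raise ValueError(
            f"shape mismatch: {y_true_onehot.shape} vs {y_pred_soft.shape}")
    axes = _class_axes(y_true_onehot)
    vol = y_true_onehot.sum(axis=axes, dtype=np.float64)
    if config.dice_class_weighting == "inverse-square-volume":
        w = 1.0 / (vol + config.epsilon) ** 2
        # a class absent from the batch would otherwise get weight 1/eps^2
        # and drown every present class; the standard guard drops it
        w[vol == 0] = 0.0
    else:
        w = np.ones_like(vol)
    inter = (y_true_onehot.astype(np.float64) * y_pred_soft).sum(axis=axes)
    total = (y_true_onehot.astype(np.float64) + y_pred_soft).sum(axis=axes)
    num = float((w * inter).sum())
    den = float((w * total).sum())
    if den == 0.0:  # both inputs empty on every class
        value = 0.0
        if not with_grad:
            return value
        return value, np.zeros_like(y_pred_soft)
    value = 1.0 - 2.0 * num / den
    if not with_grad:
        return value
    # d/dŷ_cv = −2 (w_c y_cv · den − w_c · num) / den²
    d = den
    shape = [1] * y_pred_soft.ndim
    shape[1] = len(w)
    w_b = w.reshape(shape)
    grad = -2.0 * (w_b * y_true_onehot * d - w_b * num) / d**2
    return value, grad.astype(y_pred_soft.dtype)


def generator_loss(d_on_fake: np.ndarray, y_true_onehot: np.ndarray,
                   y_pred_soft: np.ndarray, config: LossConfig | None = None,
                   ) -> tuple[float, dict]:
    """GL and its components (``adv``, ``dice``)."""
    config = config or LossConfig()
    adv = l1_to_constant(d_on_fake, 1.0)
    dice = generalized_dice_loss(y_true_onehot, y_pred_soft, config)
    return adv + config.alpha * dice, {"adv": adv, "dice": dice}


def discriminator_loss(d_on_real: np.ndarray, d_on_fake: np.ndarray,
                       ) -> tuple[float, dict]:
    """DL and its components (``real``, ``fake``)."""
    if d_on_real.shape != d_on_fake.shape:
        raise ValueError(
            f"shape mismatch: {d_on_real.shape} vs {d_on_fake.shape}")
    real = l1_to_constant(d_on_real, 1.0)
    fake = l1_to_constant(d_on_fake, 0.0)
    return real + fake, {"real": real, "fake": fake}
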