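"""Collaborative training objective: hard-label CE + soft-label KL.

Total loss = alpha * L_CE(hard, q) + beta * L_KL(soft || q), averaged over
pixels and reported in nats.  Both terms use the binary two-outcome
expansion (lesion + background channels) so that background pixels also
constrain the prediction; predictions and soft labels are clamped to
[eps, 1-eps] before any logarithm because kept-hard soft-label pixels are
exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, InvalidParameterError

__all__ = ["EPS", "LossWeights", "cross_entropy_loss", "kl_loss", "total_loss"]

EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights of the two loss terms: ``alpha`` for hard-label CE,
    ``beta`` for soft-label KL. ``beta = 0`` is the plain-CE baseline."""

    alpha: float = 1.0
    beta: float = 0.25

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError("loss weights must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise InvalidParameterError("alpha and beta cannot both be zero")


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(x, dtype=float), EPS, 1.0 - EPS)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if np.shape(a) != np.shape(b):
        raise DimensionError(f"shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def cross_entropy_loss(pred: np.ndarray, hard: np.ndarray) -> float:
    """Mean binary cross-entropy (nats) between predictions and hard labels.

    ``-(1/N) * sum[ y*log q + (1-y)*log(1-q) ]`` with q clamped to
    [eps, 1-eps].  Non-negative; ~0 for a confident correct prediction.
    """
    _check_shapes(pred, hard)
    q = _clamp(pred)
    y = np.asarray(hard, dtype=float)
    return float(-np.mean(y * np.log(q) + (1.0 - y) * np.log1p(-q)))


def kl_loss(soft: np.ndarray, pred: np.ndarray) -> float:
    """Mean KL divergence (nats) of the prediction from the soft label.

    ``KL(p_soft || q)`` summed over the two outcomes per pixel, averaged
    over pixels; zero iff the clamped distributions coincide.
    """
    _check_shapes(soft, pred)
    p = _clamp(soft)
    q = _clamp(pred)
    kl = p * (np.log(p) - np.log(q)) + (1.0 - p) * (np.log1p(-p) - np.log1p(-q))
    return float(np.mean(kl))


def total_loss(pred: np.ndarray, hard: np.ndarray,
               soft: np.ndarray | None, w: LossWeights) -> float:
    """Weighted collaborative loss ``alpha*CE + beta*KL``.

    ``soft`` may be omitted when ``beta == 0`` (the baseline arm).
    """
    loss = w.alpha * cross_entropy_loss(pred, hard) if w.alpha else 0.0
    if w.beta:
        if soft is None:
            raise InvalidParameterError("beta > 0 requires a soft label")
        loss += w.beta * kl_loss(soft, pred)
    return float(loss)
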