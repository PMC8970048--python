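"""Training objectives for the unpaired translation framework.

Two adversarial formulations are provided. The logistic (cross-entropy) form
treats critic outputs as logits of "real"; the generator uses the
non-saturating variant. The Wasserstein form treats critic outputs as raw
scores and uses the real/fake score difference, with critic weights clipped
to [-c, c] after each update to maintain a Lipschitz constraint. Cycle
consistency is the mean absolute error of both reconstruction directions.

The full generator objective is adv_ds + adv_sd + lambda * cycle.
"""

from __future__ import annotations

import numpy as np

from .nn import Layer

__all__ = [
    "logistic_adversarial_loss",
    "wasserstein_losses",
    "cycle_loss",
    "clip_critic_weights",
]


def _check_batches(real, fake):
    real = np.asarray(real, dtype=np.float64).ravel()
    fake = np.asarray(fake, dtype=np.float64).ravel()
    if real.size == 0 or fake.size == 0:
        raise ValueError("empty score batch")
    return real, fake


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def logistic_adversarial_loss(critic_scores_real, critic_scores_fake):
    """Cross-entropy GAN losses on sigmoid logits.

    Returns ``(d_loss, g_loss)`` with
    ``d_loss = -mean log sigma(real) - mean log(1 - sigma(fake))`` and the
    non-saturating generator loss ``g_loss = -mean log sigma(fake)``.
    """
    real, fake = _check_batches(critic_scores_real, critic_scores_fake)
    d_loss = _softplus(-real).mean() + _softplus(fake).mean()
    g_loss = _softplus(-fake).mean()
    return float(d_loss), float(g_loss)


def wasserstein_losses(critic_scores_real, critic_scores_fake):
    """Earth-Mover surrogate losses on raw critic scores.

    ``critic_loss = mean(fake) - mean(real)`` (the critic maximizes the score
    gap), ``gen_loss = -mean(fake)``. Both are invariant to a constant shift
    of all scores in the critic loss.
    """
    real, fake = _check_batches(critic_scores_real, critic_scores_fake)
    return float(fake.mean() - real.mean()), float(-fake.mean())


def cycle_loss(d_batch, d_reconstructed, s_batch, s_reconstructed) -> float:
    """Mean absolute reconstruction error summed over both cycle directions."""
    d, dr = np.asarray(d_batch, float), np.asarray(d_reconstructed, float)
    s, sr = np.asarray(s_batch, float), np.asarray(s_reconstructed, float)
    if d.shape != dr.shape or s.shape != sr.shape:
        raise ValueError(
            f"cycle shapes mismatch: {d.shape} vs {dr.shape}, {s.shape} vs {sr.shape}"
        )
    return float(np.abs(dr - d).mean() + np.abs(sr - s).mean())


def clip_critic_weights(critic: Layer, c: float) -> Layer:
    """Clamp every critic parameter into [-c, c] in place."""
    if not c > 0:
        raise ValueError("clip value must be positive")
    for _, sub in critic.named_layers():
        for p in sub.params.values():
            np.clip(p, -c, c, out=p)
    return critic
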