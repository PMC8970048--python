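"""Unpaired adversarial training loop.

Each step runs ``n_critic`` critic updates (with weight clipping in
Wasserstein mode) followed by one joint update of both generators on
``adv_ds + adv_sd + lambda_cyc * cycle``. Optimization is RMSProp at a low
learning rate (default 5e-4) for every network. Density-map inputs can be
corrupted with zero-mean Gaussian noise (``input_noise_std`` as a fraction of
the dynamic range), which regularizes training.

The loop is fully seeded: a single config seed drives dataset shuffling,
noise channels and input corruption through one sequential RNG, so reruns
are bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import (
    clip_critic_weights,
    cycle_loss,
    logistic_adversarial_loss,
    wasserstein_losses,
)
from .models import TranslationModel, save_checkpoint
from .nn import RMSProp
from .volume import DomainDataset

__all__ = ["TrainingConfig", "LossReport", "TrainingDiverged", "train"]


@dataclass
class TrainingConfig:
    """Hyperparameters of the adversarial training loop.

    ``lambda_cyc`` weights cycle consistency (default 10, the standard
    choice); ``lr`` is the RMSProp rate (default 5e-4); ``clip_value`` bounds
    critic weights in Wasserstein mode (default 0.01); ``adv_mode`` switches
    between ``"wasserstein"`` and ``"logistic"`` adversarial objectives.
    """

    lambda_cyc: float = 10.0
    lr: float = 5e-4
    clip_value: float = 0.01
    n_critic: int = 5
    batch_size: int = 8
    epochs: int = 100
    adv_mode: str = "wasserstein"
    input_noise_std: float = 0.0
    seed: int = 0
    max_steps: int | None = None
    checkpoint_every: int | None = None

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.clip_value <= 0 or self.lambda_cyc < 0:
            raise ValueError("require lr > 0, clip_value > 0, lambda_cyc >= 0")
        if self.n_critic < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("n_critic, batch_size and epochs must be >= 1")
        if self.adv_mode not in ("wasserstein", "logistic"):
            raise ValueError(f"adv_mode must be wasserstein or logistic, got {self.adv_mode!r}")


@dataclass
class LossReport:
    """Losses at one training step (one generator update)."""

    step: int
    adv_ds: float
    adv_sd: float
    cycle: float
    critic_a: float
    critic_b: float
    total: float


class TrainingDiverged(RuntimeError):
    pass


def _check_finite(step: int, **losses: float) -> None:
    for name, value in losses.items():
        if not np.isfinite(value):
            raise TrainingDiverged(
                f"non-finite loss at step {step}: {name} = {value}"
            )


class _BatchSampler:
    """Cycles through a shuffled pool, reshuffling at each exhaustion."""

    def __init__(self, data: np.ndarray, batch_size: int, rng: np.random.Generator):
        self.data = data
        self.batch_size = batch_size
        self.rng = rng
        self._order = rng.permutation(len(data))
        self._pos = 0

    def next(self) -> np.ndarray:
        if self._pos + self.batch_size > len(self.data):
            self._order = self.rng.permutation(len(self.data))
            self._pos = 0
        idx = self._order[self._pos : self._pos + self.batch_size]
        self._pos += self.batch_size
        return self.data[idx]


def _corrupt(batch: np.ndarray, std: float, rng: np.random.Generator) -> np.ndarray:
    if std <= 0:
        return batch
    dyn = float(batch.max() - batch.min())
    return (batch + rng.normal(0.0, std * dyn, batch.shape)).astype(np.float32)


def _adv_score_grads(real, fake, mode):
    """d(critic loss)/d(scores) for the critic update."""
    if mode == "wasserstein":
        d_loss, _ = wasserstein_losses(real, fake)
        g_real = np.full_like(real, -1.0 / real.size)
        g_fake = np.full_like(fake, 1.0 / fake.size)
    else:
        d_loss, _ = logistic_adversarial_loss(real, fake)
        sig_r = 1.0 / (1.0 + np.exp(-real))
        sig_f = 1.0 / (1.0 + np.exp(-fake))
        g_real = (-(1.0 - sig_r) / real.size).astype(np.float32)
        g_fake = (sig_f / fake.size).astype(np.float32)
    return d_loss, g_real.astype(np.float32), g_fake.astype(np.float32)


def _gen_score_grad(fake, mode):
    """Generator adversarial loss and d(loss)/d(fake scores)."""
    if mode == "wasserstein":
        _, g_loss = wasserstein_losses(np.zeros(1), fake)
        grad = np.full_like(fake, -1.0 / fake.size)
    else:
        _, g_loss = logistic_adversarial_loss(np.zeros(1), fake)
        sig_f = 1.0 / (1.0 + np.exp(-fake))
        grad = (-(1.0 - sig_f) / fake.size).astype(np.float32)
    return g_loss, grad.astype(np.float32)


def _critic_update(critic, opt, real_batch, fake_batch, mode, clip_value):
    n_real = len(real_batch)
    scores, cache = critic.forward(np.concatenate([real_batch, fake_batch]))
    d_loss, g_real, g_fake = _adv_score_grads(scores[:n_real], scores[n_real:], mode)
    critic.zero_grad()
    critic.backward(np.concatenate([g_real, g_fake]), cache)
    opt.step()
    if mode == "wasserstein":
        clip_critic_weights(critic, clip_value)
    return d_loss


def train(
    model: TranslationModel,
    dataset_d: DomainDataset,
    dataset_s: DomainDataset,
    config: TrainingConfig,
    out_dir: str | Path | None = None,
) -> tuple[TranslationModel, list[LossReport]]:
    """Train the translation model on two unpaired domains.

    Returns the model and a per-step loss history. When ``out_dir`` is given,
    ``history.csv``, a final ``model.npz`` checkpoint and the resolved config
    are written there. A non-finite loss aborts with a diagnostic naming the
    step and term.
    """
    if dataset_d.side != dataset_s.side:
        raise ValueError("both domains must share one side length")
    if dataset_d.side != model.n:
        raise ValueError(f"datasets (side {dataset_d.side}) do not match model n={model.n}")

    rng = np.random.default_rng(config.seed)
    xs_d = dataset_d.stack()[:, None]
    xs_s = dataset_s.stack()[:, None]
    sampler_d = _BatchSampler(xs_d, config.batch_size, rng)
    sampler_s = _BatchSampler(xs_s, config.batch_size, rng)

    opt_g = RMSProp_pair(model, config.lr)
    opt_da = RMSProp(model.d_a, lr=config.lr)
    opt_db = RMSProp(model.d_b, lr=config.lr)

    steps_per_epoch = max(1, min(len(xs_d), len(xs_s)) // config.batch_size)
    history: list[LossReport] = []
    step = 0
    lam = config.lambda_cyc
    done = False

    for epoch in range(config.epochs):
        if done:
            break
        for _ in range(steps_per_epoch):
            step += 1
            # ---- critic phase ----
            critic_a_loss = critic_b_loss = float("nan")
            for _ in range(config.n_critic):
                d_batch = _corrupt(sampler_d.next(), config.input_noise_std, rng)
                s_batch = sampler_s.next()
                fake_s, _ = model.g_ds.forward(
                    d_batch, noise=model.g_ds.sample_noise(len(d_batch), rng)
                )
                fake_d, _ = model.g_sd.forward(
                    s_batch, noise=model.g_sd.sample_noise(len(s_batch), rng)
                )
                critic_a_loss = _critic_update(
                    model.d_a, opt_da, s_batch, fake_s, config.adv_mode, config.clip_value
                )
                critic_b_loss = _critic_update(
                    model.d_b, opt_db, d_batch, fake_d, config.adv_mode, config.clip_value
                )
            # ---- generator phase ----
            d_batch = _corrupt(sampler_d.next(), config.input_noise_std, rng)
            s_batch = sampler_s.next()
            z = [model.g_ds.sample_noise(len(d_batch), rng) for _ in range(2)]
            z += [model.g_sd.sample_noise(len(s_batch), rng) for _ in range(2)]

            fake_s, c_ds = model.g_ds.forward(d_batch, noise=z[0])
            rec_d, c_sd_rec = model.g_sd.forward(fake_s, noise=z[2])
            fake_d, c_sd = model.g_sd.forward(s_batch, noise=z[3])
            rec_s, c_ds_rec = model.g_ds.forward(fake_d, noise=z[1])

            score_fake_s, cca = model.d_a.forward(fake_s)
            score_fake_d, ccb = model.d_b.forward(fake_d)
            adv_ds, g_score_s = _gen_score_grad(score_fake_s, config.adv_mode)
            adv_sd, g_score_d = _gen_score_grad(score_fake_d, config.adv_mode)
            cyc = cycle_loss(d_batch, rec_d, s_batch, rec_s)
            total = adv_ds + adv_sd + lam * cyc
            _check_finite(step, adv_ds=adv_ds, adv_sd=adv_sd, cycle=cyc,
                          critic_a=critic_a_loss, critic_b=critic_b_loss)

            model.g_ds.zero_grad()
            model.g_sd.zero_grad()
            # cycle gradients (L1 -> sign / numel), scaled by lambda
            g_rec_d = (lam * np.sign(rec_d - d_batch) / rec_d.size).astype(np.float32)
            g_rec_s = (lam * np.sign(rec_s - s_batch) / rec_s.size).astype(np.float32)
            g_fake_s = model.g_sd.backward(g_rec_d, c_sd_rec)
            g_fake_s = g_fake_s + model.d_a.backward(g_score_s, cca)
            model.g_ds.backward(g_fake_s, c_ds)
            g_fake_d = model.g_ds.backward(g_rec_s, c_ds_rec)
            g_fake_d = g_fake_d + model.d_b.backward(g_score_d, ccb)
            model.g_sd.backward(g_fake_d, c_sd)
            opt_g.step()
            # critics accumulated pass-through gradients; clear them
            model.d_a.zero_grad()
            model.d_b.zero_grad()

            history.append(LossReport(step, adv_ds, adv_sd, cyc,
                                      critic_a_loss, critic_b_loss, total))
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        if (out_dir is not None and config.checkpoint_every
                and (epoch + 1) % config.checkpoint_every == 0):
            save_checkpoint(model, Path(out_dir) / f"model_epoch{epoch + 1:04d}.npz")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame = history_frame(history)
        frame.to_csv(out_dir / "history.csv", index=False)
        save_checkpoint(model, out_dir / "model.npz", extra={"config": asdict(config)})
        _write_log(out_dir / "train.log", config, frame, steps_per_epoch)
    return model, history


def _write_log(path: Path, config: TrainingConfig, frame: pd.DataFrame,
               steps_per_epoch: int) -> None:
    from . import __version__

    lines = [
        f"tomocycle {__version__}",
        f"seed {config.seed}",
        f"config {asdict(config)}",
        "",
    ]
    epochs = (frame["step"] - 1) // steps_per_epoch
    for epoch, chunk in frame.groupby(epochs):
        means = chunk[["adv_ds", "adv_sd", "cycle", "critic_a", "critic_b"]].mean()
        lines.append(
            f"epoch {epoch + 1}: steps {chunk['step'].iloc[0]}-{chunk['step'].iloc[-1]}"
            + "".join(f"  {k}={v:.4f}" for k, v in means.items())
        )
    path.write_text("\n".join(lines) + "\n")


def history_frame(history: list[LossReport]) -> pd.DataFrame:
    return pd.DataFrame([asdict(h) for h in history])


class RMSProp_pair:
    """One RMSProp step over both generators."""

    def __init__(self, model: TranslationModel, lr: float):
        self._opts = [RMSProp(model.g_ds, lr=lr), RMSProp(model.g_sd, lr=lr)]

    def step(self) -> None:
        for opt in self._opts:
            opt.step()
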