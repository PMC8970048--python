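"""Generators and critics for unpaired density-map <-> subtomogram translation.

The generator follows the classic image-translation encoder/decoder recipe,
written c7s1-32, d64, d128, six R128 blocks, u64, u32, c7s1-1: a 7x7x7 stem,
two stride-2 downsampling convs, a residual stack at 1/4 resolution, a
one-channel Gaussian noise map concatenated onto the 128-channel bottleneck
(129 channels into the first upsampling layer, to diversify outputs and
resist mode collapse), two fractional-stride upsampling convs, and a 7x7x7
head ending in tanh with no normalization, so outputs live strictly in
(-1, 1).

The critic is three spectrally-normalized 4x4x4 stride-1 convs (64, 128, 256
filters, instance norm + LeakyReLU 0.2) plus a 1-filter projection conv whose
spatial mean is the scalar Wasserstein score.

Two generator/critic pairs make a :class:`TranslationModel`: ``G_ds`` maps
density maps to subtomograms with critic ``D_A`` judging the subtomogram
domain, and ``G_sd`` maps back with critic ``D_B`` judging density maps.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Conv3d,
    ConvTranspose3d,
    InstanceNorm3d,
    Layer,
    LeakyReLU,
    ReLU,
    ResidualBlock,
    Sequential,
    SNConv3d,
    Tanh,
)
from .volume import Volume

__all__ = [
    "GeneratorPlan",
    "CriticPlan",
    "Generator",
    "Critic",
    "TranslationModel",
    "build_model",
    "generate",
    "corrupt_input",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GeneratorPlan:
    """Layer plan for one generator. Defaults are the full translation network;
    ``base_width``/``n_res_blocks`` can be reduced for quick CPU experiments."""

    n: int = 28
    base_width: int = 32
    n_res_blocks: int = 6
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n % 4 != 0:
            raise ValueError(
                f"side length n={self.n} must be divisible by 4 (two stride-2 stages)"
            )
        if self.base_width < 1 or self.n_res_blocks < 1:
            raise ValueError("base_width and n_res_blocks must be positive")

    @property
    def bottleneck_side(self) -> int:
        return self.n // 4

    @property
    def bottleneck_channels(self) -> int:
        return self.base_width * 4


@dataclass
class CriticPlan:
    """Layer plan for one critic; widths default to 64/128/256."""

    n: int = 28
    base_width: int = 64
    spectral_norm: bool = True


class Generator(Layer):
    """Encoder / residual stack / noise concat / decoder."""

    def __init__(self, plan: GeneratorPlan, rng: np.random.Generator):
        super().__init__()
        w = plan.base_width
        self.plan = plan
        self.encoder = Sequential(
            Conv3d(1, w, 7, pad=3, pad_mode="reflect", rng=rng),
            InstanceNorm3d(), ReLU(),
            Conv3d(w, 2 * w, 3, stride=2, pad=1, rng=rng),
            InstanceNorm3d(), ReLU(),
            Conv3d(2 * w, 4 * w, 3, stride=2, pad=1, rng=rng),
            InstanceNorm3d(), ReLU(),
            *[ResidualBlock(4 * w, rng=rng, dropout_rate=plan.dropout_rate)
              for _ in range(plan.n_res_blocks)],
        )
        # first upsampling layer consumes bottleneck + 1 noise channel
        self.decoder = Sequential(
            ConvTranspose3d(4 * w + 1, 2 * w, 3, stride=2, pad=1, output_pad=1, rng=rng),
            InstanceNorm3d(), ReLU(),
            ConvTranspose3d(2 * w, w, 3, stride=2, pad=1, output_pad=1, rng=rng),
            InstanceNorm3d(), ReLU(),
            Conv3d(w, 1, 7, pad=3, pad_mode="reflect", rng=rng),
            Tanh(),
        )

    @property
    def noise_shape(self) -> tuple[int, int, int]:
        s = self.plan.bottleneck_side
        return (s, s, s)

    def sample_noise(self, batch: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((batch, 1, *self.noise_shape)).astype(np.float32)

    def forward(self, x, noise=None, rng=None, train=False):
        if x.shape[2] != self.plan.n:
            raise ValueError(f"expected side {self.plan.n}, got {x.shape[2]}")
        h, c_enc = self.encoder.forward(x, rng=rng, train=train)
        if noise is None:
            noise = np.zeros((x.shape[0], 1, *self.noise_shape), dtype=np.float32)
        if noise.shape != (x.shape[0], 1, *self.noise_shape):
            raise ValueError(
                f"noise must have shape {(x.shape[0], 1, *self.noise_shape)}, got {noise.shape}"
            )
        hcat = np.concatenate([h, noise], axis=1)
        y, c_dec = self.decoder.forward(hcat, rng=rng, train=train)
        return y, (c_enc, c_dec, h.shape[1])

    def backward(self, g, cache):
        c_enc, c_dec, n_feat = cache
        gcat = self.decoder.backward(g, c_dec)
        return self.encoder.backward(gcat[:, :n_feat], c_enc)

    def zero_grad(self):
        self.encoder.zero_grad()
        self.decoder.zero_grad()

    def named_layers(self):
        for name, sub in self.encoder.named_layers():
            yield f"enc.{name}", sub
        for name, sub in self.decoder.named_layers():
            yield f"dec.{name}", sub

    def set_dropout_rate(self, rate: float) -> None:
        for _, sub in self.named_layers():
            if hasattr(sub, "rate"):
                sub.rate = rate


class Critic(Layer):
    """Scalar Wasserstein score per volume."""

    def __init__(self, plan: CriticPlan, rng: np.random.Generator):
        super().__init__()
        conv = SNConv3d if plan.spectral_norm else Conv3d
        w = plan.base_width
        self.plan = plan
        self.trunk = Sequential(
            conv(1, w, 4, stride=1, pad=1, rng=rng),
            InstanceNorm3d(), LeakyReLU(0.2),
            conv(w, 2 * w, 4, stride=1, pad=1, rng=rng),
            InstanceNorm3d(), LeakyReLU(0.2),
            conv(2 * w, 4 * w, 4, stride=1, pad=1, rng=rng),
            InstanceNorm3d(), LeakyReLU(0.2),
            conv(4 * w, 1, 4, stride=1, pad=1, rng=rng),
        )

    def forward(self, x, rng=None, train=False):
        y, c = self.trunk.forward(x, rng=rng, train=train)
        score = y.mean(axis=(1, 2, 3, 4))
        return score.astype(np.float32), (c, y.shape)

    def backward(self, g, cache):
        c, y_shape = cache
        per_voxel = np.prod(y_shape[1:])
        gmap = np.broadcast_to(
            g[:, None, None, None, None].astype(np.float32) / per_voxel, y_shape
        ).copy()
        return self.trunk.backward(gmap, c)

    def zero_grad(self):
        self.trunk.zero_grad()

    def named_layers(self):
        yield from self.trunk.named_layers()


@dataclass
class TranslationModel:
    """The four networks of the unpaired translation framework.

    ``g_ds``/``g_sd`` share a plan but never parameters; ``d_a`` scores the
    subtomogram domain, ``d_b`` the density-map domain.
    """

    g_ds: Generator
    g_sd: Generator
    d_a: Critic
    d_b: Critic
    plan: GeneratorPlan
    critic_plan: CriticPlan

    @property
    def n(self) -> int:
        return self.plan.n

    def parameter_counts(self) -> dict[str, int]:
        def count(layer: Layer) -> int:
            return sum(p.size for _, sub in layer.named_layers() for p in sub.params.values())

        return {
            "g_ds": count(self.g_ds), "g_sd": count(self.g_sd),
            "d_a": count(self.d_a), "d_b": count(self.d_b),
        }

    def networks(self):
        return {"g_ds": self.g_ds, "g_sd": self.g_sd, "d_a": self.d_a, "d_b": self.d_b}


def build_model(
    n: int,
    seed: int = 0,
    dropout_rate: float = 0.0,
    base_width: int = 32,
    n_res_blocks: int = 6,
    critic_width: int = 64,
    spectral_norm: bool = True,
) -> TranslationModel:
    """Deterministically initialize the two generators and two critics.

    ``n`` must be divisible by 4. Each network draws from its own seed stream
    derived from ``seed``, so models are reproducible bit-for-bit.
    """
    plan = GeneratorPlan(n=n, base_width=base_width, n_res_blocks=n_res_blocks,
                         dropout_rate=dropout_rate)
    critic_plan = CriticPlan(n=n, base_width=critic_width, spectral_norm=spectral_norm)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]
    return TranslationModel(
        g_ds=Generator(plan, streams[0]),
        g_sd=Generator(plan, streams[1]),
        d_a=Critic(critic_plan, streams[2]),
        d_b=Critic(critic_plan, streams[3]),
        plan=plan,
        critic_plan=critic_plan,
    )


def generate(
    model: TranslationModel,
    direction: str,
    volume: Volume,
    noise_seed: int | None = 0,
    dropout_on: bool = False,
    dropout_seed: int | None = None,
) -> Volume:
    """Translate one volume across domains.

    ``direction`` is ``"ds"`` (density map -> subtomogram) or ``"sd"``. The
    injected noise channel is drawn from ``noise_seed``; with dropout off and
    a fixed seed the call is deterministic.
    """
    if direction not in ("ds", "sd"):
        raise ValueError("direction must be 'ds' or 'sd'")
    gen = model.g_ds if direction == "ds" else model.g_sd
    if volume.side != model.n:
        raise ValueError(f"volume side {volume.side} does not match model n={model.n}")
    x = volume.data[None, None].astype(np.float32)
    noise = gen.sample_noise(1, np.random.default_rng(noise_seed))
    rng = np.random.default_rng(dropout_seed) if dropout_on else None
    y, _ = gen.forward(x, noise=noise, rng=rng, train=dropout_on)
    return Volume(y[0, 0], volume.voxel_spacing, provenance=f"generated:{direction}")


def corrupt_input(volume: Volume, noise_std: float, seed: int | None = None) -> Volume:
    """Add zero-mean Gaussian noise scaled by the volume's dynamic range.

    Training-time corruption of density maps (std expressed as a fraction of
    the dynamic range) regularizes the translator; std 0 is the identity.
    """
    if noise_std < 0:
        raise ValueError("noise_std must be nonnegative")
    if noise_std == 0:
        return volume.copy()
    dyn = float(volume.data.max() - volume.data.min())
    rng = np.random.default_rng(seed)
    out = volume.data + rng.normal(0.0, noise_std * dyn, volume.data.shape)
    return Volume(out.astype(np.float32), volume.voxel_spacing, volume.provenance)


def save_checkpoint(model: TranslationModel, path: str | Path,
                    extra: dict | None = None) -> Path:
    """Single-file archive: parameters, plan metadata, optional extras."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for net_name, net in model.networks().items():
        for lname, sub in net.named_layers():
            for k, v in sub.params.items():
                arrays[f"{net_name}/{lname}/{k}"] = v
    meta = {
        "plan": asdict(model.plan),
        "critic_plan": asdict(model.critic_plan),
        "extra": extra or {},
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> TranslationModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        plan = GeneratorPlan(**meta["plan"])
        cplan = CriticPlan(**meta["critic_plan"])
        model = build_model(
            n=plan.n, dropout_rate=plan.dropout_rate, base_width=plan.base_width,
            n_res_blocks=plan.n_res_blocks, critic_width=cplan.base_width,
            spectral_norm=cplan.spectral_norm,
        )
        for net_name, net in model.networks().items():
            subs = dict(net.named_layers())
            for key in data.files:
                if key == "__meta__" or not key.startswith(net_name + "/"):
                    continue
                _, lname, pname = key.split("/")
                subs[lname].params[pname][...] = data[key]
    return model
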