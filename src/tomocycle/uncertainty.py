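"""Monte-Carlo-dropout uncertainty maps for the generator.

With dropout active at inference, repeated stochastic forward passes on the
same density map sample an implicit ensemble of subnetworks; the per-voxel
standard deviation across the draws (default 20) is an uncertainty map over
the generated subtomogram. The injected noise channel can either be held
fixed across draws, isolating dropout-induced variance (the default), or
resampled, measuring total generative variance.

Standard deviations use the population convention (divide by T); switching
to the sample convention scales every value by sqrt(T / (T - 1)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .models import TranslationModel
from .volume import Volume

__all__ = ["UncertaintyMap", "mc_uncertainty_map", "compare_dropout_settings"]


@dataclass
class UncertaintyMap:
    """Per-voxel standard deviation over repeated stochastic generations."""

    std_map: np.ndarray
    n_samples: int
    source: str = ""

    def __post_init__(self) -> None:
        self.std_map = np.asarray(self.std_map, dtype=np.float32)
        if np.any(self.std_map < 0):
            raise ValueError("standard deviations must be nonnegative")

    @property
    def mean_std(self) -> float:
        return float(self.std_map.mean())

    @property
    def max_std(self) -> float:
        return float(self.std_map.max())


def mc_uncertainty_map(
    model: TranslationModel,
    density: Volume,
    n_samples: int = 20,
    dropout_rate: float = 0.5,
    noise_mode: str = "fixed",
    seed: int = 0,
    direction: str = "ds",
) -> UncertaintyMap:
    """Per-voxel std over ``n_samples`` dropout-perturbed generations.

    ``noise_mode="fixed"`` draws the injected noise channel once and reuses
    it (variance isolates dropout); ``"resample"`` redraws it each pass.
    Deterministic for a fixed seed.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    if noise_mode not in ("fixed", "resample"):
        raise ValueError("noise_mode must be 'fixed' or 'resample'")
    gen = model.g_ds if direction == "ds" else model.g_sd
    old_rate = [l.rate for _, l in gen.named_layers() if hasattr(l, "rate")]
    gen.set_dropout_rate(dropout_rate)
    try:
        seq = np.random.SeedSequence(seed)
        noise_seed, drop_seed = seq.spawn(2)
        noise_rng = np.random.default_rng(noise_seed.generate_state(1)[0])
        drop_rng = np.random.default_rng(drop_seed.generate_state(1)[0])
        x = density.data[None, None].astype(np.float32)
        fixed_noise = gen.sample_noise(1, noise_rng)
        draws = np.empty((n_samples, *density.data.shape), dtype=np.float32)
        for t in range(n_samples):
            noise = fixed_noise if noise_mode == "fixed" else gen.sample_noise(1, noise_rng)
            y, _ = gen.forward(x, noise=noise, rng=drop_rng,
                               train=dropout_rate > 0)
            draws[t] = y[0, 0]
    finally:
        for (_, l), r in zip(
            ((n, l) for n, l in gen.named_layers() if hasattr(l, "rate")), old_rate
        ):
            l.rate = r
    std = draws.astype(np.float64).std(axis=0)  # population convention
    return UncertaintyMap(std_map=std, n_samples=n_samples,
                          source=density.provenance)


def compare_dropout_settings(
    model: TranslationModel,
    density: Volume,
    settings=(0.0, 0.5),
    n_samples: int = 20,
    noise_mode: str = "fixed",
    seed: int = 0,
) -> dict:
    """Uncertainty maps and summary statistics for several dropout rates.

    Returns ``{"settings": {rate: {mean_std, max_std}}, ...}``; the maps
    themselves are in the ``maps`` entry keyed by rate. JSON-serializable via
    :func:`report_to_json` semantics (maps excluded).
    """
    maps = {}
    summary = {}
    for rate in settings:
        m = mc_uncertainty_map(model, density, n_samples=n_samples,
                               dropout_rate=float(rate), noise_mode=noise_mode,
                               seed=seed)
        maps[float(rate)] = m
        summary[str(float(rate))] = {
            "mean_std": m.mean_std, "max_std": m.max_std, "n_samples": m.n_samples,
        }
    return {"noise_mode": noise_mode, "n_samples": n_samples,
            "settings": summary, "maps": maps}


def report_to_json(report: dict, path: str | Path) -> Path:
    """Serialize a comparison report (summary statistics only) to JSON."""
    path = Path(path)
    payload = {k: v for k, v in report.items() if k != "maps"}
    path.write_text(json.dumps(payload, indent=2))
    return path
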