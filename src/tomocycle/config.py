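"""Run configuration, YAML round-tripping and global seed fan-out.

A single global seed is fanned out to per-component seeds through numpy's
``SeedSequence`` with fixed, documented child indices (the "counter scheme"):
child 0 seeds fixture generation, 1 training, 2 model initialization,
3 evaluation, 4 uncertainty. Every run writes its resolved configuration
next to its outputs so that any result is reproducible from that file alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .simulate import SimulationParams
from .training import TrainingConfig

__all__ = ["RunConfig", "component_seed", "COMPONENTS"]

COMPONENTS = ("fixtures", "training", "model", "evaluation", "uncertainty")


def component_seed(global_seed: int, component: str) -> int:
    """Derive a component's 31-bit seed from the global seed."""
    idx = COMPONENTS.index(component)
    child = np.random.SeedSequence(global_seed).spawn(len(COMPONENTS))[idx]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Top-level configuration: global seed plus per-command blocks."""

    seed: int = 0
    out_dir: str = "runs/latest"
    verbosity: int = 1
    simulation: SimulationParams = field(default_factory=SimulationParams)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    model: dict = field(default_factory=lambda: {
        "base_width": 32, "n_res_blocks": 6, "critic_width": 64,
        "spectral_norm": True, "dropout_rate": 0.0,
    })
    evaluation: dict = field(default_factory=lambda: {"k": 5, "feature_dim": 64})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationParams(**raw.pop("simulation", {}))
        train = TrainingConfig(**raw.pop("training", {}))
        return cls(simulation=sim, training=train, **raw)

    def seed_for(self, component: str) -> int:
        return component_seed(self.seed, component)
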