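"""Validated run configuration (YAML-backed).

Unknown keys are rejected so typos fail loudly before any compute.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_min: int = 15
    n_max: int = 40
    tf_fraction: float = 0.3
    n_cells: int = 100
    noise_scale: float = 0.5
    activation_prob: float = 0.7
    n_train: int = 100
    n_test: int = 50


class ModelSection(_Strict):
    d_x: int = 64
    d_e: int = 32
    d_t: int = 64
    heads: int = 4
    gat_heads: int = 4
    n_layers: int = 3
    edge_groups: int = 4
    p_profile: int = 32
    use_gat: bool = True
    use_cross: bool = True
    use_pool: bool = True


class TrainSection(_Strict):
    T: int = 100
    epochs: int = 100
    batch_size: int = 1
    lr: float = 3e-4
    weight_decay: float = 1e-4
    clip_norm: float = 1.0
    pos_weight_cap: float = 20.0


class GenerateSection(_Strict):
    k: int | None = None
    n_ensemble: int = 8
    deterministic: bool = False
    cutoff: float = 0.5


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "planet_out"
    log_level: str = "INFO"
    sim: SimSection = Field(default_factory=SimSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    generate: GenerateSection = Field(default_factory=GenerateSection)

    @classmethod
    def from_yaml(cls, path: str | Path | None) -> "RunConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_dict(self) -> dict:
        return self.model_dump()

    def sim_config(self, seed: int | None = None):
        from .simulate import SimConfig

        return SimConfig(n_min=self.sim.n_min, n_max=self.sim.n_max,
                         tf_fraction=self.sim.tf_fraction,
                         n_cells=self.sim.n_cells,
                         noise_scale=self.sim.noise_scale,
                         activation_prob=self.sim.activation_prob,
                         seed=self.seed if seed is None else seed)

    def train_config(self, seed: int | None = None):
        from .denoiser import TriHATConfig
        from .train import TrainConfig

        return TrainConfig(T=self.train.T, epochs=self.train.epochs,
                           batch_size=self.train.batch_size,
                           lr=self.train.lr,
                           weight_decay=self.train.weight_decay,
                           clip_norm=self.train.clip_norm,
                           pos_weight_cap=self.train.pos_weight_cap,
                           seed=self.seed if seed is None else seed,
                           model=TriHATConfig(**self.model.model_dump()))
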