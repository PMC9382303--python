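"""Run configuration: a validated, fully serializable YAML key-value tree."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .params import ModelParameters

__all__ = ["RunConfig", "load_config", "dump_config"]

_MODEL_FIELDS = {f.name for f in fields(ModelParameters) if f.name != "eif"}


@dataclass
class RunConfig:
    """Settings of a full workflow run; unspecified fields use the standard
    model parameters and the default optimization protocol (dt = 0.1 ms,
    T = 500 ms, t0 = 480 ms, s_init = 10, eps_s = 1e-30, eps_u = 1e-12)."""

    point_nA: tuple = (0.45, 0.475)
    tasks: tuple = ("DU1",)
    T: float = 500.0
    t0: float = 480.0
    dt: float = 0.1
    table_path: str | None = None
    mu_grid: tuple = (-10.0, 10.0, 201)
    sigma_grid: tuple = (0.5, 5.0, 41)
    s_init: float = 10.0
    eps_s: float = 1e-30
    eps_u: float = 1e-12
    max_iterations: int = 2000
    anneal_period: int = 30
    max_anneal_blocks: int = 20
    polish_iters: int = 200
    rng_seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    model: dict = field(default_factory=dict)   # ModelParameters overrides

    def __post_init__(self):
        unknown = set(self.model) - _MODEL_FIELDS
        if unknown:
            raise ValueError(
                f"unknown model parameter(s): {sorted(unknown)}")
        for t in self.tasks:
            if t.upper() not in ("DU1", "DU2", "UD1", "UD2"):
                raise ValueError(f"unknown task name {t!r}")

    def model_parameters(self) -> ModelParameters:
        return ModelParameters(**self.model)

    def optimization_settings(self):
        from .control import OptimizationSettings

        return OptimizationSettings(
            s_init=self.s_init, eps_s=self.eps_s, eps_u=self.eps_u,
            max_iterations=self.max_iterations,
            anneal_period=self.anneal_period,
            max_anneal_blocks=self.max_anneal_blocks,
            rng_seed=self.rng_seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["point_nA"] = list(self.point_nA)
        d["tasks"] = list(self.tasks)
        d["mu_grid"] = list(self.mu_grid)
        d["sigma_grid"] = list(self.sigma_grid)
        return d


_CONFIG_FIELDS = {f.name for f in fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data)}")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("point_nA", "tasks", "mu_grid", "sigma_grid"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
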