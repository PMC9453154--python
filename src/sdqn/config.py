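"""Run configuration: nested dataclasses with YAML round-tripping.

A run config collects the network description, neuron constants, surrogate
settings, training hyperparameters and environment geometry in one
validated object.  Loading rejects unknown keys (no silent typos) and
re-checks every invariant; ``load_config(save_config(cfg)) == cfg``.

Default origins
---------------
Values stated by the model description itself: simulation window T = 16,
conv stack "c32k8-c64k4-c64k3" with a 512-unit hidden layer, Adam
optimisation, pbLN initialisation (v_th - v_reset, v_reset), pbLN on conv
layers only, per-time-step normalisation statistics over C*H*W.
Convention-chosen values (the description leaves them open): conv strides
4/2/1 and 84x84 4-frame grayscale stacks (DQN preprocessing), tau = 2,
v_th = 0.5, v_reset = 0, eps = 1e-5, surrogate tau_s = 2 centered at
threshold, gamma = 0.99, batch 32, buffer 1e5, target sync 1000, epsilon
1.0 -> 0.05 over 1e4 steps, learning rate 1e-4, reward clipping on.
``config_origins()`` returns this mapping programmatically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .agent import TrainConfig
from .env import CatchEnvConfig
from .learning import SurrogateParams
from .lif import LIFParams

__all__ = [
    "NetConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_origins",
    "build_network",
    "build_env",
]


class ConfigError(ValueError):
    """Raised for unknown keys or invariant violations, with the field path."""


@dataclass(frozen=True)
class NetConfig:
    """Network architecture description."""

    architecture: str = "c32k8s4-c64k4s2-c64k3s1"
    fc_hidden: int = 512
    n_actions: int = 3
    pbln: bool = True
    pbln_fc: bool = False
    eps: float = 1e-5
    init: str = "kaiming"          # "kaiming" | "gaussian"
    init_weight_var: float = 0.05  # D(W) for gaussian init

    def __post_init__(self) -> None:
        if self.fc_hidden < 1 or self.n_actions < 1:
            raise ConfigError("fc_hidden and n_actions must be >= 1")
        if self.init not in ("kaiming", "gaussian"):
            raise ConfigError(f"unknown init scheme {self.init!r}")
        if not self.eps > 0:
            raise ConfigError("eps must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    net: NetConfig = NetConfig()
    lif: LIFParams = LIFParams()
    surrogate: SurrogateParams = SurrogateParams()
    train: TrainConfig = TrainConfig()
    env: CatchEnvConfig = CatchEnvConfig()
    out_dir: str = "runs"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.train.frame_stack < 1:
            raise ConfigError("train.frame_stack must be >= 1")
        # the readout window and training window are the same object by
        # construction (build_network wires cfg.train.T into the network)


_SECTION_TYPES = {
    "net": NetConfig,
    "lif": LIFParams,
    "surrogate": SurrogateParams,
    "train": TrainConfig,
    "env": CatchEnvConfig,
}


def _build_section(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; an empty file yields defaults."""
    if data is None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            section = data[name] or {}
            if not isinstance(section, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    for name in ("out_dir", "log_level"):
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)


def _to_dict(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    return obj


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def config_origins() -> dict[str, str]:
    """Which defaults come from the model description vs DQN/field convention."""
    return {
        "train.T": "model description (T = 16)",
        "net.architecture": "model description (c32k8-c64k4-c64k3; strides 4/2/1 by DQN convention)",
        "net.fc_hidden": "model description (512)",
        "net.pbln": "model description (pbLN on conv PSPs)",
        "lif.tau": "convention (tau = 2, alpha = 0.5)",
        "lif.v_th": "convention (0.5)",
        "lif.v_reset": "convention (0.0)",
        "net.eps": "convention (1e-5)",
        "surrogate.tau_s": "convention (2.0, independent of membrane tau)",
        "surrogate.centered": "convention (bump centered at threshold)",
        "train.gamma": "DQN convention (0.99)",
        "train.lr": "DQN convention (1e-4, Adam per model description)",
        "train.batch_size": "DQN convention (32)",
        "train.target_sync": "DQN convention (1000 steps)",
        "train.eps_start/eps_end/eps_decay_steps": "DQN convention (1.0 -> 0.05 over 1e4)",
        "train.buffer_capacity": "DQN convention (1e5)",
        "train.frame_stack": "DQN convention (4 frames)",
        "train.clip_rewards": "DQN convention (rewards clipped to [-1, 1])",
        "env.*": "package-defined synthetic environment (catch, 21x21 -> 84x84)",
    }


def build_network(cfg: RunConfig, seed: int = 0):
    """Construct the spiking Q-network described by a run config."""
    import numpy as np

    from .network import SpikingQNetwork

    input_shape = (cfg.train.frame_stack, cfg.env.render_size, cfg.env.render_size)
    net = SpikingQNetwork(
        input_shape=input_shape,
        conv=cfg.net.architecture,
        fc_hidden=cfg.net.fc_hidden,
        n_actions=cfg.net.n_actions,
        T=cfg.train.T,
        lif=cfg.lif,
        surrogate=cfg.surrogate,
        pbln=cfg.net.pbln,
        pbln_fc=cfg.net.pbln_fc,
        eps=cfg.net.eps,
    )
    rng = np.random.default_rng(seed)
    if cfg.net.init == "gaussian":
        net.init_weights(rng, scheme="gaussian", weight_var=cfg.net.init_weight_var)
    else:
        net.init_weights(rng, scheme="kaiming")
    return net


def build_env(cfg: RunConfig):
    from .env import CatchEnv

    return CatchEnv(cfg.env)
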