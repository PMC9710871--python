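"""Run configuration shared by the CLI and the library.

Every CLI flag has a config-file equivalent; a TOML or YAML file holding a
subset of :class:`RunConfig` fields is merged under explicit flags.  Values
in effect are logged at startup.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields

__all__ = ["RunConfig", "load_config"]

logger = logging.getLogger("velonode")


@dataclass
class RunConfig:
    seed: int = 0
    solver: str = "euler"            # euler | rk23 | dop853
    velocity_scale: float = 0.65
    n_steps: int = 15
    intermediate_steps: int = 5
    anchor_k: int = 5
    pca_dims: int = 30
    knn_k: int = 30
    cci_T: int = 35
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.velocity_scale <= 2):
            raise ValueError("velocity_scale must be in (0, 2]")
        for name in ("n_steps", "intermediate_steps", "anchor_k",
                     "pca_dims", "knn_k", "cci_T"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.solver not in ("euler", "rk23", "dop853"):
            raise ValueError(f"unknown solver {self.solver!r}")

    def log(self) -> None:
        logging.basicConfig(level=self.log_level)
        for k, v in asdict(self).items():
            logger.info("config %s = %r", k, v)


def load_config(path: str | None, **overrides) -> RunConfig:
    """Read a TOML/YAML config file and apply keyword overrides on top."""
    values: dict = {}
    if path is not None:
        if str(path).endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                values = tomllib.load(fh)
        else:
            import yaml

            with open(path) as fh:
                values = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
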