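"""Flat key-value run configuration with CLI override precedence."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings shared by the command-line subcommands.

    Values from a YAML config file are overridden by any explicitly
    supplied CLI flags. Unknown keys are rejected with the valid list.
    """

    c_sa: float | None = None
    c_as: float | None = None
    y0: float = 0.0
    generations: int = 40
    tol: float = 0.02
    seed: int = 0
    n_clones: int = 50
    founder_prob: float | None = None
    colonies: int = 200
    events: int = 10000
    threshold: float = 0.15
    fold: float = 3.0
    fixture: str | None = None

    @classmethod
    def valid_keys(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = sorted(set(data) - set(cls.valid_keys()))
        if unknown:
            raise ValueError(
                f"unknown config keys {unknown}; valid keys: {cls.valid_keys()}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        return cls.from_dict(data)

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with non-None overrides applied (CLI precedence)."""
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for key, value in kwargs.items():
            if key not in data:
                raise ValueError(
                    f"unknown config key {key!r}; valid keys: {self.valid_keys()}"
                )
            if value is not None:
                data[key] = value
        return RunConfig(**data)
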