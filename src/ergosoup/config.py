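"""Ensemble configuration: parameters of the soup and their validation.

All simulator knobs live in a single flat, JSON-serializable dataclass so a
run is fully determined by (config, seed).  Defaults are the reference
conditions used throughout: 128 subsystems moving in two dimensions,
forward-Euler steps of 1/512 s, unit-variance fluctuations, a third of the
subsystems functionally closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid; names the field."""


@dataclass(frozen=True)
class ForceParams:
    """Constants of the Newtonian pair force and ambient terms.

    ``repulsion_strength`` multiplies the inverse-square repulsion,
    ``attraction_strength`` the coherence-gated attraction (active between
    subsystems whose third electrochemical states agree),
    ``viscosity_coeff`` the velocity-proportional drag and
    ``well_stiffness`` the quadratic potential well that confines the soup.
    """

    repulsion_strength: float = 1.0
    attraction_strength: float = 2.0
    viscosity_coeff: float = 4.0
    well_stiffness: float = 0.15

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not v >= 0:
                raise ConfigError(f"force_params.{f.name} must be a nonnegative real, got {v!r}")


@dataclass(frozen=True)
class EnsembleConfig:
    """Full parameterization of a soup simulation."""

    n_subsystems: int = 128
    space_dim: int = 2
    dt: float = 1.0 / 512.0
    duration: float = 2048.0
    save_interval: float = 1.0
    coupling_radius: float = 1.0
    closed_fraction: float = 1.0 / 3.0
    lorenz_params: tuple[float, float, float] = (10.0, 32.0, 8.0 / 3.0)
    force_params: ForceParams = field(default_factory=ForceParams)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_subsystems, int) and self.n_subsystems > 0):
            raise ConfigError(f"n_subsystems must be a positive integer, got {self.n_subsystems!r}")
        if not (isinstance(self.space_dim, int) and self.space_dim > 0):
            raise ConfigError(f"space_dim must be a positive integer, got {self.space_dim!r}")
        if not self.dt > 0:
            raise ConfigError(f"dt must be > 0, got {self.dt!r}")
        if self.duration < 0:
            raise ConfigError(f"duration must be >= 0, got {self.duration!r}")
        if not self.save_interval > 0:
            raise ConfigError(f"save_interval must be > 0, got {self.save_interval!r}")
        ratio = self.save_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                f"save_interval ({self.save_interval}) must be an integer multiple of dt ({self.dt})"
            )
        if not self.coupling_radius > 0:
            raise ConfigError(f"coupling_radius must be > 0, got {self.coupling_radius!r}")
        if not 0.0 <= self.closed_fraction <= 1.0:
            raise ConfigError(f"closed_fraction must lie in [0, 1], got {self.closed_fraction!r}")
        if len(tuple(self.lorenz_params)) != 3:
            raise ConfigError(f"lorenz_params must be a triple, got {self.lorenz_params!r}")
        object.__setattr__(self, "lorenz_params", tuple(float(v) for v in self.lorenz_params))
        if isinstance(self.force_params, dict):
            object.__setattr__(self, "force_params", ForceParams(**self.force_params))
        if not self.noise_sd >= 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    @property
    def steps_per_save(self) -> int:
        return round(self.save_interval / self.dt)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lorenz_params"] = list(self.lorenz_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        d = dict(d)
        if "lorenz_params" in d:
            d["lorenz_params"] = tuple(d["lorenz_params"])
        if "force_params" in d:
            fp = d["force_params"]
            if isinstance(fp, dict):
                known_fp = {f.name for f in fields(ForceParams)}
                unknown_fp = sorted(set(fp) - known_fp)
                if unknown_fp:
                    raise ConfigError(
                        f"unknown configuration key(s): force_params.{', force_params.'.join(unknown_fp)}"
                    )
                d["force_params"] = ForceParams(**fp)
        return cls(**d)


def load_config(path: str | Path) -> EnsembleConfig:
    """Read an :class:`EnsembleConfig` from a JSON file.

    Missing keys take their defaults; unknown keys are rejected.  Distinct
    errors are raised for a missing file, malformed JSON and invalid values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a JSON object, got {type(raw).__name__}")
    return EnsembleConfig.from_dict(raw)


def save_config(config: EnsembleConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")
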