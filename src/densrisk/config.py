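"""Configuration objects for the cohort simulator and the neural models.

Defaults reproduce the study conditions of the feasibility analysis: a
cohort of 1000 screening-age patients whose age follows a truncated normal
law, with breast density (``densitanum``) a quadratic function of age and a
composite cancer-risk index (``riskenum``) driven by log-age and density,
each perturbed by Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    The default values are the study's fixed simulation conditions:
    Age ~ TruncNormal(mu=52, sigma=12, [25, 85]);
    densitanum = 1.8 + 0.10*age - 0.002*age^2 + N(0, 0.35);
    riskenum = 12 + 0.25*ln(age) + 0.20*densitanum + N(0, 0.25);
    n_patients = 1000. ``riskenum`` uses the realized (noisy) density.
    """

    n_patients: int = 1000
    age_mu: float = 52.0
    age_sigma: float = 12.0
    age_min: float = 25.0
    age_max: float = 85.0
    dens_intercept: float = 1.8
    dens_age_coef: float = 0.10
    dens_age2_coef: float = -0.002
    dens_noise_sd: float = 0.35
    risk_intercept: float = 12.0
    risk_logage_coef: float = 0.25
    risk_density_coef: float = 0.20
    risk_noise_sd: float = 0.25
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_patients, (int,)) or self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        if self.age_sigma <= 0:
            raise ConfigurationError(f"age_sigma must be > 0, got {self.age_sigma!r}")
        if not self.age_min < self.age_max:
            raise ConfigurationError(
                f"age_min must be strictly below age_max, got age_min={self.age_min!r}, age_max={self.age_max!r}"
            )
        if self.dens_noise_sd < 0:
            raise ConfigurationError(f"dens_noise_sd must be >= 0, got {self.dens_noise_sd!r}")
        if self.risk_noise_sd < 0:
            raise ConfigurationError(f"risk_noise_sd must be >= 0, got {self.risk_noise_sd!r}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigurationError(f"unknown simulation config field(s): {sorted(extra)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a JSON or YAML file (YAML is a JSON superset, so one loader)."""
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def with_noise_variance_factor(self, factor: float) -> "SimulationConfig":
        """Scale both noise *variances* by ``factor`` (SDs by sqrt(factor))."""
        if factor <= 0:
            raise ConfigurationError(f"variance factor must be > 0, got {factor!r}")
        return dataclasses.replace(
            self,
            dens_noise_sd=self.dens_noise_sd * factor**0.5,
            risk_noise_sd=self.risk_noise_sd * factor**0.5,
        )


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters.

    Defaults are the study protocol: MLP hidden sizes (64, 32); the
    bifurcated net's shared trunk Dense(32, ReLU, L2) -> BatchNorm ->
    Dropout(0.4) -> Dense(8) splitting into a density branch
    Dense(8) -> linear output and a risk branch Dropout(0.3) ->
    linear output; Adam (lr 0.001, default betas), batch 32, at most
    300 epochs with early-stopping patience 10, 80/20 train/test split.
    """

    architecture: str = "bifurcated"  # "single_output_mlp" | "bifurcated"
    hidden_sizes: tuple[int, int] = (64, 32)
    trunk_width: int = 32
    trunk_bottleneck: int = 8
    trunk_dropout: float = 0.4
    batch_norm: bool = True
    density_branch_width: int = 8
    risk_branch_dropout: float = 0.3
    l2_lambda: float = 1e-3
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 10
    validation_fraction: float = 0.2
    train_fraction: float = 0.8
    loss_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("single_output_mlp", "bifurcated"):
            raise ConfigurationError(
                f"architecture must be 'single_output_mlp' or 'bifurcated', got {self.architecture!r}"
            )
        for name in ("trunk_dropout", "risk_branch_dropout"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ConfigurationError(f"{name} must lie in [0, 1), got {rate!r}")
        for name in ("validation_fraction", "train_fraction"):
            frac = getattr(self, name)
            if not 0 < frac < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {frac!r}")
        if self.patience > self.max_epochs:
            raise ConfigurationError(
                f"patience ({self.patience}) must not exceed max_epochs ({self.max_epochs})"
            )
        if self.max_epochs < 1:
            raise ConfigurationError(f"max_epochs must be >= 1, got {self.max_epochs!r}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size!r}")
        if self.learning_rate < 0:
            raise ConfigurationError(f"learning_rate must be >= 0, got {self.learning_rate!r}")
        if self.l2_lambda < 0:
            raise ConfigurationError(f"l2_lambda must be >= 0, got {self.l2_lambda!r}")
        if any(w < 0 for w in self.loss_weights):
            raise ConfigurationError(f"loss_weights must be non-negative, got {self.loss_weights!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["loss_weights"] = list(self.loss_weights)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigurationError(f"unknown network config field(s): {sorted(extra)}")
        data = dict(data)
        if "hidden_sizes" in data:
            data["hidden_sizes"] = tuple(data["hidden_sizes"])
        if "loss_weights" in data:
            data["loss_weights"] = tuple(data["loss_weights"])
        return cls(**data)

    def replace(self, **kwargs: Any) -> "NetworkConfig":
        return dataclasses.replace(self, **kwargs)
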