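"""End-to-end pipeline: simulate -> fit -> evaluate -> stability/sensitivity.

One YAML config with ``simulation``, ``models`` and ``evaluation``
sections drives a full reproducible run. Every stochastic stage takes its
seed from the config, so re-running the same config reproduces every
numeric output byte for byte (timestamps live only in the run manifest,
never in numeric artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import sklearn
import statsmodels
import yaml

from . import __version__
from .config import NetworkConfig, SimulationConfig
from .evaluation import compare_models, noise_sensitivity, seed_stability
from .exceptions import ConfigurationError
from .linear import model_a, model_b, recover_generative_parameters
from .networks.models import split_cohort, train_bifurcated, train_mlp
from .simulate import generate_cohort, write_cohort

log = logging.getLogger("densrisk.pipeline")


@dataclass
class RunConfig:
    """Validated top-level pipeline configuration."""

    simulation: SimulationConfig
    network: NetworkConfig
    split_seed: int = 0
    stability_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    sensitivity_variance_factor: float | None = 1.2

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        errors: list[str] = []
        known_sections = {"simulation", "models", "evaluation"}
        for section in set(data) - known_sections:
            errors.append(f"unknown config section {section!r}")
        sim = net = None
        try:
            sim = SimulationConfig.from_dict(data.get("simulation", {}) or {})
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"simulation: {exc}")
        try:
            net = NetworkConfig.from_dict(data.get("models", {}) or {})
        except (ConfigurationError, TypeError) as exc:
            errors.append(f"models: {exc}")
        ev = dict(data.get("evaluation", {}) or {})
        split_seed = ev.pop("split_seed", 0)
        stability_seeds = tuple(ev.pop("stability_seeds", (0, 1, 2, 3, 4)))
        factor = ev.pop("sensitivity_variance_factor", 1.2)
        if ev:
            errors.append(f"evaluation: unknown field(s) {sorted(ev)}")
        if factor is not None and factor <= 0:
            errors.append(f"evaluation: sensitivity_variance_factor must be > 0, got {factor!r}")
        if errors:
            raise ConfigurationError("invalid run config:\n  " + "\n  ".join(errors))
        return cls(
            simulation=sim,
            network=net,
            split_seed=int(split_seed),
            stability_seeds=stability_seeds,
            sensitivity_variance_factor=factor,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"run config {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": self.simulation.to_dict(),
            "models": self.network.to_dict(),
            "evaluation": {
                "split_seed": self.split_seed,
                "stability_seeds": list(self.stability_seeds),
                "sensitivity_variance_factor": self.sensitivity_variance_factor,
            },
        }


def default_run_config() -> dict[str, Any]:
    """The shipped default configuration (the study's conditions)."""
    return RunConfig(simulation=SimulationConfig(), network=NetworkConfig()).to_dict()


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, versions, artifacts, stage status."""

    config: dict[str, Any]
    output_dir: str
    started: str
    software: dict[str, str] = field(default_factory=dict)
    stages: list[dict[str, Any]] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)
    finished: str | None = None
    status: str = "running"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _versions() -> dict[str, str]:
    return {
        "densrisk": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_pipeline(config: str | Path | RunConfig | dict, output_dir: str | Path) -> RunManifest:
    """Execute the full pipeline; halt (with a manifest) on any stage failure."""
    if isinstance(config, (str, Path)):
        run_config = RunConfig.from_file(config)
    elif isinstance(config, dict):
        run_config = RunConfig.from_dict(config)
    else:
        run_config = config

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=run_config.to_dict(),
        output_dir=str(outdir),
        started=_now(),
        software=_versions(),
    )
    manifest_path = outdir / "manifest.json"

    def record(stage: str, seed: Any, artifacts: dict[str, Path]) -> None:
        hashes = {name: _sha256(p) for name, p in artifacts.items()}
        manifest.stages.append({"stage": stage, "status": "ok", "seed": seed, "outputs": hashes})
        for name, p in artifacts.items():
            manifest.artifacts[name] = str(p)
        log.info("stage=%s seed=%s outputs=%s", stage, seed, {k: h[:12] for k, h in hashes.items()})

    try:
        # 1. simulate
        cohort = generate_cohort(run_config.simulation)
        cohort_path = outdir / "cohort.csv"
        write_cohort(cohort, cohort_path)
        record("simulate", run_config.simulation.master_seed, {"cohort": cohort_path})

        # 2. linear baselines + parameter recovery
        paths = {}
        for name, result in (
            ("model_a", model_a(cohort)),
            ("model_b", model_b(cohort)),
        ):
            p = outdir / f"{name}.json"
            result.to_json(p)
            paths[name] = p
        dens_fit, risk_fit = recover_generative_parameters(cohort)
        recovery_path = outdir / "recovery.json"
        recovery_path.write_text(
            json.dumps(
                {"density_equation": dens_fit.to_dict(), "risk_equation": risk_fit.to_dict()},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        paths["recovery"] = recovery_path
        record("linear_baselines", None, paths)

        # 3. neural models on a shared split
        train, test = split_cohort(cohort, run_config.network.train_fraction, run_config.split_seed)
        mlp = train_mlp(train, "riskenum", run_config.network.replace(architecture="single_output_mlp"))
        bif = train_bifurcated(train, run_config.network.replace(architecture="bifurcated"))
        model_paths = {}
        for name, model in (("mlp_riskenum", mlp), ("bifurcated", bif)):
            mdir = outdir / "models" / name
            model.save(mdir)
            model_paths[f"{name}_manifest"] = mdir / "manifest.json"
        record("train", run_config.network.seed, model_paths)

        # 4. evaluation (comparison + stability + sensitivity)
        report = compare_models(
            cohort,
            run_config.network,
            split_seed=run_config.split_seed,
            mlp_model=mlp,
            bif_model=bif,
        )
        evaluation: dict[str, Any] = {"comparison": report.to_dict()}
        if len(run_config.stability_seeds) >= 2:
            stability = seed_stability(
                cohort, run_config.network, seeds=run_config.stability_seeds, split_seed=run_config.split_seed
            )
            evaluation["stability"] = stability.to_dict()
        if run_config.sensitivity_variance_factor is not None:
            evaluation["sensitivity"] = noise_sensitivity(
                run_config.simulation,
                run_config.sensitivity_variance_factor,
                run_config.network,
                split_seed=run_config.split_seed,
            )
        eval_path = outdir / "evaluation.json"
        eval_path.write_text(json.dumps(evaluation, indent=2, sort_keys=True) + "\n")
        record("evaluate", run_config.split_seed, {"evaluation": eval_path})

        manifest.status = "ok"
    except Exception as exc:
        manifest.stages.append({"stage": "failed", "status": "error", "error": f"{type(exc).__name__}: {exc}"})
        manifest.status = "failed"
        manifest.finished = _now()
        manifest.write(manifest_path)
        raise
    manifest.finished = _now()
    manifest.write(manifest_path)
    return manifest
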