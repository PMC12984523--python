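"""Model objects for the single-output MLP and the bifurcated network.

The public surface follows the model/results convention of statistical
modelling packages: a model class is constructed from a training cohort
and a :class:`~densrisk.config.NetworkConfig`, and ``fit()`` returns a
:class:`TrainedModel` results object carrying the fitted weights, the
feature scaler, the stopped epoch and the training history, with
``predict``/``evaluate``/``summary`` methods. Thin functional wrappers
(`train_mlp`, `train_bifurcated`, `predict`) expose the same operations.

Both architectures consume the same two features, age and age squared
(the quadratic term lets the nets capture the parabolic density trend),
standardized with statistics estimated on the training split only.
Targets stay in natural units so MAE/MSE read directly on the density
and risk scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from sklearn.preprocessing import StandardScaler

from ..config import NetworkConfig
from ..exceptions import ConfigurationError, NotFittedError
from ..simulate import Cohort, cohort_fingerprint
from . import engine

OUTPUT_NAMES = ("densitanum", "riskenum")


def make_features(ages: np.ndarray) -> np.ndarray:
    """Feature matrix with columns (age, age^2), one row per input age."""
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1:
        ages = ages.ravel()
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    return np.column_stack([ages, ages**2])


def split_cohort(cohort: Cohort, train_fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Shuffled, disjoint, exhaustive train/test split (floor(f*n) train rows)."""
    if not 0 < train_fraction < 1:
        raise ConfigurationError(f"train_fraction must lie in (0, 1), got {train_fraction!r}")
    n = len(cohort)
    if n < 10:
        raise ValueError(f"cohort must have at least 10 records to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    frame = cohort.data
    return (
        Cohort(frame.iloc[train_idx].reset_index(drop=True), provenance=cohort.provenance),
        Cohort(frame.iloc[test_idx].reset_index(drop=True), provenance=cohort.provenance),
    )


def fit_scaler(train_features: np.ndarray) -> StandardScaler:
    """Standardize columns to zero mean / unit SD using training rows only."""
    train_features = np.asarray(train_features, dtype=float)
    if train_features.shape[0] < 2:
        raise ConfigurationError("scaler needs at least 2 training rows")
    if np.any(train_features.std(axis=0) == 0):
        raise ConfigurationError("scaler requires nonzero spread in every feature column")
    return StandardScaler().fit(train_features)


def apply_scaler(scaler: StandardScaler, features: np.ndarray) -> np.ndarray:
    return scaler.transform(np.asarray(features, dtype=float))


@dataclass
class TrainedModel:
    """Results object for a fitted network.

    ``outputs`` names the prediction columns; the bifurcated model always
    emits ("densitanum", "riskenum"), the MLP the single target it was
    trained for.
    """

    config: NetworkConfig
    scaler: StandardScaler
    net: object
    outputs: tuple[str, ...]
    stopped_epoch: int
    training_history: list[dict[str, float]] = field(repr=False)
    train_fingerprint: str | None = None

    def predict(self, ages: np.ndarray) -> dict[str, np.ndarray]:
        """Deterministic inference (dropout off, batch norm on running stats)."""
        if self.net is None:
            raise NotFittedError("model has no fitted weights")
        features = apply_scaler(self.scaler, make_features(np.asarray(ages, dtype=float)))
        raw = self.net.forward(features, training=False)
        return {name: raw[:, i] for i, name in enumerate(self.outputs)}

    def evaluate(self, cohort: Cohort) -> dict[str, "FitMetrics"]:
        """Per-output test metrics on a held-out cohort."""
        from ..evaluation import compute_metrics  # local import breaks the cycle

        preds = self.predict(cohort.age)
        truth = {"densitanum": cohort.densitanum, "riskenum": cohort.riskenum}
        return {name: compute_metrics(truth[name], preds[name], name) for name in self.outputs}

    @property
    def final_losses(self) -> dict[str, float]:
        last = self.training_history[-1]
        return {"train_loss": last["train_loss"], "val_loss": last["val_loss"]}

    def summary(self) -> str:
        lines = [
            f"{type(self.net).__name__} ({self.config.architecture})",
            f"outputs: {', '.join(self.outputs)}",
            f"stopped epoch: {self.stopped_epoch} / {self.config.max_epochs}",
            f"final train loss: {self.final_losses['train_loss']:.6g}",
            f"final val loss:   {self.final_losses['val_loss']:.6g}",
            f"seed: {self.config.seed}",
        ]
        return "\n".join(lines)

    # -- artifact serialization (runtime outputs, not repo fixtures) ----

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, layer in enumerate(self.net.all_layers()):
            for j, p in enumerate(engine._state(layer)):
                arrays[f"layer{i}_p{j}"] = p
        np.savez(directory / "weights.npz", **arrays)
        manifest = {
            "config": self.config.to_dict(),
            "outputs": list(self.outputs),
            "stopped_epoch": self.stopped_epoch,
            "final_losses": self.final_losses,
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "n_epochs_run": len(self.training_history),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _prepare(train: Cohort, targets: list[str], config: NetworkConfig):
    """Scale features, carve a validation subset out of the training split."""
    features = make_features(train.age)
    scaler = fit_scaler(features)
    X = apply_scaler(scaler, features)
    y = np.column_stack([getattr(train, t) for t in targets])

    streams = np.random.SeedSequence(config.seed).spawn(4)
    init_rng, shuffle_rng, dropout_rng, carve_rng = (np.random.default_rng(s) for s in streams)
    n = X.shape[0]
    perm = carve_rng.permutation(n)
    n_val = max(1, int(np.floor(config.validation_fraction * n)))
    if n - n_val < 1:
        raise ConfigurationError("validation_fraction leaves no training rows")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    return scaler, X[tr_idx], y[tr_idx], X[val_idx], y[val_idx], init_rng, shuffle_rng, dropout_rng


def _fit(net, scaler, X_tr, y_tr, X_val, y_val, outputs, config, shuffle_rng,
         fingerprint: str | None = None) -> TrainedModel:
    # warm-start each linear output at its target mean: targets are kept in
    # natural units, and Adam's bounded step size cannot move a zero bias to
    # a distant target mean within the fixed epoch budget
    net.set_output_bias(y_tr.mean(axis=0))
    stopped_epoch, history = engine.train_network(
        net,
        X_tr,
        y_tr,
        X_val,
        y_val,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        loss_weights=config.loss_weights,
        shuffle_rng=shuffle_rng,
    )
    return TrainedModel(
        config=config,
        scaler=scaler,
        net=net,
        outputs=outputs,
        stopped_epoch=stopped_epoch,
        training_history=history,
        train_fingerprint=fingerprint,
    )


class SingleOutputMLP:
    """Single-output regressor: Dense(64, ReLU) -> Dense(32, ReLU) -> linear.

    Trained with Adam on an MSE loss; inputs (age, age^2) standardized on
    the training split.
    """

    def __init__(self, train: Cohort, target: str, config: NetworkConfig | None = None) -> None:
        if target not in OUTPUT_NAMES:
            raise ConfigurationError(f"target must be one of {OUTPUT_NAMES}, got {target!r}")
        self.train_cohort = train
        self.target = target
        self.config = (config or NetworkConfig(architecture="single_output_mlp")).replace(
            architecture="single_output_mlp"
        )

    def fit(self) -> TrainedModel:
        cfg = self.config
        scaler, X_tr, y_tr, X_val, y_val, init_rng, shuffle_rng, _ = _prepare(
            self.train_cohort, [self.target], cfg
        )
        net = engine.MLPNetwork(X_tr.shape[1], cfg.hidden_sizes, init_rng)
        return _fit(net, scaler, X_tr, y_tr, X_val, y_val, (self.target,), cfg, shuffle_rng,
                    fingerprint=cohort_fingerprint(self.train_cohort))


class BifurcatedNetwork:
    """Multi-output model predicting density and risk from a shared trunk.

    The joint loss is the weighted sum of the two per-output MSEs; shared
    layers let the correlated targets regularize each other (the
    multi-task-learning rationale for the architecture).
    """

    def __init__(self, train: Cohort, config: NetworkConfig | None = None) -> None:
        self.train_cohort = train
        self.config = (config or NetworkConfig()).replace(architecture="bifurcated")

    def fit(self) -> TrainedModel:
        cfg = self.config
        scaler, X_tr, y_tr, X_val, y_val, init_rng, shuffle_rng, dropout_rng = _prepare(
            self.train_cohort, list(OUTPUT_NAMES), cfg
        )
        net = engine.BifurcatedNetwork(
            X_tr.shape[1],
            trunk_width=cfg.trunk_width,
            bottleneck=cfg.trunk_bottleneck,
            trunk_dropout=cfg.trunk_dropout,
            batch_norm=cfg.batch_norm,
            density_branch_width=cfg.density_branch_width,
            risk_branch_dropout=cfg.risk_branch_dropout,
            l2_lambda=cfg.l2_lambda,
            init_rng=init_rng,
            dropout_rng=dropout_rng,
        )
        return _fit(net, scaler, X_tr, y_tr, X_val, y_val, OUTPUT_NAMES, cfg, shuffle_rng,
                    fingerprint=cohort_fingerprint(self.train_cohort))


def train_mlp(train: Cohort, target: str, config: NetworkConfig | None = None) -> TrainedModel:
    """Functional wrapper around :class:`SingleOutputMLP`."""
    return SingleOutputMLP(train, target, config).fit()


def train_bifurcated(train: Cohort, config: NetworkConfig | None = None) -> TrainedModel:
    """Functional wrapper around :class:`BifurcatedNetwork`."""
    return BifurcatedNetwork(train, config).fit()


def predict(model: TrainedModel, ages: np.ndarray) -> dict[str, np.ndarray]:
    """Per-output predictions at the given ages."""
    return model.predict(ages)
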