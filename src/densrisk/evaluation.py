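"""Evaluation protocol: metrics, paired tests, stability and sensitivity.

Implements the study's evaluation procedures: per-output MSE/MAE/R^2 on a
held-out test set, a Wilcoxon signed-rank comparison of paired absolute
prediction errors (MLP vs bifurcated network on the risk output),
seed-stability of retraining, and a noise-sensitivity re-run with the
generative noise variance inflated.

The Wilcoxon test is implemented to a fixed contract: zero differences
are dropped (Wilcoxon's original rule, not Pratt's), tied absolute
differences receive average ranks, the null distribution is enumerated
exactly for up to 12 effective pairs (dynamic programming over doubled
ranks, which are integers even with midranks), and larger samples use
the normal approximation with tie correction and a continuity
correction. p-values are two-sided throughout.

R^2 on test data uses the test-set mean in the total sum of squares
(out-of-sample convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import NetworkConfig, SimulationConfig
from .exceptions import ConfigurationError, DegenerateComparisonError
from .linear import model_b
from .networks.models import TrainedModel, split_cohort, train_bifurcated, train_mlp
from .reference import PUBLISHED_PERFORMANCE
from .simulate import Cohort, cohort_fingerprint, generate_cohort

_JENSEN_SLACK = 1e-9


@dataclass(frozen=True)
class FitMetrics:
    """MSE, MAE and R^2 for one output on one evaluation set."""

    output_name: str
    mse: float
    mae: float
    r_squared: float
    n_test: int

    def to_dict(self) -> dict:
        return {
            "output": self.output_name,
            "mse": self.mse,
            "mae": self.mae,
            "r_squared": self.r_squared,
            "n_test": self.n_test,
        }


def compute_metrics(true_values: np.ndarray, predictions: np.ndarray, output_name: str) -> FitMetrics:
    y = np.asarray(true_values, dtype=float).ravel()
    p = np.asarray(predictions, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty evaluation set")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} true values vs {p.size} predictions")
    resid = y - p
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError(f"r_squared undefined: zero variance in true values for {output_name!r}")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    # Jensen: (mean |e|)^2 <= mean e^2, checked on every report
    assert mae**2 <= mse + _JENSEN_SLACK
    return FitMetrics(output_name=output_name, mse=mse, mae=mae, r_squared=r2, n_test=y.size)


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank sum, two-sided p, effective n and the method used."""

    statistic: float
    p_value: float
    n_effective: int
    method: str  # "exact" | "normal-approximation"
    zero_handling: str = "dropped (Wilcoxon's rule, not Pratt's)"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_effective": self.n_effective,
            "method": self.method,
            "zero_handling": self.zero_handling,
        }


EXACT_LIMIT = 12


def _exact_two_sided_p(doubled_ranks: np.ndarray, w_plus_doubled: int) -> float:
    """Exact two-sided p by DP over the 2^n sign assignments.

    ``doubled_ranks`` are the tie-adjusted ranks times two (integers);
    the DP array counts sign assignments achieving each doubled
    positive-rank sum.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)  # doubled ranks are >= 2
        counts[r:] = counts[r:] + counts[:-r]
    n_assignments = counts.sum()
    lower = counts[: w_plus_doubled + 1].sum() / n_assignments
    upper = counts[w_plus_doubled:].sum() / n_assignments
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(abs_errors_a: np.ndarray, abs_errors_b: np.ndarray) -> WilcoxonResult:
    """Paired signed-rank test on the differences a - b."""
    a = np.asarray(abs_errors_a, dtype=float).ravel()
    b = np.asarray(abs_errors_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"paired samples must have equal length, got {a.size} and {b.size}")
    d = a - b
    if np.all(d == 0):
        raise DegenerateComparisonError("all paired differences are zero; the comparison is degenerate")
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError(f"need at least 5 nonzero paired differences, got {n}")

    ranks = rankdata(np.abs(d))  # average ranks for ties
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_LIMIT:
        doubled = np.rint(2.0 * ranks).astype(int)
        w2 = int(np.rint(2.0 * w_plus))
        p = _exact_two_sided_p(doubled, w2)
        return WilcoxonResult(statistic=w_plus, p_value=max(p, np.finfo(float).tiny), n_effective=n, method="exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups of |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        raise DegenerateComparisonError("zero variance in the signed-rank statistic")
    delta = w_plus - mean
    # continuity correction shrinks |delta| by 0.5
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var) if delta != 0 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, p_value=max(p, np.finfo(float).tiny), n_effective=n,
                          method="normal-approximation")


@dataclass
class ComparisonReport:
    """Table-2-shaped comparison of linear, MLP and bifurcated models."""

    rows: list[dict]
    wilcoxon: WilcoxonResult
    interpretation: str
    n_train: int
    n_test: int
    split_seed: int
    published_reference: dict = field(default_factory=lambda: PUBLISHED_PERFORMANCE)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "wilcoxon_mlp_vs_bifurcated_risk": self.wilcoxon.to_dict(),
            "interpretation": self.interpretation,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "split_seed": self.split_seed,
            "r_squared_convention": "test-set mean in SS_tot (out-of-sample)",
            "published_reference": self.published_reference,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def _interpret(p_value: float, alpha: float = 0.05) -> str:
    if p_value >= alpha:
        return (
            f"The signed-rank test did not find enough evidence to conclude that the "
            f"two models' risk-prediction errors differ (p = {p_value:.3g}). A "
            f"non-significant result does not demonstrate that they perform the same."
        )
    return (
        f"The signed-rank test indicates a difference between the two models' paired "
        f"risk-prediction errors (p = {p_value:.3g})."
    )


def compare_models(
    cohort: Cohort,
    net_config: NetworkConfig | None = None,
    split_seed: int = 0,
    mlp_model: TrainedModel | None = None,
    bif_model: TrainedModel | None = None,
) -> ComparisonReport:
    """Fit all model classes on one shared 80/20 split and compare them.

    Pre-trained models may be supplied, but they must have been trained on
    the very training split this comparison uses (checked by fingerprint);
    otherwise the paired Wilcoxon comparison would be meaningless.
    """
    net_config = net_config or NetworkConfig()
    train, test = split_cohort(cohort, net_config.train_fraction, split_seed)
    fp = cohort_fingerprint(train)

    for name, model in (("mlp_model", mlp_model), ("bif_model", bif_model)):
        if model is not None and getattr(model, "train_fingerprint", None) != fp:
            raise ValueError(f"{name} was not trained on the shared training split of this comparison")

    if mlp_model is None:
        mlp_model = train_mlp(train, "riskenum", net_config.replace(architecture="single_output_mlp"))
    if bif_model is None:
        bif_model = train_bifurcated(train, net_config.replace(architecture="bifurcated"))

    linear_fit = model_b(train)
    linear_pred = (
        linear_fit.coefficients[0]
        + linear_fit.coefficients[1] * test.age
        + linear_fit.coefficients[2] * test.densitanum
    )
    linear_metrics = compute_metrics(test.riskenum, linear_pred, "riskenum")
    mlp_metrics = mlp_model.evaluate(test)["riskenum"]
    bif_metrics = bif_model.evaluate(test)

    rows = [
        {"model": "linear_regression", **linear_metrics.to_dict(), "notes": "Model B on the training split"},
        {"model": "mlp", **mlp_metrics.to_dict(), "notes": "single-output"},
        {"model": "bifurcated", **bif_metrics["densitanum"].to_dict(), "notes": "simultaneous prediction"},
        {"model": "bifurcated", **bif_metrics["riskenum"].to_dict(), "notes": "simultaneous prediction"},
    ]

    mlp_abs = np.abs(test.riskenum - mlp_model.predict(test.age)["riskenum"])
    bif_abs = np.abs(test.riskenum - bif_model.predict(test.age)["riskenum"])
    wres = wilcoxon_signed_rank(mlp_abs, bif_abs)

    return ComparisonReport(
        rows=rows,
        wilcoxon=wres,
        interpretation=_interpret(wres.p_value),
        n_train=len(train),
        n_test=len(test),
        split_seed=split_seed,
    )


@dataclass(frozen=True)
class StabilityReport:
    """Test-MAE dispersion across retrainings that differ only in model seed.

    ``spread`` is the max-minus-min reading of run-to-run variation; the
    per-output SD is reported alongside because a "plus/minus" bound can
    also be read as a half-spread or an SD.
    """

    per_seed_mae: dict[str, list[float]]
    spread: dict[str, float]
    sd: dict[str, float]
    n_seeds: int
    seeds: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "per_seed_mae": self.per_seed_mae,
            "spread_max_minus_min": self.spread,
            "sd": self.sd,
            "n_seeds": self.n_seeds,
            "seeds": list(self.seeds),
        }


def seed_stability(
    cohort: Cohort,
    config: NetworkConfig | None = None,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    split_seed: int = 0,
) -> StabilityReport:
    """Retrain the bifurcated model once per seed on a fixed cohort and split."""
    if len(seeds) < 2:
        raise ConfigurationError(f"seed_stability needs at least 2 seeds, got {len(seeds)}")
    config = config or NetworkConfig()
    train, test = split_cohort(cohort, config.train_fraction, split_seed)
    maes: dict[str, list[float]] = {"densitanum": [], "riskenum": []}
    for seed in seeds:
        model = train_bifurcated(train, config.replace(seed=int(seed)))
        metrics = model.evaluate(test)
        for name in maes:
            maes[name].append(metrics[name].mae)
    spread = {k: float(max(v) - min(v)) for k, v in maes.items()}
    sd = {k: float(np.std(v, ddof=1)) for k, v in maes.items()}
    return StabilityReport(per_seed_mae=maes, spread=spread, sd=sd, n_seeds=len(seeds), seeds=tuple(int(s) for s in seeds))


def noise_sensitivity(
    base_config: SimulationConfig,
    variance_factor: float,
    net_config: NetworkConfig | None = None,
    split_seed: int = 0,
) -> dict:
    """Regenerate, retrain and evaluate with noise variance scaled by ``variance_factor``.

    The noise SDs scale by sqrt(factor). All seeds are held fixed, so a
    factor of 1.0 reproduces the base run exactly.
    """
    net_config = net_config or NetworkConfig()

    def run(sim_config: SimulationConfig) -> dict[str, dict]:
        cohort = generate_cohort(sim_config)
        train, test = split_cohort(cohort, net_config.train_fraction, split_seed)
        model = train_bifurcated(train, net_config)
        return {name: m.to_dict() for name, m in model.evaluate(test).items()}

    scaled_config = base_config.with_noise_variance_factor(variance_factor)
    return {
        "variance_factor": variance_factor,
        "noise_sd_scale": variance_factor**0.5,
        "base": run(base_config),
        "scaled": run(scaled_config),
    }


def response_surface(
    model: TrainedModel,
    age_grid: np.ndarray,
    age_range: tuple[float, float] = (25.0, 85.0),
) -> pd.DataFrame:
    """Tabulate model predictions over an age grid (descriptive only).

    This samples the learned response surface for inspection and
    plotting; it fits nothing and verifies nothing. Grid points outside
    ``age_range`` are flagged as extrapolation and trigger a warning.
    """
    ages = np.asarray(age_grid, dtype=float).ravel()
    lo, hi = age_range
    outside = (ages < lo) | (ages > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} grid point(s) outside the training age range [{lo}, {hi}]; "
            "predictions there are extrapolation",
            stacklevel=2,
        )
    preds = model.predict(ages)
    frame = pd.DataFrame({"age": ages})
    for name, values in preds.items():
        frame[name] = values
    frame["extrapolated"] = outside
    return frame
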