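"""Synthetic cohort generation and CSV I/O.

The cohort emulates a population-based breast-screening sample: patient age
drawn from a truncated normal distribution, a continuous breast-density
surrogate (``densitanum``) with a parabolic age trend, and a composite
cancer-risk index (``riskenum``) driven by log-age and the realized density.
Density and risk are deliberately abstract surrogates; they map to no
clinical scale (not BI-RADS, not a validated risk score).

Sampling is fully deterministic per master seed: one seed spawns three
independent sub-streams (ages, density noise, risk noise), so changing one
noise SD never perturbs the other draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .config import SimulationConfig
from .exceptions import CohortFormatError, ConfigurationError

COLUMNS = ("age", "densitanum", "riskenum")


@dataclass(frozen=True)
class Cohort:
    """A table of simulated (or loaded) patient records.

    ``data`` holds columns ``age``, ``densitanum``, ``riskenum`` in record
    order. ``provenance`` is the :class:`SimulationConfig` that produced a
    simulated cohort, or ``None`` for cohorts read from external files.
    """

    data: pd.DataFrame
    provenance: SimulationConfig | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortFormatError(f"cohort table missing column(s): {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def age(self) -> np.ndarray:
        return self.data["age"].to_numpy(dtype=float)

    @property
    def densitanum(self) -> np.ndarray:
        return self.data["densitanum"].to_numpy(dtype=float)

    @property
    def riskenum(self) -> np.ndarray:
        return self.data["riskenum"].to_numpy(dtype=float)

    def targets(self) -> np.ndarray:
        """(n, 2) array of (densitanum, riskenum), the two model outputs."""
        return np.column_stack([self.densitanum, self.riskenum])


def sample_truncated_ages(
    n: int,
    mu: float,
    sigma: float,
    lower: float,
    upper: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` ages from a normal law truncated to [lower, upper].

    Uses exact inverse-CDF sampling on the truncated interval: uniforms on
    (Phi(alpha), Phi(beta)) mapped through the normal quantile function.
    Deterministic for a given integer seed.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n!r}")
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be > 0, got {sigma!r}")
    if not lower < upper:
        raise ConfigurationError(f"lower must be strictly below upper, got lower={lower!r}, upper={upper!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = (lower - mu) / sigma
    beta = (upper - mu) / sigma
    p_lo, p_hi = ndtr(alpha), ndtr(beta)
    u = rng.uniform(p_lo, p_hi, size=n)
    ages = mu + sigma * ndtri(u)
    # inverse-CDF can land exactly on a bound only through floating error
    return np.clip(ages, lower, upper)


def truncated_normal_mean(mu: float, sigma: float, lower: float, upper: float) -> float:
    """Closed-form mean of the truncated normal: mu + sigma*(phi(a)-phi(b))/Z."""
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi)  # noqa: E731
    z = ndtr(b) - ndtr(a)
    return float(mu + sigma * (phi(a) - phi(b)) / z)


def density_mean(config: SimulationConfig, age: np.ndarray) -> np.ndarray:
    """Deterministic part of the density equation at the given ages."""
    return config.dens_intercept + config.dens_age_coef * age + config.dens_age2_coef * age**2


def risk_mean(config: SimulationConfig, age: np.ndarray, densitanum: np.ndarray) -> np.ndarray:
    """Deterministic part of the risk equation; density enters as realized."""
    return config.risk_intercept + config.risk_logage_coef * np.log(age) + config.risk_density_coef * densitanum


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a cohort under ``config``; bit-identical per master_seed."""
    streams = np.random.SeedSequence(config.master_seed).spawn(3)
    age_rng, dens_rng, risk_rng = (np.random.default_rng(s) for s in streams)

    age = sample_truncated_ages(
        config.n_patients, config.age_mu, config.age_sigma, config.age_min, config.age_max, age_rng
    )
    densitanum = density_mean(config, age) + dens_rng.normal(0.0, config.dens_noise_sd, size=config.n_patients)
    riskenum = risk_mean(config, age, densitanum) + risk_rng.normal(0.0, config.risk_noise_sd, size=config.n_patients)

    frame = pd.DataFrame({"age": age, "densitanum": densitanum, "riskenum": riskenum})
    return Cohort(frame, provenance=config)


def cohort_fingerprint(cohort: Cohort) -> str:
    """Hash of the cohort table; used to verify shared-split preconditions."""
    import hashlib

    arr = np.ascontiguousarray(cohort.data[list(COLUMNS)].to_numpy(dtype=float))
    return hashlib.sha256(arr.tobytes()).hexdigest()


def write_cohort(cohort: Cohort, destination: str | Path | IO[str]) -> None:
    """Write as CSV with header ``age,densitanum,riskenum``, 17 significant digits."""
    cohort.data.loc[:, list(COLUMNS)].to_csv(destination, index=False, float_format="%.17g")


def read_cohort(source: str | Path | IO[str]) -> Cohort:
    """Read a cohort CSV; enforce exact columns and numeric cells."""
    try:
        # round_trip parsing: the default fast parser can be off by 1 ulp
        frame = pd.read_csv(source, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # malformed CSV structure
        raise CohortFormatError(f"unparseable cohort CSV: {exc}") from exc
    missing = [c for c in COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns if c not in COLUMNS]
    if missing or extra:
        raise CohortFormatError(
            f"cohort CSV must have exactly columns {list(COLUMNS)}; missing={missing}, extra={extra}"
        )
    if len(frame) == 0:
        raise CohortFormatError("cohort CSV contains no records")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise CohortFormatError(f"non-numeric cell at data row {row}")
    if numeric.isna().any().any():
        row = int(numeric.isna().any(axis=1).idxmax())
        raise CohortFormatError(f"missing value at data row {row}")
    return Cohort(numeric.astype(float).loc[:, list(COLUMNS)], provenance=None)
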