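"""Linear regression baselines with full OLS inference.

Two descriptive baselines mirror the study's regressions — Model A
(densitanum ~ age + riskenum) and Model B (riskenum ~ age + densitanum) —
and two *generative-form* regressions (density on age + age^2; risk on
log-age + density) serve as the parameter-recovery check of the simulator:
their coefficients and residual SDs estimate the configured generative
values. Estimation is delegated to statsmodels OLS; this module defines the
result contract and the model surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import statsmodels.api as sm

from .exceptions import SingularDesignError
from .simulate import Cohort


@dataclass(frozen=True)
class OLSResult:
    """Coefficients with full inference for one fitted linear model.

    p-values are two-sided from the t distribution with n_obs - n_params
    degrees of freedom; ``f_p_value`` is the p-value of the overall F-test
    against the intercept-only model ("F significance").
    """

    term_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    ci95_lower: np.ndarray
    ci95_upper: np.ndarray
    r_squared: float
    f_statistic: float
    f_p_value: float
    residual_sd: float
    n_obs: int
    n_params: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.term_names.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.term_names.index(term)])

    def to_dict(self) -> dict:
        return {
            "terms": [
                {
                    "term": t,
                    "estimate": float(b),
                    "std_error": float(s),
                    "t": float(tv),
                    "p_value": float(p),
                    "ci95_lower": float(lo),
                    "ci95_upper": float(hi),
                }
                for t, b, s, tv, p, lo, hi in zip(
                    self.term_names,
                    self.coefficients,
                    self.standard_errors,
                    self.t_statistics,
                    self.p_values,
                    self.ci95_lower,
                    self.ci95_upper,
                )
            ],
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "f_p_value": self.f_p_value,
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def summary(self) -> str:
        lines = [
            f"{'term':>12} {'coef':>12} {'se':>10} {'t':>9} {'p':>10} {'[0.025':>10} {'0.975]':>10}",
        ]
        for i, t in enumerate(self.term_names):
            lines.append(
                f"{t:>12} {self.coefficients[i]:>12.6g} {self.standard_errors[i]:>10.4g} "
                f"{self.t_statistics[i]:>9.3f} {self.p_values[i]:>10.3g} "
                f"{self.ci95_lower[i]:>10.4g} {self.ci95_upper[i]:>10.4g}"
            )
        lines.append(
            f"R^2 = {self.r_squared:.4f}   F = {self.f_statistic:.4g} "
            f"(p = {self.f_p_value:.3g})   residual SD = {self.residual_sd:.4f}   n = {self.n_obs}"
        )
        return "\n".join(lines)


def fit_ols(predictor_matrix: np.ndarray, response: np.ndarray, term_names: list[str] | None = None) -> OLSResult:
    """Fit OLS with an intercept added internally.

    ``term_names`` labels the predictor columns (the intercept label is
    prepended). Raises :class:`SingularDesignError` on rank-deficient
    designs and ``ValueError`` on shape or degrees-of-freedom violations.
    """
    X = np.asarray(predictor_matrix, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"predictor matrix has {X.shape[0]} rows but response has {y.shape[0]}")
    design = sm.add_constant(X, has_constant="add")
    n_obs, n_params = design.shape
    if n_obs <= n_params:
        raise ValueError(f"need n_obs > n_params, got n_obs={n_obs}, n_params={n_params}")
    if np.linalg.matrix_rank(design) < n_params:
        raise SingularDesignError(f"design matrix is rank deficient ({n_params} columns)")
    if term_names is None:
        term_names = [f"x{i + 1}" for i in range(X.shape[1])]
    if len(term_names) != X.shape[1]:
        raise ValueError(f"{len(term_names)} term names for {X.shape[1]} predictor columns")

    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    return OLSResult(
        term_names=("intercept", *term_names),
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        t_statistics=np.asarray(res.tvalues),
        p_values=np.asarray(res.pvalues),
        ci95_lower=np.asarray(ci)[:, 0],
        ci95_upper=np.asarray(ci)[:, 1],
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_p_value=float(res.f_pvalue),
        residual_sd=float(np.sqrt(res.mse_resid)),
        n_obs=n_obs,
        n_params=n_params,
    )


def model_a(cohort: Cohort) -> OLSResult:
    """Model A: densitanum ~ age + riskenum."""
    X = np.column_stack([cohort.age, cohort.riskenum])
    return fit_ols(X, cohort.densitanum, ["age", "riskenum"])


def model_b(cohort: Cohort) -> OLSResult:
    """Model B: riskenum ~ age + densitanum."""
    X = np.column_stack([cohort.age, cohort.densitanum])
    return fit_ols(X, cohort.riskenum, ["age", "densitanum"])


def recover_generative_parameters(cohort: Cohort) -> tuple[OLSResult, OLSResult]:
    """Fit the two generative forms; residual SDs estimate the noise SDs.

    Returns (density fit on age + age^2, risk fit on ln(age) + densitanum).
    """
    age = cohort.age
    dens_fit = fit_ols(np.column_stack([age, age**2]), cohort.densitanum, ["age", "age2"])
    risk_fit = fit_ols(
        np.column_stack([np.log(age), cohort.densitanum]), cohort.riskenum, ["log_age", "densitanum"]
    )
    return dens_fit, risk_fit
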