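"""Published reference values, embedded as inert metadata.

The source study reports model-performance numbers whose scale is
mutually inconsistent and incompatible with its own stated generative
equations: under those equations the deterministic age trend alone gives
OLS R^2 near 0.97, and Gaussian target noise of SD 0.35 / 0.25 puts the
irreducible MAE floor near 0.28 / 0.20 — orders of magnitude below the
printed MAEs of 2.624 / 3.731 and MSEs of 9.5-21.7. These printed values
therefore cannot be reproduced by any implementation of the stated
simulation at any sample size. They are kept here purely for side-by-side
display in reports, flagged ``reproducible: False``; nothing in the
package fits, tunes or validates against them.

The external clinical regression ("Cancers 2025", BPE ~ age + density)
is likewise carried only as static reference coefficients.
"""

from __future__ import annotations

import math

#: half-normal mean factor: E|N(0, sigma)| = sigma * sqrt(2/pi)
HALF_NORMAL_FACTOR = math.sqrt(2.0 / math.pi)

#: Reported performance table of the source study (simulated data).
#: All entries are non-reproducible under the stated generative equations.
PUBLISHED_PERFORMANCE = {
    "reproducible": False,
    "note": (
        "Printed values are inconsistent with the stated generative "
        "equations (irreducible MAE floor ~0.279 density / ~0.199 risk); "
        "shown for reference only, excluded from any validation."
    ),
    "linear_regression": {"output": "riskenum", "mse": 10.2, "mae": 3.9, "r_squared": 0.144},
    "mlp": {"output": "riskenum", "mse": 9.558, "mae": 3.1, "r_squared": 0.436},
    "multi_output": {
        "densitanum": {"test_loss": 21.729, "mae": 2.624},
        "riskenum": {"test_loss": 11.420, "mae": 3.731},
    },
    "wilcoxon_p_mlp_vs_multi_output_risk": 0.12,
    "model_a": {"r_squared": 0.144, "age_coef": -0.063, "riskenum_coef": 0.13},
    "model_b": {"r_squared_text": 0.0178, "r_squared_table": 0.140, "age_p_value": 0.51},
}

#: External clinical model reproduced only as static metadata.
CANCERS_2025_CLINICAL_MODEL = {
    "dependent": "BPE",
    "r_squared": 0.144,
    "age_coef": 0.0088,
    "density_coef": 0.4265,
    "age_significant": False,
    "note": "external published model; never fitted or validated here",
}


def irreducible_mae_floor(noise_sd: float) -> float:
    """Minimum achievable expected MAE given Gaussian target noise of SD sigma.

    The best possible predictor (the conditional mean) leaves an error of
    |N(0, sigma)|, whose mean is sigma*sqrt(2/pi).
    """
    return noise_sd * HALF_NORMAL_FACTOR
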