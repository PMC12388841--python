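"""Synthetic full-factorial datasets with known ground truth.

The generator emulates the statistical structure of the extraction
experiment: a 3x3x3 design, a (typically concave) quadratic response
surface on the coded scale, homoscedastic Gaussian replicate noise, and
per-run triplicate summaries (mean, SD, n).  Because the true coefficients
are known, every downstream stage — OLS refitting, stationary-point
analysis, surrogate training, GA search — can be tested by parameter or
optimum recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_FACTORS, Factor, FactorialDataset, full_factorial
from .rsm import build_design_matrix

__all__ = ["QUADRATIC_BETA_TAS", "NOISE_SD_TAS", "GeneratorSpec", "generate", "tas_like"]

#: Coefficients of the quadratic TAS surface fitted to the P. flaccida
#: extraction experiment (coded scale, mmol/L), in the quadratic basis order
#: 1, x1, x2, x3, x1*x2, x1*x3, x2*x3, x1^2, x2^2, x3^2.
QUADRATIC_BETA_TAS: tuple[float, ...] = (
    3.94, -0.082, -0.478, 0.024, 0.064, 0.002, -0.012, -0.401, -0.714, -0.151,
)

#: Replicate-noise SD (mmol/L) matching the residual scale of that fit
#: (R^2 of about 0.99 on the 27 run means).
NOISE_SD_TAS: float = 0.06


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth for one synthetic dataset.

    ``true_beta`` is on the coded scale in the 10-term quadratic basis;
    ``noise_sd`` is the replicate-level Gaussian SD in response units.
    """

    factors: tuple[Factor, ...] = DEFAULT_FACTORS
    true_beta: tuple[float, ...] = QUADRATIC_BETA_TAS
    noise_sd: float = NOISE_SD_TAS
    n_rep: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_beta) != 10:
            raise ValueError("true_beta must have 10 quadratic-basis coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_rep < 1:
            raise ValueError("n_rep must be positive")


def generate(spec: GeneratorSpec) -> FactorialDataset:
    """Draw one dataset: per design point, ``n_rep`` replicates of
    quadratic(true_beta) + N(0, noise_sd^2), summarized as mean/SD/n."""
    rng = np.random.default_rng(spec.seed)
    points = full_factorial(spec.factors)
    coded = np.array([p.coded for p in points])
    X = build_design_matrix(coded, "quadratic")
    truth = X @ np.asarray(spec.true_beta)
    reps = truth[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(points), spec.n_rep))
    frame = pd.DataFrame(
        {f.name: [p.natural[i] for p in points] for i, f in enumerate(spec.factors)}
    )
    frame["response_mean"] = reps.mean(axis=1)
    if spec.n_rep > 1 and spec.noise_sd > 0:
        frame["response_sd"] = reps.std(axis=1, ddof=1)
    else:
        frame["response_sd"] = 0.0
    frame["n_rep"] = spec.n_rep
    return FactorialDataset(tuple(spec.factors), frame)


def tas_like(seed: int = 0) -> FactorialDataset:
    """A dataset statistically resembling the published TAS table: the
    fitted quadratic surface as truth, noise_sd 0.06 mmol/L, triplicates."""
    return generate(GeneratorSpec(seed=seed))
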