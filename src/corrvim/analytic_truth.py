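"""Closed-form population values implied by the linear generating model.

For y = X b + eps with predictor correlation matrix V (unit variances) and
noise SD sigma_eps, the population quantities of the single-predictor
("bivariate") regressions are available in closed form:

    sigma_y^2     = b' V b + sigma_eps^2
    beta_biv[i]   = (V b)[i] / V[i, i]        (slope of y on x_i alone)
    r(x_i, y)     = (V b)[i] / sigma_y

These are what make a correlated proxy look influential marginally: the
bivariate slope of a predictor is the correlation-weighted sum of all the
coefficients it is correlated with, not its own generating coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import GeneratingModel

__all__ = ["TruthTable", "response_sd", "true_bivariate_beta", "true_marginal_correlation", "truth_table"]


def response_sd(model: GeneratingModel) -> float:
    """Population standard deviation of y: sqrt(b' V b + sigma_eps^2)."""
    b, V = model.coefficients, model.correlation
    return float(np.sqrt(b @ V @ b + model.noise_sd**2))


def true_bivariate_beta(model: GeneratingModel) -> np.ndarray:
    """Population slope of y regressed on each predictor alone: (V b) / diag(V)."""
    Vb = model.correlation @ model.coefficients
    return Vb / np.diag(model.correlation)


def true_marginal_correlation(model: GeneratingModel) -> np.ndarray:
    """Population Pearson correlation of each predictor with y: (V b) / sigma_y."""
    Vb = model.correlation @ model.coefficients
    return Vb / response_sd(model)


@dataclass(frozen=True)
class TruthTable:
    """Per-predictor population truths of the bivariate regressions."""

    sigma_y: float
    bivariate_beta: np.ndarray
    marginal_r: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        p = len(self.bivariate_beta)
        return pd.DataFrame(
            {
                "predictor": [f"x{i + 1}" for i in range(p)],
                "true_bivariate_beta": self.bivariate_beta,
                "true_marginal_r": self.marginal_r,
            }
        )


def truth_table(model: GeneratingModel) -> TruthTable:
    return TruthTable(
        sigma_y=response_sd(model),
        bivariate_beta=true_bivariate_beta(model),
        marginal_r=true_marginal_correlation(model),
    )
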