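"""Generating model and simulator for the correlated-predictor design.

The study design has twelve standard-normal predictors.  The first four form
an equi-correlated block (pairwise Pearson r = 0.9); the remaining eight are
mutually independent and independent of the block.  The response is linear
with no intercept,

    y = X b + eps,        eps ~ N(0, sigma_eps^2) i.i.d.,

with coefficient vector b = (5, 5, 2, 0, -5, -5, -2, 0, 0, 0, 0, 0) under the
alternative hypothesis (``HA``).  Under the null (``H0``) every coefficient is
zero while the correlation structure of the predictors is retained.  The
noise scale is parameterised by its standard deviation, default 0.5.

Because x4 carries a zero coefficient but sits inside the correlated block,
its marginal (bivariate) association with y is almost as strong as that of
the truly influential block members — the "spurious correlation" the study
revolves around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HA_COEFFICIENTS",
    "GeneratingModel",
    "SimulatedDataset",
    "block_correlation_matrix",
    "derive_seed",
    "make_generating_model",
    "replicate_seeds",
    "simulate_dataset",
]

#: Generating coefficients under the alternative hypothesis.
HA_COEFFICIENTS = np.array([5.0, 5.0, 2.0, 0.0, -5.0, -5.0, -2.0, 0.0, 0.0, 0.0, 0.0, 0.0])

_PSD_TOL = 1e-10


def derive_seed(master_seed: int, *path: int) -> int:
    """Derive an independent child seed from ``master_seed`` and a counter path.

    Uses :class:`numpy.random.SeedSequence` with the path as extra entropy
    words, so distinct paths give statistically independent streams and any
    (master, path) pair is individually re-runnable.  The result fits in a
    signed 32-bit integer.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, path)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def replicate_seeds(master_seed: int, n_replicates: int) -> list[int]:
    """Per-replicate data seeds: ``derive_seed(master_seed, r)`` for r = 0..n-1."""
    return [derive_seed(master_seed, r) for r in range(n_replicates)]


def block_correlation_matrix(p: int, block_size: int, rho: float) -> np.ndarray:
    """Correlation matrix with one leading equi-correlated block.

    The leading ``block_size`` x ``block_size`` block has ``rho`` in every
    off-diagonal cell; everything else is the identity.  For 0 <= rho < 1 the
    result is positive definite (block eigenvalues 1 + (k-1) rho and 1 - rho).
    """
    if not 1 <= block_size <= p:
        raise ValueError(f"block_size must be in [1, p]; got {block_size} with p={p}")
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1); got {rho}")
    V = np.eye(p)
    V[:block_size, :block_size] = rho
    np.fill_diagonal(V, 1.0)
    return V


@dataclass(frozen=True)
class GeneratingModel:
    """Linear generating model: coefficients, predictor correlation, noise SD."""

    coefficients: np.ndarray
    correlation: np.ndarray
    noise_sd: float
    scenario: str

    def __post_init__(self) -> None:
        b = np.asarray(self.coefficients, dtype=float)
        V = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "coefficients", b)
        object.__setattr__(self, "correlation", V)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("correlation must be a square matrix")
        if b.ndim != 1 or b.shape[0] != V.shape[0]:
            raise ValueError("coefficients length must match correlation dimension")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(V).min() < -_PSD_TOL:
            raise ValueError("correlation matrix must be positive semi-definite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.scenario not in ("HA", "H0"):
            raise ValueError(f"scenario must be 'HA' or 'H0'; got {self.scenario!r}")
        if self.scenario == "H0" and np.any(b != 0.0):
            raise ValueError("H0 scenario requires all coefficients to be exactly 0")

    @property
    def p(self) -> int:
        return self.coefficients.shape[0]


def make_generating_model(
    scenario: str,
    *,
    noise_sd: float = 0.5,
    rho: float = 0.9,
    block_size: int = 4,
) -> GeneratingModel:
    """The study's twelve-predictor generating model for ``HA`` or ``H0``.

    Defaults encode the study conditions: a leading block of four predictors
    equi-correlated at 0.9, noise standard deviation 0.5, and coefficients
    :data:`HA_COEFFICIENTS` (all-zero under ``H0``).
    """
    if scenario == "HA":
        b = HA_COEFFICIENTS.copy()
    elif scenario == "H0":
        b = np.zeros_like(HA_COEFFICIENTS)
    else:
        raise ValueError(f"scenario must be 'HA' or 'H0'; got {scenario!r}")
    V = block_correlation_matrix(len(b), block_size, rho)
    return GeneratingModel(coefficients=b, correlation=V, noise_sd=noise_sd, scenario=scenario)


@dataclass(frozen=True)
class SimulatedDataset:
    """One replicate: design matrix, response, and the seed that produced them."""

    X: np.ndarray
    y: np.ndarray
    seed: int
    model: GeneratingModel = field(repr=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_dataframe(self):
        """Plain tabular export with columns x1..xp, y."""
        import pandas as pd

        p = self.X.shape[1]
        df = pd.DataFrame(self.X, columns=[f"x{i + 1}" for i in range(p)])
        df["y"] = self.y
        return df


def simulate_dataset(model: GeneratingModel, n: int, seed: int) -> SimulatedDataset:
    """Draw one replicate of ``n`` observations from the generating model.

    Predictors are multivariate normal with mean zero and covariance equal to
    the model's correlation matrix (unit variances), drawn via a Cholesky
    factor; the response is ``X b`` plus i.i.d. Gaussian noise with standard
    deviation ``model.noise_sd``.  Identical (model, n, seed) give
    bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        L = np.linalg.cholesky(model.correlation)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite; cannot simulate") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, model.p))
    X = Z @ L.T
    eps = model.noise_sd * rng.standard_normal(n)
    y = X @ model.coefficients + eps
    return SimulatedDataset(X=X, y=y, seed=int(seed), model=model)
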