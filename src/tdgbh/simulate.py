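"""Synthetic z-score / p-value matrices with two-way signal enrichment.

The generator emulates large-scale association testing between n features
(rows; genes, taxa) and m outcomes (columns; cell types, metabolites).
Null cells carry z ~ N(0, 1); a fraction theta of all cells carry signal
z ~ N(mu, sigma^2), confined to an "enriched" sub-rectangle of
ceil(n * p_i) randomly chosen features by ceil(m * p_j) randomly chosen
outcomes.  p_i = 1 gives outcome-wise enrichment, p_j = 1 feature-wise
enrichment, and both < 1 a doubly enriched block.  z-scores are converted
to one-sided p-values p = 1 - Phi(z).

Correlated noise is applied across features within each outcome column
(columns independent): an equicorrelated block structure or an AR(1)
structure with parameter rho.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

__all__ = [
    "Correlation",
    "SimulationScenario",
    "SimulatedDataset",
    "simulate_dataset",
    "scenario_grid",
]


class Correlation(str, enum.Enum):
    INDEPENDENT = "independent"
    BLOCK = "block"
    AR1 = "ar1"


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulation setting.

    Attributes
    ----------
    n, m:
        Feature (row) and outcome (column) counts.
    theta:
        Overall signal density: floor(n * m * theta) cells are nonnull.
    p_i, p_j:
        Fractions of signal-bearing features and outcomes; the nonnull
        cells are placed uniformly at random inside the resulting
        ceil(n*p_i) x ceil(m*p_j) rectangle.
    mu, sigma:
        Mean and standard deviation of the alternative z-score
        distribution N(mu, sigma^2).
    correlation, rho, block_size:
        Noise dependence across features within each outcome column.
    seed, runs:
        Base RNG seed and replication count for benchmark use.
    """

    n: int = 1000
    m: int = 20
    theta: float = 0.05
    p_i: float = 1.0
    p_j: float = 0.2
    mu: float = 2.0
    sigma: float = 1.0
    correlation: Correlation = Correlation.INDEPENDENT
    rho: float = 0.7
    block_size: int = 20
    seed: int = 0
    runs: int = 100
    scenario_id: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "correlation", Correlation(self.correlation))
        if self.n < 2 or self.m < 2:
            raise ValueError("need n >= 2 and m >= 2")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if not 0.0 < self.p_i <= 1.0 or not 0.0 < self.p_j <= 1.0:
            raise ValueError("p_i and p_j must be in (0, 1]")
        if self.correlation is not Correlation.INDEPENDENT and not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if self.correlation is Correlation.BLOCK and self.block_size < 1:
            raise ValueError("block_size must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_signals > self.n_signal_features * self.n_signal_outcomes:
            raise ValueError(
                f"{self.n_signals} signal cells do not fit in the "
                f"{self.n_signal_features} x {self.n_signal_outcomes} "
                "enriched sub-rectangle; lower theta or raise p_i/p_j"
            )

    @property
    def n_signals(self) -> int:
        return math.floor(self.n * self.m * self.theta)

    @property
    def n_signal_features(self) -> int:
        return math.ceil(self.n * self.p_i)

    @property
    def n_signal_outcomes(self) -> int:
        return math.ceil(self.m * self.p_j)

    @property
    def id(self) -> str:
        if self.scenario_id is not None:
            return self.scenario_id
        return (
            f"n{self.n}_m{self.m}_theta{self.theta:g}_pi{self.p_i:g}_"
            f"pj{self.p_j:g}_{Correlation(self.correlation).value}"
        )


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated matrix: z-scores, one-sided p-values and truth mask."""

    z: np.ndarray
    p: np.ndarray
    truth: np.ndarray


def _correlated_noise(
    scenario: SimulationScenario, rng: np.random.Generator
) -> np.ndarray:
    """n x m noise matrix; columns independent, features correlated."""
    n, m = scenario.n, scenario.m
    corr = Correlation(scenario.correlation)
    if corr is Correlation.INDEPENDENT:
        return rng.standard_normal((n, m))
    rho = scenario.rho
    if corr is Correlation.AR1:
        # exact AR(1) recursion: stationary unit-variance chain per column
        eps = np.empty((n, m))
        innov = rng.standard_normal((n, m))
        eps[0] = innov[0]
        scale = math.sqrt(1.0 - rho**2)
        for i in range(1, n):
            eps[i] = rho * eps[i - 1] + scale * innov[i]
        return eps
    # equicorrelated blocks: shared factor construction gives cov rho
    # within block, unit variance, zero across blocks
    n_blocks = math.ceil(n / scenario.block_size)
    factors = rng.standard_normal((n_blocks, m))
    idio = rng.standard_normal((n, m))
    block_of = np.minimum(np.arange(n) // scenario.block_size, n_blocks - 1)
    return math.sqrt(rho) * factors[block_of] + math.sqrt(1.0 - rho) * idio


def simulate_dataset(
    scenario: SimulationScenario,
    seed: Optional[int | np.random.SeedSequence] = None,
) -> SimulatedDataset:
    """Generate one z-score / p-value matrix for a scenario.

    ``seed`` overrides ``scenario.seed``; identical seeds give bit-identical
    datasets.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n, m = scenario.n, scenario.m

    signal_rows = rng.choice(n, size=scenario.n_signal_features, replace=False)
    signal_cols = rng.choice(m, size=scenario.n_signal_outcomes, replace=False)
    n_cells = scenario.n_signal_features * scenario.n_signal_outcomes
    flat = rng.choice(n_cells, size=scenario.n_signals, replace=False)
    truth = np.zeros((n, m), dtype=bool)
    rows = signal_rows[flat // scenario.n_signal_outcomes]
    cols = signal_cols[flat % scenario.n_signal_outcomes]
    truth[rows, cols] = True

    if Correlation(scenario.correlation) is Correlation.INDEPENDENT:
        z = rng.standard_normal((n, m))
        z[truth] = rng.normal(scenario.mu, scenario.sigma, size=scenario.n_signals)
    else:
        z = _correlated_noise(scenario, rng)
        z = z + np.where(truth, scenario.mu, 0.0)
    p = stats.norm.sf(z)
    return SimulatedDataset(z=z, p=p, truth=truth)


# theta grids of the benchmark: outcome-enriched and feature-enriched
# settings share one grid; the doubly enriched setting halves it so the
# signal block is not overfilled.
_THETA_ONEWAY = (0.01, 0.02, 0.05, 0.1)
_THETA_TWOWAY = (0.005, 0.01, 0.02, 0.04)


def scenario_grid(
    n: int = 1000,
    outcome_counts: tuple = (20, 500),
    correlations: tuple = (
        Correlation.INDEPENDENT,
        Correlation.BLOCK,
        Correlation.AR1,
    ),
    include_null: bool = True,
) -> List[SimulationScenario]:
    """The benchmark grid: three enrichment patterns by a theta grid, for
    each outcome count and correlation structure, plus global-null
    scenarios (theta = 0)."""
    grid: List[SimulationScenario] = []
    for m in outcome_counts:
        for corr in correlations:
            tag = Correlation(corr).value
            if include_null:
                grid.append(
                    SimulationScenario(
                        n=n, m=m, theta=0.0, p_i=1.0, p_j=1.0,
                        correlation=corr,
                        scenario_id=f"null_m{m}_{tag}",
                    )
                )
            for theta in _THETA_ONEWAY:
                grid.append(
                    SimulationScenario(
                        n=n, m=m, theta=theta, p_i=1.0, p_j=0.2,
                        correlation=corr,
                        scenario_id=f"outcome_m{m}_theta{theta:g}_{tag}",
                    )
                )
                grid.append(
                    SimulationScenario(
                        n=n, m=m, theta=theta, p_i=0.2, p_j=1.0,
                        correlation=corr,
                        scenario_id=f"feature_m{m}_theta{theta:g}_{tag}",
                    )
                )
            for theta in _THETA_TWOWAY:
                grid.append(
                    SimulationScenario(
                        n=n, m=m, theta=theta, p_i=0.2, p_j=0.2,
                        correlation=corr,
                        scenario_id=f"both_m{m}_theta{theta:g}_{tag}",
                    )
                )
    return grid
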