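"""Two-dimensional group Benjamini-Hochberg (2dGBH) procedure.

The procedure adjusts an n x m matrix of p-values whose rows are features
(genes, taxa, ...) and whose columns are outcomes (cell types, metabolites,
...).  Null proportions are estimated globally, per row and per column,
shrunk toward the global estimate, combined per cell through a balance
factor ``R`` that reflects the informativeness of each grouping direction,
turned into weights ``W = (1 - pi0) / pi0``, and the weighted p-values are
finally passed through the classic BH step-up.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Pi0Estimator",
    "CombineMode",
    "Pi0Config",
    "PValueMatrix",
    "Pi0Surface",
    "WeightMatrix",
    "AdjustedResult",
    "estimate_pi0_storey",
    "estimate_pi0_lsl",
    "estimate_pi0_tst",
    "shrink_group_pi0",
    "compute_balance_factor",
    "combine_pi0",
    "compute_weights",
    "weight_pvalues",
    "bh_adjust",
    "two_d_gbh",
]

DEFAULT_PI0_FLOOR = 1e-8


class Pi0Estimator(str, enum.Enum):
    """Null-proportion estimators selectable for the global and group steps."""

    STOREY = "storey"
    LSL = "lsl"
    TST = "tst"


class CombineMode(str, enum.Enum):
    """How the row-wise and column-wise shrunken pi0 estimates are merged."""

    WEIGHTED = "weighted"    # pi0_ij = row^(1-R) * col^R with data-driven R
    GEOMETRIC = "geometric"  # same with R fixed at 0.5
    ARITHMETIC = "arithmetic"  # (row + col) / 2


@dataclass(frozen=True)
class Pi0Config:
    """Tuning knobs of the 2dGBH procedure.

    Parameters
    ----------
    estimator:
        Null-proportion estimator for the global and per-group steps.
    storey_lambda:
        Tail threshold of the Storey estimator, in (0, 1).
    shrinkage:
        Shrinkage factor ``S`` in [0, 1] pulling group estimates toward the
        global one; ``S = 1`` collapses every group to the global estimate.
    combine:
        How the two directions' estimates are merged per cell.
    pi0_floor:
        Lower clip bound for every pi0 estimate; keeps weights finite.
    balance_override:
        If set, use this value for the balance factor ``R`` instead of the
        standard-deviation-based formula (0 uses rows only, 1 columns only).
    """

    estimator: Pi0Estimator = Pi0Estimator.STOREY
    storey_lambda: float = 0.5
    shrinkage: float = 0.1
    combine: CombineMode = CombineMode.WEIGHTED
    pi0_floor: float = DEFAULT_PI0_FLOOR
    balance_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError(f"shrinkage must be in [0, 1], got {self.shrinkage}")
        if not 0.0 < self.storey_lambda < 1.0:
            raise ValueError(
                f"storey_lambda must be in (0, 1), got {self.storey_lambda}"
            )
        if not 0.0 < self.pi0_floor < 1.0:
            raise ValueError(f"pi0_floor must be in (0, 1), got {self.pi0_floor}")
        if self.balance_override is not None and not 0.0 <= self.balance_override <= 1.0:
            raise ValueError(
                f"balance_override must be in [0, 1], got {self.balance_override}"
            )
        # accept plain strings for convenience
        object.__setattr__(self, "estimator", Pi0Estimator(self.estimator))
        object.__setattr__(self, "combine", CombineMode(self.combine))


@dataclass(frozen=True)
class PValueMatrix:
    """An n x m matrix of raw p-values with feature (row) and outcome
    (column) identifiers.

    Both grouping directions must exist (``n >= 2`` and ``m >= 2``) and the
    matrix must be complete: missing entries are rejected because they would
    silently change group sizes and hence every pi0 estimate.
    """

    values: np.ndarray
    feature_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    outcome_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {values.shape}")
        n, m = values.shape
        if n < 2 or m < 2:
            raise ValueError(
                f"need at least 2 features and 2 outcomes, got {n} x {m}"
            )
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite p-value at row {bad[0]}, column {bad[1]}"
            )
        if (values < 0).any() or (values > 1).any():
            bad = np.argwhere((values < 0) | (values > 1))[0]
            raise ValueError(
                f"p-value outside [0, 1] at row {bad[0]}, column {bad[1]}: "
                f"{values[bad[0], bad[1]]}"
            )
        object.__setattr__(self, "values", values)
        feature_ids = self.feature_ids
        outcome_ids = self.outcome_ids
        if feature_ids is None:
            feature_ids = [f"feature_{i}" for i in range(n)]
        if outcome_ids is None:
            outcome_ids = [f"outcome_{j}" for j in range(m)]
        feature_ids = [str(x) for x in feature_ids]
        outcome_ids = [str(x) for x in outcome_ids]
        if len(feature_ids) != n:
            raise ValueError(
                f"{len(feature_ids)} feature ids for {n} rows"
            )
        if len(outcome_ids) != m:
            raise ValueError(
                f"{len(outcome_ids)} outcome ids for {m} columns"
            )
        if len(set(feature_ids)) != n:
            raise ValueError("duplicate feature identifiers")
        if len(set(outcome_ids)) != m:
            raise ValueError("duplicate outcome identifiers")
        object.__setattr__(self, "feature_ids", feature_ids)
        object.__setattr__(self, "outcome_ids", outcome_ids)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Pi0Surface:
    """All intermediate null-proportion quantities of one 2dGBH run."""

    pi0_global: float
    pi0_row_raw: np.ndarray
    pi0_col_raw: np.ndarray
    pi0_row_shrunk: np.ndarray
    pi0_col_shrunk: np.ndarray
    sigma_row: float
    sigma_col: float
    R: float
    pi0_cell: np.ndarray
    pi0_w: float


@dataclass(frozen=True)
class WeightMatrix:
    """Per-cell nonnegative weights ``W = (1 - pi0) / pi0``."""

    W: np.ndarray


@dataclass(frozen=True)
class AdjustedResult:
    """Weighted p-values, their BH adjustment and the rejection mask."""

    p_weighted: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray
    alpha: float

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def _as_pvector(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return p


def estimate_pi0_storey(
    p, lam: float = 0.5, pi0_floor: float = DEFAULT_PI0_FLOOR
) -> float:
    """Storey tail-proportion estimate of the null fraction.

    Counts p-values strictly above the threshold ``lam`` and rescales by the
    tail mass ``1 - lam``; clipped to ``[pi0_floor, 1]``.
    """
    p = _as_pvector(p)
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must be in (0, 1), got {lam}")
    raw = np.count_nonzero(p > lam) / ((1.0 - lam) * p.size)
    return float(min(max(raw, pi0_floor), 1.0))


def estimate_pi0_lsl(p, pi0_floor: float = DEFAULT_PI0_FLOOR) -> float:
    """Least-slope (LSL) estimate of the null fraction.

    With sorted p-values the slope ``l_i = (1 - p_(i)) / (k + 1 - i)`` rises
    through an initial run of small (signal-rich) p-values and drops where
    the flat null tail begins.  The slope just before the first strict
    decrease determines the estimate ``(1 / l + 1) / k``; if the slopes
    never decrease the estimate saturates at 1.
    """
    p = _as_pvector(p)
    k = p.size
    if k == 1:
        return 1.0
    ps = np.sort(p)
    slopes = (1.0 - ps) / (k + 1 - np.arange(1, k + 1))
    decreases = np.flatnonzero(np.diff(slopes) < 0)
    if decreases.size == 0:
        return 1.0
    l = slopes[decreases[0]]  # slope preceding the first decrease
    raw = (1.0 / l + 1.0) / k if l > 0 else 1.0
    return float(min(max(raw, pi0_floor), 1.0))


def estimate_pi0_tst(
    p, alpha: float = 0.05, pi0_floor: float = DEFAULT_PI0_FLOOR
) -> float:
    """Two-stage (TST) estimate: run BH at level ``alpha / (1 + alpha)`` and
    take the fraction of non-rejected hypotheses."""
    p = _as_pvector(p)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = p.size
    stage_level = alpha / (1.0 + alpha)
    r = int(np.count_nonzero(bh_adjust(p) <= stage_level))
    raw = (k - r) / k
    return float(min(max(raw, pi0_floor), 1.0))


_ESTIMATORS = {
    Pi0Estimator.STOREY: "storey",
    Pi0Estimator.LSL: "lsl",
    Pi0Estimator.TST: "tst",
}


def _estimate_pi0(p, config: Pi0Config, alpha: float) -> float:
    est = Pi0Estimator(config.estimator)
    if est is Pi0Estimator.STOREY:
        return estimate_pi0_storey(p, config.storey_lambda, config.pi0_floor)
    if est is Pi0Estimator.LSL:
        return estimate_pi0_lsl(p, config.pi0_floor)
    return estimate_pi0_tst(p, alpha, config.pi0_floor)


def shrink_group_pi0(raw, global_pi0: float, shrinkage: float) -> np.ndarray:
    """Convex combination ``(1 - S) * raw + S * global`` of group and global
    null-proportion estimates."""
    raw = np.asarray(raw, dtype=float)
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError(f"shrinkage must be in [0, 1], got {shrinkage}")
    return (1.0 - shrinkage) * raw + shrinkage * global_pi0


def compute_balance_factor(
    sigma_row: float, sigma_col: float, n: int, m: int
) -> float:
    """Balance factor ``R`` apportioning weight between the two grouping
    directions.

    ``R = (sigma_col / m) / (sigma_row / n + sigma_col / m)`` where
    ``sigma_row`` is the standard deviation of the n row-wise shrunken
    estimates and ``sigma_col`` that of the m column-wise ones.  A direction
    with more spread in its group estimates (more informative grouping) and
    larger groups receives more weight.  When both spreads vanish there is
    no informativeness signal in either direction and 0.5 is returned; the
    choice is inconsequential because both directions then deliver the same
    per-cell estimate.
    """
    if sigma_row < 0 or sigma_col < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n < 2 or m < 2:
        raise ValueError("need at least 2 groups in each direction")
    denom = sigma_row / n + sigma_col / m
    if denom == 0.0:
        return 0.5
    return float((sigma_col / m) / denom)


def combine_pi0(
    row_shrunk,
    col_shrunk,
    R: float,
    mode: CombineMode = CombineMode.WEIGHTED,
    pi0_floor: float = DEFAULT_PI0_FLOOR,
) -> np.ndarray:
    """Per-cell null proportion from the two directions' shrunken estimates.

    ``weighted`` uses the geometric form ``row^(1-R) * col^R``; ``geometric``
    fixes R at 0.5; ``arithmetic`` averages the two.  Entries are clipped to
    ``[pi0_floor, 1]``.
    """
    row = np.asarray(row_shrunk, dtype=float)[:, None]
    col = np.asarray(col_shrunk, dtype=float)[None, :]
    mode = CombineMode(mode)
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"R must be in [0, 1], got {R}")
    if mode is CombineMode.ARITHMETIC:
        cell = (row + col) / 2.0
    else:
        if mode is CombineMode.GEOMETRIC:
            R = 0.5
        cell = row ** (1.0 - R) * col**R
    return np.clip(cell, pi0_floor, 1.0)


def compute_weights(pi0_cell: np.ndarray) -> WeightMatrix:
    """Weights ``W = (1 - pi0) / pi0``; zero exactly where ``pi0 = 1``."""
    pi0_cell = np.asarray(pi0_cell, dtype=float)
    if (pi0_cell <= 0).any() or (pi0_cell > 1).any():
        raise ValueError("pi0 entries must lie in (0, 1]")
    return WeightMatrix(W=(1.0 - pi0_cell) / pi0_cell)


def weight_pvalues(P: np.ndarray, W: np.ndarray, pi0_w: float) -> np.ndarray:
    """Weighted p-values ``P / W * (1 - pi0_w)``.

    Cells with zero weight (a group estimated as pure null) get +inf so the
    subsequent BH step can never reject them.  Values above 1 are left
    untruncated; the step-up never rejects them anyway.
    """
    P = np.asarray(P, dtype=float)
    W = np.asarray(W, dtype=float)
    if P.shape != W.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {W.shape}")
    if not 0.0 < pi0_w <= 1.0:
        raise ValueError(f"pi0_w must be in (0, 1], got {pi0_w}")
    out = np.full(P.shape, np.inf)
    nz = W > 0
    out[nz] = P[nz] / W[nz] * (1.0 - pi0_w)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    Accepts weighted inputs above 1 (and +inf sentinels); adjusted values
    are capped at 1 and mapped back to the input order.  Rejection at level
    alpha is exactly ``adjusted <= alpha``.
    """
    p = np.asarray(p, dtype=float)
    shape = p.shape
    flat = p.ravel()
    if flat.size == 0:
        raise ValueError("empty p-value input")
    if (flat < 0).any() or np.isnan(flat).any():
        raise ValueError("p-values must be nonnegative and non-NaN")
    M = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * M / np.arange(1, M + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(M)
    adjusted[order] = adjusted_sorted
    return adjusted.reshape(shape)


def _groupwise_pi0(values: np.ndarray, axis: int, config: Pi0Config, alpha: float) -> np.ndarray:
    """Null-proportion estimate for every slice along ``axis``
    (axis=0 -> per row, axis=1 -> per column)."""
    est = Pi0Estimator(config.estimator)
    if est is Pi0Estimator.STOREY:
        # vectorised fast path for the default estimator
        other = 1 - axis
        k = values.shape[other]
        raw = np.count_nonzero(values > config.storey_lambda, axis=other) / (
            (1.0 - config.storey_lambda) * k
        )
        return np.clip(raw, config.pi0_floor, 1.0)
    slices = values if axis == 0 else values.T
    return np.array([_estimate_pi0(row, config, alpha) for row in slices])


def two_d_gbh(
    P: PValueMatrix | np.ndarray,
    config: Pi0Config | None = None,
    alpha: float = 0.05,
    return_surface: bool = False,
):
    """Run the full 2dGBH procedure on a feature x outcome p-value matrix.

    Steps: global pi0 estimate on all n*m p-values; per-row and per-column
    estimates; shrinkage toward the global value; balance factor R from the
    sample standard deviations of the two shrunken vectors; per-cell pi0 and
    weights; weighted p-values scaled by ``1 - pi0_w`` with
    ``pi0_w = mean(pi0_cell)``; classic BH on the weighted values.

    Parameters
    ----------
    P:
        Validated :class:`PValueMatrix` or a plain 2-D array.
    config:
        :class:`Pi0Config`; defaults to the standard settings (storey
        estimator, lambda 0.5, shrinkage 0.1, weighted combine).
    alpha:
        Target FDR level for the rejection mask.
    return_surface:
        Also return the :class:`Pi0Surface` diagnostics.

    Returns
    -------
    AdjustedResult, or ``(AdjustedResult, Pi0Surface)`` if requested.
    """
    if not isinstance(P, PValueMatrix):
        P = PValueMatrix(np.asarray(P, dtype=float))
    if config is None:
        config = Pi0Config()
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    values = P.values
    n, m = values.shape

    pi0_global = _estimate_pi0(values.ravel(), config, alpha)
    pi0_row_raw = _groupwise_pi0(values, axis=0, config=config, alpha=alpha)
    pi0_col_raw = _groupwise_pi0(values, axis=1, config=config, alpha=alpha)
    S = config.shrinkage
    pi0_row_shrunk = shrink_group_pi0(pi0_row_raw, pi0_global, S)
    pi0_col_shrunk = shrink_group_pi0(pi0_col_raw, pi0_global, S)
    # reduce over sorted values so the outputs are bit-identical under row
    # or column permutations of the input (no hidden order dependence)
    sigma_row = float(np.std(np.sort(pi0_row_shrunk), ddof=1))
    sigma_col = float(np.std(np.sort(pi0_col_shrunk), ddof=1))
    if config.balance_override is not None:
        R = float(config.balance_override)
    else:
        R = compute_balance_factor(sigma_row, sigma_col, n, m)
    pi0_cell = combine_pi0(
        pi0_row_shrunk, pi0_col_shrunk, R, config.combine, config.pi0_floor
    )
    weights = compute_weights(pi0_cell)
    pi0_w = float(np.mean(np.sort(pi0_cell, axis=None)))
    p_weighted = weight_pvalues(values, weights.W, pi0_w) if pi0_w < 1.0 else np.full(
        values.shape, np.inf
    )
    p_adjusted = bh_adjust(p_weighted)
    rejected = p_adjusted <= alpha
    result = AdjustedResult(
        p_weighted=p_weighted,
        p_adjusted=p_adjusted,
        rejected=rejected,
        alpha=alpha,
    )
    if not return_surface:
        return result
    surface = Pi0Surface(
        pi0_global=pi0_global,
        pi0_row_raw=pi0_row_raw,
        pi0_col_raw=pi0_col_raw,
        pi0_row_shrunk=pi0_row_shrunk,
        pi0_col_shrunk=pi0_col_shrunk,
        sigma_row=sigma_row,
        sigma_col=sigma_col,
        R=R,
        pi0_cell=pi0_cell,
        pi0_w=pi0_w,
    )
    return result, surface
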