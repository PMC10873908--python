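"""Comparator FDR procedures: BH, Storey's q-value, one-way adaptive GBH,
and stratified BH/ST.

These are the standard alternatives a practitioner would apply to a
feature x outcome p-value matrix by pooling all cells or by grouping along
one direction only.  They double as independent cross-checks for the
limiting cases of the two-dimensional procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DEFAULT_PI0_FLOOR,
    Pi0Estimator,
    bh_adjust,
    estimate_pi0_lsl,
    estimate_pi0_storey,
    estimate_pi0_tst,
)

__all__ = [
    "GroupedPValues",
    "storey_qvalue",
    "adaptive_gbh_oneway",
    "stratified_adjust",
]


@dataclass(frozen=True)
class GroupedPValues:
    """A p-value vector with a parallel vector of stratum labels.

    Each cell of a matrix carries either its row or its column identity as
    the label, depending on the chosen grouping direction.
    """

    values: np.ndarray
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        labels = np.asarray(self.group_labels).ravel()
        if values.size == 0:
            raise ValueError("empty p-value vector")
        if values.size != labels.size:
            raise ValueError(
                f"{values.size} p-values but {labels.size} group labels"
            )
        if (values < 0).any() or (values > 1).any() or np.isnan(values).any():
            raise ValueError("p-values must lie in [0, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "group_labels", labels)

    @classmethod
    def from_matrix(cls, P: np.ndarray, by: str) -> "GroupedPValues":
        """Flatten a matrix into grouped p-values, ``by`` 'row' or 'column'."""
        P = np.asarray(P, dtype=float)
        n, m = P.shape
        if by == "row":
            labels = np.repeat(np.arange(n), m)
        elif by == "column":
            labels = np.tile(np.arange(m), n)
        else:
            raise ValueError(f"by must be 'row' or 'column', got {by!r}")
        return cls(values=P.ravel(), group_labels=labels)


def storey_qvalue(
    p, lam: float = 0.5, pi0_floor: float = DEFAULT_PI0_FLOOR
) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimator.

    ``q = bh_adjust(p) * pi0`` capped at 1, with pi0 the tail-proportion
    estimate at threshold ``lam``.  With ``pi0 = 1`` this reduces to plain
    BH.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    pi0 = estimate_pi0_storey(p.ravel(), lam, pi0_floor)
    return np.minimum(bh_adjust(p) * pi0, 1.0)


def _group_pi0(p: np.ndarray, estimator: Pi0Estimator, alpha: float,
               lam: float, pi0_floor: float) -> float:
    estimator = Pi0Estimator(estimator)
    if estimator is Pi0Estimator.STOREY:
        return estimate_pi0_storey(p, lam, pi0_floor)
    if estimator is Pi0Estimator.LSL:
        return estimate_pi0_lsl(p, pi0_floor)
    return estimate_pi0_tst(p, alpha, pi0_floor)


def adaptive_gbh_oneway(
    g: GroupedPValues,
    estimator: Pi0Estimator | str = Pi0Estimator.STOREY,
    alpha: float = 0.05,
    lam: float = 0.5,
    pi0_floor: float = DEFAULT_PI0_FLOOR,
    group_pi0: dict | None = None,
) -> np.ndarray:
    """One-way adaptive group Benjamini-Hochberg adjusted values.

    Estimates a null proportion per group, weights each p-value by
    ``w_g = (1 - pi0_g) / pi0_g``, rescales by ``1 - pi0_overall`` (the
    size-weighted mean of the group estimates) and applies BH to the pooled
    weighted values.  Groups estimated as pure null (``pi0_g = 1``) receive
    adjusted value 1 and are never rejected.

    ``group_pi0`` optionally supplies precomputed per-group estimates
    (label -> pi0), e.g. shrunken ones, bypassing estimation.
    """
    labels = g.group_labels
    values = g.values
    uniq, inverse = np.unique(labels, return_inverse=True)
    pi0_by_group = np.empty(uniq.size)
    for gi, lab in enumerate(uniq):
        if group_pi0 is not None:
            pi0_by_group[gi] = pi0_by_group_val = group_pi0[lab]
            if not 0.0 < pi0_by_group_val <= 1.0:
                raise ValueError(f"supplied pi0 for group {lab!r} not in (0, 1]")
        else:
            members = values[inverse == gi]
            if members.size < 2:
                warnings.warn(
                    f"group {lab!r} has fewer than 2 p-values; "
                    "falling back to the overall pi0 estimate",
                    stacklevel=2,
                )
                pi0_by_group[gi] = np.nan  # filled below
            else:
                pi0_by_group[gi] = _group_pi0(
                    members, estimator, alpha, lam, pi0_floor
                )
    if np.isnan(pi0_by_group).any():
        overall_raw = _group_pi0(values, estimator, alpha, lam, pi0_floor)
        pi0_by_group = np.where(np.isnan(pi0_by_group), overall_raw, pi0_by_group)

    sizes = np.bincount(inverse)
    pi0_overall = float(np.sum(pi0_by_group * sizes) / values.size)
    pi0_cell = pi0_by_group[inverse]
    weights = (1.0 - pi0_cell) / pi0_cell
    weighted = np.full(values.size, np.inf)
    nz = weights > 0
    if pi0_overall < 1.0:
        weighted[nz] = values[nz] / weights[nz] * (1.0 - pi0_overall)
    return bh_adjust(weighted)


def stratified_adjust(
    g: GroupedPValues,
    method: str = "bh",
    lam: float = 0.5,
    pi0_floor: float = DEFAULT_PI0_FLOOR,
) -> np.ndarray:
    """Apply BH or Storey's q-value independently within each stratum.

    Returns per-position adjusted values; the rejection mask at level alpha
    is ``adjusted <= alpha`` assembled across strata.  With a single stratum
    this is identical to the global method.
    """
    if method not in ("bh", "st"):
        raise ValueError(f"method must be 'bh' or 'st', got {method!r}")
    values = g.values
    _, inverse = np.unique(g.group_labels, return_inverse=True)
    adjusted = np.empty(values.size)
    for gi in range(inverse.max() + 1):
        mask = inverse == gi
        sub = values[mask]
        if method == "bh":
            adjusted[mask] = bh_adjust(sub)
        else:
            adjusted[mask] = storey_qvalue(sub, lam, pi0_floor)
    return adjusted
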