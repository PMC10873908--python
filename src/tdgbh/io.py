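"""Reading and writing p-value matrices and adjustment results.

The on-disk format is delimited text (TSV by default, CSV accepted) with a
header row of outcome identifiers and a first column of feature
identifiers.  Values are written with 17 significant digits so adjusted
p-values survive a write/read round trip bit-for-bit.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .core import AdjustedResult, PValueMatrix, Pi0Surface

__all__ = [
    "read_pvalue_matrix",
    "write_pvalue_matrix",
    "write_results",
    "write_surface",
]

_FLOAT_FMT = "%.17g"


def _sniff_delimiter(path: str, delimiter: str) -> str:
    if delimiter in ("\t", ","):
        return delimiter
    if delimiter == "tsv":
        return "\t"
    if delimiter == "csv":
        return ","
    if delimiter != "auto":
        raise ValueError(f"delimiter must be auto/tsv/csv, got {delimiter!r}")
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_pvalue_matrix(path: str, delimiter: str = "auto") -> PValueMatrix:
    """Load and validate a feature x outcome p-value matrix.

    Rows are features, columns outcomes.  Non-numeric or missing cells,
    values outside [0, 1] and duplicate identifiers are each rejected with
    a diagnostic naming the offending cell.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(
            f"matrix in {path} is {df.shape[0]} x {df.shape[1]}; "
            "need at least 2 features and 2 outcomes"
        )
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric or missing p-value at feature {df.index[i]!r}, "
            f"outcome {df.columns[j]!r} in {path}"
        )
    values = body.to_numpy(dtype=float)
    out = np.argwhere((values < 0) | (values > 1))
    if out.size:
        i, j = out[0]
        raise ValueError(
            f"p-value outside [0, 1] at feature {df.index[i]!r}, "
            f"outcome {df.columns[j]!r}: {values[i, j]}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate outcome identifier {dup!r}")
    return PValueMatrix(
        values=values,
        feature_ids=[str(x) for x in df.index],
        outcome_ids=[str(x) for x in df.columns],
    )


def _to_frame(values: np.ndarray, P: PValueMatrix) -> pd.DataFrame:
    return pd.DataFrame(values, index=P.feature_ids, columns=P.outcome_ids)


def write_pvalue_matrix(P: PValueMatrix, path: str, sep: str = "\t") -> None:
    """Write a p-value matrix in the canonical delimited-text layout."""
    _to_frame(P.values, P).to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def write_results(
    result: AdjustedResult,
    P: PValueMatrix,
    path: str,
    long_format: bool = False,
    sep: str = "\t",
) -> None:
    """Write adjusted p-values, matrix-shaped or as a long table.

    The long table has one row per (feature, outcome) cell with the raw,
    weighted and adjusted p-values and the rejection flag.
    """
    if not long_format:
        _to_frame(result.p_adjusted, P).to_csv(path, sep=sep, float_format=_FLOAT_FMT)
        return
    n, m = P.values.shape
    long = pd.DataFrame(
        {
            "feature": np.repeat(P.feature_ids, m),
            "outcome": np.tile(P.outcome_ids, n),
            "p_raw": P.values.ravel(),
            "p_weighted": result.p_weighted.ravel(),
            "p_adjusted": result.p_adjusted.ravel(),
            "rejected": result.rejected.ravel(),
        }
    )
    long.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_surface(
    surface: Pi0Surface, P: PValueMatrix, path: str, sep: str = "\t"
) -> None:
    """Dump the null-proportion diagnostics as a long table.

    Scalars (global pi0, balance factor R, the two sigmas, pi0_w) come
    first, then one row per feature and per outcome with the raw and
    shrunken group estimates.
    """
    rows = [
        {"kind": "scalar", "id": "pi0_global", "raw": surface.pi0_global, "shrunk": ""},
        {"kind": "scalar", "id": "sigma_row", "raw": surface.sigma_row, "shrunk": ""},
        {"kind": "scalar", "id": "sigma_col", "raw": surface.sigma_col, "shrunk": ""},
        {"kind": "scalar", "id": "R", "raw": surface.R, "shrunk": ""},
        {"kind": "scalar", "id": "pi0_w", "raw": surface.pi0_w, "shrunk": ""},
    ]
    for fid, raw, shr in zip(
        P.feature_ids, surface.pi0_row_raw, surface.pi0_row_shrunk
    ):
        rows.append({"kind": "feature", "id": fid, "raw": raw, "shrunk": shr})
    for oid, raw, shr in zip(
        P.outcome_ids, surface.pi0_col_raw, surface.pi0_col_shrunk
    ):
        rows.append({"kind": "outcome", "id": oid, "raw": raw, "shrunk": shr})
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
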