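"""Correspondence analysis of RSCU matrices, from first principles.

Given a non-negative matrix X (rows = species or genes, columns = sense
codons), the analysis forms the correspondence matrix P = X / grand total,
row masses r and column masses c, the standardized residual matrix
S = D_r^(-1/2) (P - r c^T) D_c^(-1/2), and its SVD. Principal coordinates
are the mass-rescaled singular vectors scaled by the singular values; the
squared singular values are the per-axis inertias and are reported as
percentages of the total (the chi-square statistic divided by the grand
total). Stop-codon columns, all-zero columns and all-zero rows are removed
before the decomposition, mirroring standard codon-usage practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_codes_io import GeneticCode
from .rscu_bias import RscuMatrix

logger = logging.getLogger("mitocub")

_RANK_TOL = 1e-12


@dataclass
class CoaResult:
    """Principal coordinates and inertia decomposition of one CA run."""

    row_coords: pd.DataFrame      # rows x axes
    col_coords: pd.DataFrame      # columns x axes
    singular_values: np.ndarray   # non-increasing
    inertia: np.ndarray           # per-axis, = singular_values**2
    total_inertia: float
    dropped_rows: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def inertia_pct(self) -> np.ndarray:
        if self.total_inertia <= 0.0:
            return np.zeros_like(self.inertia)
        return 100.0 * self.inertia / self.total_inertia

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


def correspondence_analysis(
    matrix: RscuMatrix | pd.DataFrame,
    code: GeneticCode | None = None,
    *,
    n_axes: int | None = None,
) -> CoaResult:
    """Run correspondence analysis on an RSCU (or count) matrix.

    Parameters
    ----------
    matrix:
        Non-negative matrix; an :class:`RscuMatrix` contributes its values
        (undefined cells enter as 0, consistent with absent families).
    code:
        When given, stop-codon columns are dropped explicitly (RSCU matrices
        exclude them already by construction).
    n_axes:
        Number of axes to retain; default keeps every axis, i.e.
        min(rows, cols) - 1.

    Degenerate input (rank 0 after centering, e.g. identical rows) returns
    an all-zero-inertia result with a warning rather than raising.
    """
    df = matrix.values if isinstance(matrix, RscuMatrix) else matrix
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("correspondence analysis needs non-negative entries")

    dropped_cols: list[str] = []
    if code is not None:
        stops = [c for c in df.columns if c in code.stop_codons]
        dropped_cols.extend(str(c) for c in stops)
        df = df.drop(columns=stops)
    zero_cols = [c for c in df.columns if df[c].sum() == 0.0]
    dropped_cols.extend(str(c) for c in zero_cols)
    df = df.drop(columns=zero_cols)
    zero_rows = [i for i in df.index if df.loc[i].sum() == 0.0]
    df = df.drop(index=zero_rows)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(
            f"matrix too small after deletions: {df.shape[0]}x{df.shape[1]}"
        )

    X = df.to_numpy()
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    d_r = 1.0 / np.sqrt(r)
    d_c = 1.0 / np.sqrt(c)
    S = d_r[:, None] * (P - np.outer(r, c)) * d_c[None, :]

    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    max_axes = min(df.shape) - 1
    keep = min(n_axes, max_axes) if n_axes is not None else max_axes
    U, sigma, Vt = U[:, :keep], sigma[:keep], Vt[:keep, :]
    total_inertia = float(np.sum((d_r[:, None] * (P - np.outer(r, c))
                                  * d_c[None, :]) ** 2))
    if total_inertia <= _RANK_TOL:
        logger.warning("degenerate matrix: zero total inertia "
                       "(rows proportional to column margins)")
        sigma = np.zeros_like(sigma)
        total_inertia = 0.0

    # principal coordinates: F = D_r^(-1/2) U Sigma, G = D_c^(-1/2) V Sigma
    F = d_r[:, None] * U * sigma[None, :]
    G = d_c[:, None] * Vt.T * sigma[None, :]

    # orient each axis so the largest-magnitude column loading is positive
    for j in range(keep):
        col = G[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            G[:, j] = -col
            F[:, j] = -F[:, j]

    axes = [f"axis{i + 1}" for i in range(keep)]
    return CoaResult(
        row_coords=pd.DataFrame(F, index=df.index, columns=axes),
        col_coords=pd.DataFrame(G, index=df.columns, columns=axes),
        singular_values=sigma,
        inertia=sigma ** 2,
        total_inertia=total_inertia,
        dropped_rows=[str(i) for i in zero_rows],
        dropped_columns=dropped_cols,
    )


def inertia_table(results: dict[str, CoaResult]) -> pd.DataFrame:
    """Per-gene axis-inertia percentages, one row per (gene, axis)."""
    rows = []
    for gene, res in results.items():
        for i, (sv, pct) in enumerate(zip(res.singular_values,
                                          res.inertia_pct), start=1):
            rows.append({"gene": gene, "axis": i,
                         "singular_value": float(sv),
                         "inertia_pct": float(pct)})
    return pd.DataFrame(rows)
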