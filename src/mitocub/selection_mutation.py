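"""Neutrality-plot regression, PR2 bias ratios and composition-ENC correlations.

The neutrality plot regresses GC12 (mean GC at codon positions 1 and 2) on
GC3 across taxa: a slope near 1 means directional mutation pressure moves
all three positions together, a slope near 0 means positions 1-2 are held by
selective constraint while position 3 drifts. The PR2 (parity rule 2) plot
places each gene at (G3/(G3+C3), A3/(A3+T3)); under strand-symmetric
mutation with no selection both ratios sit at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionProfile
from .genetic_codes_io import CodonCounts, GeneticCode

logger = logging.getLogger("mitocub")


@dataclass
class NeutralityFit:
    gene: str
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n_points: int

    @property
    def mutation_pressure_pct(self) -> float:
        """Percentage of directional-mutation effect, 100 x slope."""
        return 100.0 * self.slope


@dataclass
class Pr2Point:
    species: str
    gene: str
    at_bias: float | None  # A3 / (A3 + T3)
    gc_bias: float | None  # G3 / (G3 + C3)

    @property
    def defined(self) -> bool:
        return self.at_bias is not None and self.gc_bias is not None


@dataclass
class CorrelationCell:
    row: str
    col: str
    r: float | None
    p: float | None

    @property
    def stars(self) -> str:
        if self.p is None:
            return ""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""

    @property
    def computable(self) -> bool:
        return self.r is not None


def neutrality_regression(
    profiles: Sequence[CompositionProfile], *, gene: str | None = None
) -> NeutralityFit:
    """OLS of GC12 on GC3 across species for one gene.

    Requires at least 3 points and non-constant GC3. Both axes are on the
    0-100 percentage scale (the slope is scale-invariant when the axes
    share a scale).
    """
    profiles = list(profiles)
    if gene is None:
        genes = {p.gene for p in profiles}
        if len(genes) != 1:
            raise ValueError(f"profiles span several genes: {sorted(genes)}")
        gene = genes.pop()
    if len(profiles) < 3:
        raise ValueError(f"{gene}: need >=3 species points, got {len(profiles)}")
    x = np.array([p.pct_GC3 for p in profiles], dtype=float)
    y = np.array([p.pct_GC12 for p in profiles], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError(f"{gene}: GC3 constant across species; regression degenerate")
    fit = stats.linregress(x, y)
    return NeutralityFit(
        gene=gene, slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), r2=float(fit.rvalue) ** 2,
        p=float(fit.pvalue), n_points=len(profiles),
    )


def pr2_bias(profile: CompositionProfile) -> Pr2Point:
    """PR2 ratios from third-position composition of all sense codons."""
    a3t3 = profile.pct_A3 + profile.pct_T3
    g3c3 = profile.pct_G3 + profile.pct_C3
    at = profile.pct_A3 / a3t3 if a3t3 > 0 else None
    gc = profile.pct_G3 / g3c3 if g3c3 > 0 else None
    if at is None or gc is None:
        logger.warning("%s|%s: PR2 ratio undefined (zero denominator)",
                       profile.species, profile.gene)
    return Pr2Point(species=profile.species, gene=profile.gene,
                    at_bias=at, gc_bias=gc)


def pr2_bias_fourfold(
    counts: CodonCounts, code: GeneticCode, *,
    species: str = "", gene: str = "",
) -> Pr2Point:
    """Classical PR2 variant restricted to fourfold-degenerate families.

    Offered as an option; the default `pr2_bias` uses third positions of all
    sense codons, matching how A3/T3/G3/C3 are defined for composition.
    """
    third = {b: 0 for b in "ACGT"}
    for fam in code.families:
        if fam.degeneracy != 4:
            continue
        for codon in fam.codons:
            third[codon[2]] += counts[codon]
    a3t3 = third["A"] + third["T"]
    g3c3 = third["G"] + third["C"]
    return Pr2Point(
        species=species, gene=gene,
        at_bias=third["A"] / a3t3 if a3t3 > 0 else None,
        gc_bias=third["G"] / g3c3 if g3c3 > 0 else None,
    )


ROW_VARIABLES = ("A%", "T%", "G%", "C%", "GC%", "ENC")
COL_VARIABLES = ("A3%", "T3%", "G3%", "C3%", "GC3%")


def correlation_matrix(
    profiles: Sequence[CompositionProfile],
    enc_values: Sequence[float],
) -> list[CorrelationCell]:
    """Pearson correlations of overall composition and ENC against
    third-position composition, across species for one gene.

    Cells whose inputs have zero variance are returned non-computable
    (rendered "NO" by the writers). With the study's five species per gene
    the p-values rest on n = 5; a log warning notes the small sample.
    """
    profiles = list(profiles)
    n = len(profiles)
    if n < 3:
        raise ValueError(f"need >=3 species, got {n}")
    if len(enc_values) != n:
        raise ValueError("ENC vector length must match profiles")
    if n < 8:
        logger.warning("correlation matrix on n=%d points; p-values are weak", n)
    series: dict[str, np.ndarray] = {
        "A%": np.array([p.pct_A for p in profiles]),
        "T%": np.array([p.pct_T for p in profiles]),
        "G%": np.array([p.pct_G for p in profiles]),
        "C%": np.array([p.pct_C for p in profiles]),
        "GC%": np.array([p.pct_GC for p in profiles]),
        "ENC": np.asarray(enc_values, dtype=float),
        "A3%": np.array([p.pct_A3 for p in profiles]),
        "T3%": np.array([p.pct_T3 for p in profiles]),
        "G3%": np.array([p.pct_G3 for p in profiles]),
        "C3%": np.array([p.pct_C3 for p in profiles]),
        "GC3%": np.array([p.pct_GC3 for p in profiles]),
    }
    cells: list[CorrelationCell] = []
    for row in ROW_VARIABLES:
        for col in COL_VARIABLES:
            x, y = series[row], series[col]
            if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                cells.append(CorrelationCell(row, col, None, None))
                continue
            r, p = stats.pearsonr(x, y)
            cells.append(CorrelationCell(row, col, float(r), float(p)))
    return cells


def correlation_table(
    cells: Iterable[CorrelationCell], *, decimals: int = 3, annotate: bool = True
) -> pd.DataFrame:
    """Correlation grid as a DataFrame (rows x third-position columns)."""
    grid: dict[str, dict[str, str]] = {}
    for cell in cells:
        if cell.r is None:
            text = "NO"
        else:
            text = f"{cell.r:.{decimals}f}"
            if annotate:
                text += cell.stars
        grid.setdefault(cell.row, {})[cell.col] = text
    return pd.DataFrame(grid).T.reindex(
        index=[r for r in ROW_VARIABLES if r in grid], columns=list(COL_VARIABLES)
    )


def neutrality_table(fits: Iterable[NeutralityFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": f.gene, "slope": f.slope, "intercept": f.intercept,
        "r": f.r, "r2": f.r2, "p": f.p, "n": f.n_points,
        "mutation_pressure_pct": f.mutation_pressure_pct,
    } for f in fits])


def pr2_table(points: Iterable[Pr2Point]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": p.species, "gene": p.gene,
        "gc_bias": p.gc_bias, "at_bias": p.at_bias,
    } for p in points])
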