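"""Relative synonymous codon usage (RSCU) and codon-preference summaries.

RSCU for codon j of a synonymous family with degeneracy n_i is
``n_i * X_j / sum_j X_j``: the observed count relative to the count expected
under uniform synonymous usage. Within any expressed family the values sum
to the degeneracy. Classification follows the conventional thresholds:
over-represented above 1.6, under-represented below 0.6, with RSCU = 1
treated as bias-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .genetic_codes_io import CodonCounts, GeneticCode

RSCU_OVER = 1.6
RSCU_UNDER = 0.6
_UNBIASED_TOL = 1e-9


@dataclass
class RscuEntry:
    codon: str
    amino_acid: str
    count: int
    rscu: float
    category: str  # over | high | unbiased | low | under
    defined: bool  # False when the whole family is absent


def _classify(rscu: float) -> str:
    if abs(rscu - 1.0) <= _UNBIASED_TOL:
        return "unbiased"
    if rscu > RSCU_OVER:
        return "over"
    if rscu > 1.0:
        return "high"
    if rscu >= RSCU_UNDER:
        return "low"
    return "under"


def compute_rscu(counts: CodonCounts, code: GeneticCode) -> list[RscuEntry]:
    """Per-codon RSCU over all sense codons of the code.

    Families absent from the counts yield ``defined=False`` entries with
    RSCU 0, so every sense codon always appears exactly once in the output.
    """
    out: list[RscuEntry] = []
    for fam in code.families:
        family_total = sum(counts[c] for c in fam.codons)
        for codon in fam.codons:
            x = counts[codon]
            if family_total == 0:
                out.append(RscuEntry(codon, fam.amino_acid, 0, 0.0,
                                     "under", False))
            else:
                rscu = fam.degeneracy * x / family_total
                out.append(RscuEntry(codon, fam.amino_acid, x, rscu,
                                     _classify(rscu), True))
    return out


def preferred_codon_summary(entries: Iterable[RscuEntry]) -> dict[str, int]:
    """Count over-represented (RSCU > 1.6) and high-bias (1 < RSCU <= 1.6)
    codons; their sum is the number of preferred codons."""
    n_over = n_high = 0
    for e in entries:
        if not e.defined:
            continue
        if e.category == "over":
            n_over += 1
        elif e.category == "high":
            n_high += 1
    return {"n_over": n_over, "n_high": n_high,
            "n_preferred": n_over + n_high}


def amino_acid_frequencies(
    counts: CodonCounts, code: GeneticCode
) -> pd.Series:
    """Relative usage frequency of each amino acid (sums to 1)."""
    if counts.total_codons == 0:
        raise ValueError("no codons counted")
    freqs = {
        fam.amino_acid: sum(counts[c] for c in fam.codons) / counts.total_codons
        for fam in code.families
    }
    return pd.Series(freqs).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# RSCU matrices and heatmap ordering
# ---------------------------------------------------------------------------

@dataclass
class RscuMatrix:
    """Rows = analysis units (genes or species-gene pairs), columns = sense
    codons, cells = RSCU. ``undefined`` marks cells whose family was absent
    (stored as 0 in ``values``)."""

    values: pd.DataFrame
    undefined: pd.DataFrame

    @property
    def row_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def codons(self) -> list[str]:
        return list(self.values.columns)


def rscu_matrix(
    counts_by_unit: Mapping[str, CodonCounts], code: GeneticCode
) -> RscuMatrix:
    """Assemble an RSCU matrix from per-unit codon counts (stops excluded)."""
    codons = list(code.sense_codons)
    vals, mask = {}, {}
    for unit, counts in counts_by_unit.items():
        entries = {e.codon: e for e in compute_rscu(counts, code)}
        vals[unit] = [entries[c].rscu for c in codons]
        mask[unit] = [not entries[c].defined for c in codons]
    values = pd.DataFrame.from_dict(vals, orient="index", columns=codons)
    undefined = pd.DataFrame.from_dict(mask, orient="index", columns=codons)
    return RscuMatrix(values=values, undefined=undefined)


def hierarchical_cluster_order(
    matrix: RscuMatrix,
    metric: str = "euclidean",
    linkage: str = "average",
) -> tuple[list[int], list[int]]:
    """Leaf orderings of rows and columns for an RSCU clustering heatmap.

    Undefined cells are imputed as 0 for distance computation. Deterministic
    for fixed input (scipy's linkage with its default tie-breaking).
    """
    values = matrix.values.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")

    def order(data: np.ndarray) -> list[int]:
        if data.shape[0] < 2:
            return [0]
        dist = pdist(data, metric=metric)
        return [int(i) for i in leaves_list(scipy_linkage(dist, method=linkage))]

    return order(values), order(values.T)


def rscu_long_table(
    entries_by_unit: Mapping[str, Sequence[RscuEntry]]
) -> pd.DataFrame:
    """Long-format RSCU table: one row per (unit, codon)."""
    rows = []
    for unit, entries in entries_by_unit.items():
        for e in entries:
            rows.append({
                "unit": unit, "codon": e.codon, "amino_acid": e.amino_acid,
                "count": e.count, "rscu": e.rscu, "category": e.category,
                "defined": e.defined,
            })
    return pd.DataFrame(rows)
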