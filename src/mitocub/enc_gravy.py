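"""Effective number of codons (Wright's Nc) and GRAVY hydropathy.

Nc generalizes Wright's statistic to any synonymous-family structure: the
codon homozygosity of a family with degeneracy k and n observations is
``F = (n * sum p_i^2 - 1) / (n - 1)``, class means F-bar_k are taken over
expressed families of each degeneracy, and ``Nc = S1 + sum_k N_k / F-bar_k``
where N_k is the code's number of k-fold families and S1 its number of
single-codon families. The result is clamped to the code's sense-codon
count, so the attainable range for the invertebrate mitochondrial code is
20 (one codon per amino acid) to 62 (uniform usage) rather than the 20-61
of the standard code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .genetic_codes_io import CodonCounts, GeneticCode

#: Kyte-Doolittle hydropathy index per amino acid (Ile 4.5 ... Arg -4.5).
KYTE_DOOLITTLE: dict[str, float] = dict(_KYTE_DOOLITTLE)


@dataclass
class EncResult:
    species: str
    gene: str
    nc: float
    #: degeneracy class -> mean homozygosity F-bar_k (imputed classes included)
    family_homozygosities: dict[int, float]
    #: classes with no computable family, imputed at the neutral value 1/k
    imputed_classes: list[int] = field(default_factory=list)
    n_families_skipped: int = 0


@dataclass
class GravyResult:
    species: str
    gene: str
    gravy: float
    length: int

    @property
    def character(self) -> str:
        return "hydrophobic" if self.gravy > 0 else "hydrophilic"


def effective_number_of_codons(
    counts: CodonCounts,
    code: GeneticCode,
    *,
    species: str = "",
    gene: str = "",
) -> EncResult:
    """Wright's effective number of codons for one codon count vector.

    Families with fewer than 2 observations, or with a non-positive
    homozygosity estimate, are excluded from their class mean and counted in
    ``n_families_skipped``. A degeneracy class with no usable family at all
    is imputed at the neutral homozygosity 1/k and flagged, which keeps Nc
    defined for short genes.
    """
    f_by_class: dict[int, list[float]] = {}
    n_skipped = 0
    any_computed = False
    for fam in code.families:
        if fam.degeneracy == 1:
            continue
        n = sum(counts[c] for c in fam.codons)
        if n < 2:
            n_skipped += 1
            continue
        sum_p2 = sum((counts[c] / n) ** 2 for c in fam.codons)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f <= 0.0:
            n_skipped += 1
            continue
        f_by_class.setdefault(fam.degeneracy, []).append(f)
        any_computed = True
    if not any_computed:
        raise ValueError(
            f"{species}|{gene}: no synonymous family with >=2 observations; "
            "Nc undefined"
        )
    by_deg = code.families_by_degeneracy()
    nc = float(len(by_deg.get(1, ())))  # single-codon families count directly
    f_bars: dict[int, float] = {}
    imputed: list[int] = []
    for k, fams in by_deg.items():
        if k == 1:
            continue
        fs = f_by_class.get(k)
        if fs:
            f_bar = sum(fs) / len(fs)
        else:
            f_bar = 1.0 / k
            imputed.append(k)
        f_bars[k] = f_bar
        nc += len(fams) / f_bar
    nc = min(nc, float(code.n_sense_codons))
    return EncResult(
        species=species, gene=gene, nc=nc,
        family_homozygosities=f_bars,
        imputed_classes=imputed,
        n_families_skipped=n_skipped,
    )


def gravy(
    counts: CodonCounts,
    code: GeneticCode,
    scale: dict[str, float] | None = None,
    *,
    species: str = "",
    gene: str = "",
) -> GravyResult:
    """Grand average of hydropathy from codon counts.

    GRAVY is the frequency-weighted mean Kyte-Doolittle index over the
    translated residues; it depends only on the amino-acid composition, so
    it is invariant to synonymous codon reshuffling. Positive values read as
    hydrophobic, negative as hydrophilic.
    """
    if counts.total_codons == 0:
        raise ValueError(f"{species}|{gene}: no residues, GRAVY undefined")
    scale = scale or KYTE_DOOLITTLE
    total = 0.0
    for fam in code.families:
        n = sum(counts[c] for c in fam.codons)
        total += n * scale[fam.amino_acid]
    return GravyResult(
        species=species, gene=gene,
        gravy=total / counts.total_codons,
        length=counts.total_codons,
    )


def gravy_protein(protein: str, scale: dict[str, float] | None = None) -> float:
    """GRAVY of a plain protein string (no stops)."""
    if not protein:
        raise ValueError("empty protein")
    scale = scale or KYTE_DOOLITTLE
    return sum(scale[aa] for aa in protein) / len(protein)
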