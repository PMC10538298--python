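"""Genetic-code registry and coding-sequence ingestion.

Codon tables come from Biopython's NCBI registry; the synonymous-family
(degeneracy) structure is derived programmatically from the codon->amino-acid
map, never hard-coded per table. Mitochondrial CDS records frequently end in
truncated stop codons (``T``/``TA`` completed by polyadenylation), so
ingestion normalizes every sequence to a stop-free, in-frame codon string
before any statistic is computed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("mitocub")

BASES = "TCAG"
ALL_CODONS: tuple[str, ...] = tuple(
    b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES
)

#: The 13 mitochondrial protein-coding genes, in conventional order.
MITO_PCGS: tuple[str, ...] = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)

_GENE_SYNONYMS: dict[str, str] = {
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATP SYNTHASE F0 SUBUNIT 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATP SYNTHASE F0 SUBUNIT 8": "ATP8",
    "COX1": "COX1", "CO1": "COX1", "COI": "COX1", "COX-1": "COX1",
    "CYTOCHROME C OXIDASE SUBUNIT 1": "COX1",
    "CYTOCHROME C OXIDASE SUBUNIT I": "COX1",
    "COX2": "COX2", "CO2": "COX2", "COII": "COX2",
    "CYTOCHROME C OXIDASE SUBUNIT 2": "COX2",
    "CYTOCHROME C OXIDASE SUBUNIT II": "COX2",
    "COX3": "COX3", "CO3": "COX3", "COIII": "COX3",
    "CYTOCHROME C OXIDASE SUBUNIT 3": "COX3",
    "CYTOCHROME C OXIDASE SUBUNIT III": "COX3",
    "CYTB": "CYTB", "COB": "CYTB", "CYTOCHROME B": "CYTB",
    "ND1": "ND1", "NAD1": "ND1", "NADH DEHYDROGENASE SUBUNIT 1": "ND1",
    "ND2": "ND2", "NAD2": "ND2", "NADH DEHYDROGENASE SUBUNIT 2": "ND2",
    "ND3": "ND3", "NAD3": "ND3", "NADH DEHYDROGENASE SUBUNIT 3": "ND3",
    "ND4": "ND4", "NAD4": "ND4", "NADH DEHYDROGENASE SUBUNIT 4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L",
    "NADH DEHYDROGENASE SUBUNIT 4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5", "NADH DEHYDROGENASE SUBUNIT 5": "ND5",
    "ND6": "ND6", "NAD6": "ND6", "NADH DEHYDROGENASE SUBUNIT 6": "ND6",
}


class UnsupportedCodeError(ValueError):
    """Raised for a translation-table id absent from the NCBI registry."""


class CdsValidationError(ValueError):
    """Raised when a CDS violates the alphabet or reading-frame contract."""


def canonical_gene_name(label: str) -> str | None:
    """Map a gene/product qualifier to one of the 13 PCG names, or ``None``."""
    return _GENE_SYNONYMS.get(label.strip().upper().replace("_", ""))


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynonymousFamily:
    """One amino acid's codon family under a given genetic code."""

    amino_acid: str
    codons: tuple[str, ...]

    @property
    def degeneracy(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class GeneticCode:
    """A complete codon -> amino-acid map with its degeneracy structure.

    Attributes
    ----------
    table_id:
        NCBI translation table number (e.g. 5 = invertebrate mitochondrial).
    codon_to_aa:
        Maps each of the 64 DNA codons to a one-letter amino acid or ``"*"``.
    stop_codons:
        The stop codons of the table.
    families:
        One :class:`SynonymousFamily` per amino acid; together the families
        partition the sense codons exactly.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    families: tuple[SynonymousFamily, ...]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    @property
    def n_sense_codons(self) -> int:
        return 64 - len(self.stop_codons)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(f.amino_acid for f in self.families)

    def family_of(self, amino_acid: str) -> SynonymousFamily:
        for fam in self.families:
            if fam.amino_acid == amino_acid:
                return fam
        raise KeyError(amino_acid)

    def families_by_degeneracy(self) -> dict[int, tuple[SynonymousFamily, ...]]:
        out: dict[int, list[SynonymousFamily]] = {}
        for fam in self.families:
            out.setdefault(fam.degeneracy, []).append(fam)
        return {k: tuple(v) for k, v in sorted(out.items())}

    def translate(self, nucleotides: str) -> str:
        """Translate an in-frame DNA string; stops render as ``*``."""
        return "".join(
            self.codon_to_aa[nucleotides[i:i + 3]]
            for i in range(0, len(nucleotides) - len(nucleotides) % 3, 3)
        )


def get_genetic_code(table_id: int) -> GeneticCode:
    """Return the :class:`GeneticCode` for an NCBI translation table.

    The synonymous families are rebuilt from the codon map each call, so any
    table Biopython knows (1, 2, 5, ...) is supported uniformly.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise UnsupportedCodeError(
            f"unknown NCBI translation table id {table_id!r}"
        ) from exc
    codon_to_aa = {c: "*" for c in table.stop_codons}
    codon_to_aa.update(table.forward_table)
    by_aa: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = codon_to_aa[codon]
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    families = tuple(
        SynonymousFamily(aa, tuple(codons)) for aa, codons in sorted(by_aa.items())
    )
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(table.stop_codons),
        families=families,
    )


# ---------------------------------------------------------------------------
# Coding sequences
# ---------------------------------------------------------------------------

@dataclass
class CodingSequence:
    """One protein-coding sequence, normalized to a stop-free codon string."""

    species: str
    gene: str
    nucleotides: str
    code_table: int = 5
    #: True when the gene label could not be mapped to one of the 13 PCGs.
    free_label: bool = False

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> list[str]:
        return [self.nucleotides[i:i + 3] for i in range(0, len(self.nucleotides), 3)]

    def code(self) -> GeneticCode:
        return get_genetic_code(self.code_table)

    def translate(self) -> str:
        return self.code().translate(self.nucleotides)


@dataclass
class CodonCounts:
    """Codon counts over the 64 slots for one (or several pooled) CDS."""

    counts: dict[str, int]
    total_codons: int = field(init=False)

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] = int(n)
        self.counts = full
        self.total_codons = sum(full.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(
            {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        )

    def scale(self, factor: int) -> "CodonCounts":
        if factor <= 0:
            raise ValueError("scale factor must be a positive integer")
        return CodonCounts({c: n * factor for c, n in self.counts.items()})


def normalize_cds(
    raw: str, code: GeneticCode, *, context: str = "<cds>"
) -> str:
    """Apply ingestion normalization and validate a CDS.

    Uppercases, maps U->T, rejects ambiguity codes, drops a trailing partial
    codon (truncated mitochondrial stop), then drops a terminal complete stop
    codon. Raises :class:`CdsValidationError` on internal stops, reporting the
    1-based codon position.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise CdsValidationError(
            f"{context}: non-ACGT symbol(s) {sorted(bad)} in CDS"
        )
    if not seq:
        raise CdsValidationError(f"{context}: empty CDS")
    overhang = len(seq) % 3
    if overhang:
        logger.warning(
            "%s: dropping %d-base partial terminal codon %r (truncated stop)",
            context, overhang, seq[-overhang:],
        )
        seq = seq[: len(seq) - overhang]
    if len(seq) >= 3 and seq[-3:] in code.stop_codons:
        seq = seq[:-3]
    if not seq:
        raise CdsValidationError(f"{context}: CDS empty after stop trimming")
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in code.stop_codons:
            raise CdsValidationError(
                f"{context}: internal stop codon {codon} at codon "
                f"position {i // 3 + 1}"
            )
    return seq


def count_codons(cds: CodingSequence, code: GeneticCode) -> CodonCounts:
    """Count every in-frame codon of a CDS, excluding a terminal stop."""
    seq = cds.nucleotides
    n_whole = len(seq) // 3
    codons = [seq[i * 3:i * 3 + 3] for i in range(n_whole)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    for idx, codon in enumerate(codons):
        if codon in code.stop_codons:
            raise CdsValidationError(
                f"{cds.species}|{cds.gene}: internal stop codon {codon} at "
                f"codon position {idx + 1}"
            )
    return CodonCounts(dict(Counter(codons)))


def pool_counts(counts: Iterable[CodonCounts]) -> CodonCounts:
    """Slot-wise sum of several codon count vectors."""
    total = CodonCounts({})
    for c in counts:
        total = total + c
    if total.total_codons == 0:
        raise ValueError("no codons to pool")
    return total


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_cds(
    path: str | Path,
    format: str = "fasta",
    *,
    code_table: int = 5,
    header_sep: str = "|",
) -> list[CodingSequence]:
    """Load CDS records from a FASTA or GenBank flatfile.

    FASTA headers use the ``species<sep>gene`` dialect (configurable
    separator). GenBank records contribute one CDS per annotated CDS feature;
    the species comes from the organism annotation and the gene from the
    ``/gene`` or ``/product`` qualifier, mapped to the 13 canonical PCG names
    where possible. Unknown gene labels are kept but flagged
    (``free_label=True``).
    """
    path = Path(path)
    code = get_genetic_code(code_table)
    out: list[CodingSequence] = []
    if format == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            header = record.description or record.id
            if header_sep in header:
                species, gene = header.split(header_sep, 1)
                species, gene = species.strip(), gene.strip().split()[0]
            else:
                species, gene = record.id, ""
            canonical = canonical_gene_name(gene) if gene else None
            free = canonical is None
            if free:
                logger.warning(
                    "%s: gene label %r not one of the 13 PCGs; kept as free label",
                    path.name, gene,
                )
            seq = normalize_cds(
                str(record.seq), code, context=f"{species}|{gene or record.id}"
            )
            out.append(CodingSequence(
                species=species, gene=canonical or gene or record.id,
                nucleotides=seq, code_table=code_table, free_label=free,
            ))
    elif format == "genbank":
        for record in SeqIO.parse(str(path), "genbank"):
            species = record.annotations.get("organism", record.id)
            for feature in record.features:
                if feature.type != "CDS":
                    continue
                label = (feature.qualifiers.get("gene")
                         or feature.qualifiers.get("product") or ["?"])[0]
                canonical = canonical_gene_name(label)
                free = canonical is None
                if free:
                    logger.warning(
                        "%s: CDS label %r not one of the 13 PCGs; kept as "
                        "free label", record.id, label,
                    )
                raw = str(feature.extract(record.seq))
                seq = normalize_cds(raw, code, context=f"{species}|{label}")
                out.append(CodingSequence(
                    species=species, gene=canonical or label,
                    nucleotides=seq, code_table=code_table, free_label=free,
                ))
    else:
        raise ValueError(f"unsupported format {format!r} (use fasta or genbank)")
    if not out:
        raise CdsValidationError(f"{path}: no CDS records found")
    return out


def write_fasta(
    records: Sequence[CodingSequence],
    path: str | Path,
    *,
    header_sep: str = "|",
    width: int = 70,
) -> None:
    """Write CDS records as plain FASTA with ``species<sep>gene`` headers."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.species}{header_sep}{rec.gene}\n")
            for i in range(0, len(rec.nucleotides), width):
                fh.write(rec.nucleotides[i:i + width] + "\n")
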