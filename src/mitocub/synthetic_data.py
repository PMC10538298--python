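"""Synthetic multi-species CDS sets with controlled mutation-selection structure.

The generator draws each codon independently from a closed-form distribution
built in two stages:

1. the first two codon bases are sampled i.i.d. with G/C probability
   ``theta12`` (= ``theta_gc3`` in ``linked`` mode, pinned at 0.45 in
   ``fixed`` mode, each split equally between G and C);
2. given the two-base prefix, a sense codon is chosen with weight
   ``aa_freqs[aa] * m(b3) * exp(selection_s * [b3 in {A,T}])`` where the
   mutational third-base weight ``m`` places probability ``theta_gc3`` on
   G/C (split equally) and the exponential term is the AT-ending selective
   preference.

Because every statistic downstream is a function of the codon distribution,
the model admits exact expectations (``expected_codon_distribution``,
``expected_rscu``, ``expected_gc3_pct``) against which simulated data can be
checked with binomial/multinomial error bounds. ``linked`` mode makes GC12
track ``theta_gc3`` exactly (slope-1 regime of the neutrality plot);
``fixed`` mode holds GC12 at 0.45 while GC3 still follows ``theta_gc3``
(selection-dominated, slope-0 regime). Amino-acid weights act within
two-base prefix blocks, so the realized amino-acid composition is shaped by,
but not identical to, ``aa_freqs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .genetic_codes_io import (
    BASES,
    CodingSequence,
    GeneticCode,
    get_genetic_code,
)

#: 13 mito PCGs with realistic codon counts (short ATP8, long ND5).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ATP6": 226, "ATP8": 53, "COX1": 511, "COX2": 226, "COX3": 261,
    "CYTB": 378, "ND1": 308, "ND2": 324, "ND3": 117, "ND4": 444,
    "ND4L": 95, "ND5": 562, "ND6": 165,
}

#: Mito-protein-like amino-acid weights: Leu/Ile/Met/Ser/Phe enriched.
DEFAULT_AA_FREQS: dict[str, float] = {
    "L": 0.15, "I": 0.12, "S": 0.10, "M": 0.08, "F": 0.08,
    **{aa: 0.47 / 15 for aa in "ACDEGHKNPQRTVWY"},
}

_FIXED_GC12 = 0.45


@dataclass
class SynthSpec:
    """Parameters of one synthetic CDS-set generation run.

    ``theta_gc3`` may be a single probability shared by all species or a
    per-species sequence (used for neutrality-plot sweeps).
    """

    n_species: int = 5
    gene_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    aa_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQS))
    theta_gc3: float | Sequence[float] = 0.2
    selection_s: float = 1.0
    gc12_mode: str = "fixed"  # "linked" | "fixed"
    code_table: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for gene, length in self.gene_lengths.items():
            if length < 30:
                raise ValueError(f"{gene}: gene length {length} < 30 codons")
        total = sum(self.aa_freqs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"aa_freqs sum to {total}, expected 1")
        if any(w < 0 for w in self.aa_freqs.values()):
            raise ValueError("aa_freqs must be non-negative")
        if all(w == 0 for w in self.aa_freqs.values()):
            raise ValueError("all amino-acid weights are zero")
        for theta in self.thetas():
            if not 0.0 < theta < 1.0:
                raise ValueError(f"theta_gc3 {theta} outside (0, 1)")
        if self.selection_s < 0:
            raise ValueError("selection_s must be >= 0")
        if self.gc12_mode not in ("linked", "fixed"):
            raise ValueError(f"unknown gc12_mode {self.gc12_mode!r}")

    def thetas(self) -> list[float]:
        """Per-species third-position GC probabilities."""
        if isinstance(self.theta_gc3, (int, float)):
            return [float(self.theta_gc3)] * self.n_species
        thetas = [float(t) for t in self.theta_gc3]
        if len(thetas) != self.n_species:
            raise ValueError(
                f"theta_gc3 sequence length {len(thetas)} != n_species "
                f"{self.n_species}")
        return thetas

    def species_names(self) -> list[str]:
        return [f"species{i + 1:02d}" for i in range(self.n_species)]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["gene_lengths"] = dict(self.gene_lengths)
        data["aa_freqs"] = dict(self.aa_freqs)
        if not isinstance(data["theta_gc3"], (int, float)):
            data["theta_gc3"] = list(map(float, data["theta_gc3"]))
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


def neutral_spec(**overrides) -> SynthSpec:
    """Symmetric reference spec: uniform amino acids, theta 0.5, no selection.

    Under this spec every synonymous codon is equiprobable within its family
    and every expected RSCU equals 1 (linked mode keeps the two-base prefix
    distribution uniform as well; the fixed-mode 0.45 pin would tilt
    multi-prefix families like Leu).
    """
    defaults = dict(
        aa_freqs={aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"},
        theta_gc3=0.5, selection_s=0.0, gc12_mode="linked",
    )
    defaults.update(overrides)
    return SynthSpec(**defaults)


# ---------------------------------------------------------------------------
# Closed-form codon distribution
# ---------------------------------------------------------------------------

def _base_weights(gc_prob: float) -> dict[str, float]:
    return {"G": gc_prob / 2, "C": gc_prob / 2,
            "A": (1 - gc_prob) / 2, "T": (1 - gc_prob) / 2}


def expected_codon_distribution(
    spec: SynthSpec, species_index: int = 0, code: GeneticCode | None = None
) -> dict[str, float]:
    """Exact per-codon sampling probabilities over the sense codons."""
    code = code or get_genetic_code(spec.code_table)
    theta = spec.thetas()[species_index]
    theta12 = theta if spec.gc12_mode == "linked" else _FIXED_GC12
    w12 = _base_weights(theta12)
    m3 = _base_weights(theta)
    sel = np.exp(spec.selection_s)

    def codon_weight(codon: str) -> float:
        aa = code.codon_to_aa[codon]
        w = spec.aa_freqs.get(aa, 0.0) * m3[codon[2]]
        if codon[2] in "AT":
            w *= sel
        return w

    probs: dict[str, float] = {}
    prefix_mass = 0.0
    for b1 in BASES:
        for b2 in BASES:
            prefix = b1 + b2
            codons = [prefix + b3 for b3 in BASES
                      if prefix + b3 not in code.stop_codons]
            weights = {c: codon_weight(c) for c in codons}
            z = sum(weights.values())
            if z == 0.0:
                continue  # prefix unreachable (all its amino acids weight 0)
            pw = w12[b1] * w12[b2]
            prefix_mass += pw
            for c, w in weights.items():
                probs[c] = pw * w / z
    if not probs:
        raise ValueError("no codon has positive probability under this spec")
    return {c: p / prefix_mass for c, p in probs.items()}


def expected_rscu(
    spec: SynthSpec, code: GeneticCode | None = None, species_index: int = 0
) -> dict[str, float]:
    """Closed-form expected RSCU per sense codon under the sampling model."""
    code = code or get_genetic_code(spec.code_table)
    probs = expected_codon_distribution(spec, species_index, code)
    out: dict[str, float] = {}
    for fam in code.families:
        total = sum(probs.get(c, 0.0) for c in fam.codons)
        for c in fam.codons:
            out[c] = (fam.degeneracy * probs.get(c, 0.0) / total
                      if total > 0 else 0.0)
    return out


def expected_gc3_pct(spec: SynthSpec, species_index: int = 0) -> float:
    """Exact expected third-position G+C percentage of generated codons."""
    probs = expected_codon_distribution(spec, species_index)
    return 100.0 * sum(p for c, p in probs.items() if c[2] in "GC")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cds_set(spec: SynthSpec) -> list[CodingSequence]:
    """Draw a full species x gene CDS set; deterministic for a fixed seed.

    Each CDS carries a terminal stop codon valid under the spec's code
    (stripped again by ingestion normalization / codon counting).
    """
    code = get_genetic_code(spec.code_table)
    stop = "TAA" if "TAA" in code.stop_codons else sorted(code.stop_codons)[0]
    rng = np.random.default_rng(spec.seed)
    records: list[CodingSequence] = []
    for s_idx, species in enumerate(spec.species_names()):
        dist = expected_codon_distribution(spec, s_idx, code)
        codons = np.array(sorted(dist))
        p = np.array([dist[c] for c in codons])
        p = p / p.sum()
        for gene, length in spec.gene_lengths.items():
            draw = rng.choice(len(codons), size=length, p=p)
            seq = "".join(codons[draw]) + stop
            records.append(CodingSequence(
                species=species, gene=gene, nucleotides=seq,
                code_table=spec.code_table,
            ))
    return records
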