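"""Nucleotide composition, positional GC content and strand skews.

All statistics are computed on normalized (stop-free, in-frame) CDS.
Percentages are carried at full precision and only rounded by report
writers. AT/GC skews follow the strand-asymmetry definitions
``(A - T)/(A + T)`` and ``(G - C)/(G + C)``; a zero denominator yields an
undefined (``None``) skew rather than a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Literal

import pandas as pd

from .genetic_codes_io import CodingSequence


@dataclass
class CompositionProfile:
    """Base composition of one CDS (or a group mean), on the 0-100 scale."""

    species: str
    gene: str
    length: int
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    pct_A3: float
    pct_T3: float
    pct_G3: float
    pct_C3: float
    pct_GC: float
    pct_GC1: float
    pct_GC2: float
    pct_GC3: float
    pct_GC12: float
    at_skew: float | None
    gc_skew: float | None

    def numeric_fields(self) -> dict[str, float | None]:
        skip = {"species", "gene"}
        return {f.name: getattr(self, f.name)
                for f in fields(self) if f.name not in skip}


def _pcts(seq: str) -> tuple[float, float, float, float]:
    n = len(seq)
    return tuple(100.0 * seq.count(b) / n for b in "ATGC")  # type: ignore


def _skew(x: int, y: int) -> float | None:
    return None if x + y == 0 else (x - y) / (x + y)


def composition_profile(cds: CodingSequence) -> CompositionProfile:
    """Compute the full positional composition profile of one CDS."""
    seq = cds.nucleotides
    if not seq:
        raise ValueError(f"{cds.species}|{cds.gene}: zero-length CDS")
    if len(seq) % 3:
        raise ValueError(f"{cds.species}|{cds.gene}: CDS length not a multiple of 3")
    p1, p2, p3 = seq[0::3], seq[1::3], seq[2::3]
    a, t, g, c = _pcts(seq)
    a3, t3, g3, c3 = _pcts(p3)
    gc1 = 100.0 * sum(p1.count(b) for b in "GC") / len(p1)
    gc2 = 100.0 * sum(p2.count(b) for b in "GC") / len(p2)
    gc3 = g3 + c3
    return CompositionProfile(
        species=cds.species, gene=cds.gene, length=len(seq),
        pct_A=a, pct_T=t, pct_G=g, pct_C=c,
        pct_A3=a3, pct_T3=t3, pct_G3=g3, pct_C3=c3,
        pct_GC=g + c, pct_GC1=gc1, pct_GC2=gc2, pct_GC3=gc3,
        pct_GC12=(gc1 + gc2) / 2.0,
        at_skew=_skew(seq.count("A"), seq.count("T")),
        gc_skew=_skew(seq.count("G"), seq.count("C")),
    )


def aggregate_composition(
    profiles: Iterable[CompositionProfile],
    by: Literal["gene", "species", "overall"] = "gene",
) -> dict[str, CompositionProfile]:
    """Unweighted per-group arithmetic means of composition profiles.

    Grouping is by gene, by species, or a single overall group. Skews with
    any undefined member propagate as undefined. Length-weighted averaging is
    deliberately not the default: per-gene means across species of
    near-equal length are the convention for these summaries.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to aggregate")
    groups: dict[str, list[CompositionProfile]] = {}
    for p in profiles:
        key = {"gene": p.gene, "species": p.species, "overall": "overall"}[by]
        groups.setdefault(key, []).append(p)

    def _mean(vals: list[float | None]) -> float | None:
        if any(v is None for v in vals):
            return None
        return math.fsum(vals) / len(vals)  # type: ignore[arg-type]

    out: dict[str, CompositionProfile] = {}
    for key, members in groups.items():
        kwargs = {}
        for f in fields(CompositionProfile):
            if f.name in ("species", "gene"):
                continue
            vals = [getattr(m, f.name) for m in members]
            kwargs[f.name] = (round(_mean(vals)) if f.name == "length"
                              else _mean(vals))
        out[key] = CompositionProfile(
            species=key if by == "species" else "mean",
            gene=key if by == "gene" else "mean",
            **kwargs,
        )
    return out


def base_ordering(profile: CompositionProfile, third_position: bool = False) -> str:
    """Rank bases by abundance, e.g. ``"T>A>C>G"`` (``T3>A3>C3>G3``)."""
    if third_position:
        vals = {"T3": profile.pct_T3, "A3": profile.pct_A3,
                "C3": profile.pct_C3, "G3": profile.pct_G3}
    else:
        vals = {"T": profile.pct_T, "A": profile.pct_A,
                "C": profile.pct_C, "G": profile.pct_G}
    return ">".join(sorted(vals, key=lambda k: -vals[k]))


def composition_table(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """One row per (species, gene) with every composition statistic."""
    rows = []
    for p in profiles:
        row = {"species": p.species, "gene": p.gene}
        row.update(p.numeric_fields())
        rows.append(row)
    return pd.DataFrame(rows)


def write_composition_tsv(
    profiles: Iterable[CompositionProfile], path, *, decimals: int | None = None
) -> None:
    df = composition_table(profiles)
    if decimals is not None:
        df = df.round(decimals)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
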