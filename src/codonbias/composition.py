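"""Per-gene base-composition indices.

GC1/GC2/GC3 are the G+C fractions at the three codon positions over sense
codons; GC12 is their positional mean over positions 1-2 and GC is the mean
over all three positions. T3s/C3s/A3s/G3s and GC3s restrict attention to
synonymous codons (amino acids of degeneracy >= 2; Met, Trp and stops never
contribute). Two X3s conventions are offered:

* ``"simple"`` (default): X3s is the proportion of synonymous third
  positions equal to base X, so the four values sum to 1 and
  GC3s = G3s + C3s exactly.
* ``"codonw"``: each base's denominator is the number of synonymous codons
  whose family offers that base at the third position, the dialect used by
  the classic codonW tool. GC3s is identical under both conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, List, Sequence

import pandas as pd

from .genetic_code import STANDARD_CODE, GeneticCode
from .sequences import CodingSequence, CodonCountTable, count_codons

X3S_CONVENTIONS = ("simple", "codonw")


@dataclass(frozen=True)
class CompositionProfile:
    """Composition indices of one gene (all values are fractions in [0, 1])."""

    gene_id: str
    t3s: float
    c3s: float
    a3s: float
    g3s: float
    gc3s: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc: float


def positional_gc(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE):
    """(gc1, gc2, gc3, gc12, gc) over the sense codons of a count table."""
    total = counts.sense_total
    if total == 0:
        raise ValueError("no sense codons: positional GC undefined")
    gc_at = [0, 0, 0]
    for codon in code.sense_codons:
        n = counts.counts[codon]
        if n == 0:
            continue
        for pos in range(3):
            if codon[pos] in "GC":
                gc_at[pos] += n
    gc1, gc2, gc3 = (g / total for g in gc_at)
    return gc1, gc2, gc3, (gc1 + gc2) / 2, (gc1 + gc2 + gc3) / 3


def synonymous_third_position(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    convention: str = "simple",
):
    """(t3s, c3s, a3s, g3s, gc3s) over synonymous codons.

    GC3s is always the G+C proportion of synonymous third positions; the
    per-base X3s values follow the chosen convention (see module docstring).
    """
    if convention not in X3S_CONVENTIONS:
        raise ValueError(f"unknown X3s convention: {convention!r}")
    syn = code.synonymous_codons
    total = sum(counts.counts[c] for c in syn)
    if total == 0:
        raise ValueError("no synonymous codons: X3s/GC3s undefined")
    base_counts = {b: 0 for b in "UCAG"}
    for codon in syn:
        base_counts[codon[2]] += counts.counts[codon]
    gc3s = (base_counts["G"] + base_counts["C"]) / total
    if convention == "simple":
        denom = {b: total for b in "UCAG"}
    else:  # codonW: per-base denominator over families offering that base
        denom = {b: 0 for b in "UCAG"}
        for codon in syn:
            offered = {c[2] for c in code.family_of(codon)}
            for b in offered:
                denom[b] += counts.counts[codon]
    x3s = {b: (base_counts[b] / denom[b] if denom[b] else math.nan) for b in "UCAG"}
    return x3s["U"], x3s["C"], x3s["A"], x3s["G"], gc3s


def composition_profile(
    cds: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    convention: str = "simple",
) -> CompositionProfile:
    """All composition indices for one CDS."""
    counts = count_codons(cds, code=code)
    gc1, gc2, gc3, gc12, gc = positional_gc(counts, code=code)
    t3s, c3s, a3s, g3s, gc3s = synonymous_third_position(counts, code=code, convention=convention)
    return CompositionProfile(
        gene_id=cds.gene_id,
        t3s=t3s, c3s=c3s, a3s=a3s, g3s=g3s, gc3s=gc3s,
        gc1=gc1, gc2=gc2, gc3=gc3, gc12=gc12, gc=gc,
    )


def profile_frame(
    sequences: Iterable[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
    convention: str = "simple",
) -> pd.DataFrame:
    """Per-gene composition indices as a DataFrame indexed by gene_id.

    Columns mirror the roles of a per-gene supplementary table:
    T3s, C3s, A3s, G3s, GC3s, GC1, GC2, GC3, GC12, GC.
    """
    rows = [asdict(composition_profile(s, code=code, convention=convention)) for s in sequences]
    df = pd.DataFrame(rows).set_index("gene_id")
    return df[["t3s", "c3s", "a3s", "g3s", "gc3s", "gc1", "gc2", "gc3", "gc12", "gc"]]


def write_profiles_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.4f")
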