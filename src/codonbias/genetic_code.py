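"""Standard genetic code and its synonymous-family structure.

Every statistic in this package is defined over synonymous-codon families:
the set of codons translating to the same amino acid. Under the standard
code there are 61 sense codons and 3 stop codons; Met and Trp are encoded
by a single codon, Ile by three, nine amino acids by two, five by four and
three (Leu, Ser, Arg) by six. Codons are keyed in the RNA alphabet (U, not
T) throughout, matching the convention of codon-usage tables; DNA input is
converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Tuple

from Bio.Data import CodonTable

RNA_BASES: Tuple[str, ...] = ("U", "C", "A", "G")
STOP_CODONS: Tuple[str, ...] = ("UAA", "UAG", "UGA")
STOP_SYMBOL = "*"


def dna_to_rna(codon: str) -> str:
    """Convert a DNA codon/sequence to the RNA alphabet (upper-case)."""
    return codon.upper().replace("T", "U")


def rna_to_dna(codon: str) -> str:
    """Convert an RNA codon/sequence to the DNA alphabet (upper-case)."""
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A codon-to-amino-acid map plus its synonymous-family partition.

    Attributes
    ----------
    codon_to_aa
        Maps each of the 64 RNA codons to a one-letter amino-acid symbol,
        with ``*`` for the three stop codons.
    families
        Maps each amino acid (and ``*``) to the tuple of codons encoding it,
        in a fixed deterministic order.
    degeneracy_classes
        Maps family size k (1, 2, 3, 4, 6) to the tuple of amino acids whose
        family has exactly k codons (stops excluded).
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, Tuple[str, ...]]
    degeneracy_classes: Mapping[int, Tuple[str, ...]]

    @classmethod
    def standard(cls) -> "GeneticCode":
        """Build the standard (table 1) genetic code."""
        table = CodonTable.unambiguous_rna_by_id[1]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = STOP_SYMBOL
        families: dict[str, list[str]] = {}
        for codon in sorted(codon_to_aa):
            families.setdefault(codon_to_aa[codon], []).append(codon)
        fam = {aa: tuple(codons) for aa, codons in families.items()}
        classes: dict[int, list[str]] = {}
        for aa in sorted(fam):
            if aa == STOP_SYMBOL:
                continue
            classes.setdefault(len(fam[aa]), []).append(aa)
        deg = {k: tuple(aas) for k, aas in sorted(classes.items())}
        return cls(codon_to_aa=codon_to_aa, families=fam, degeneracy_classes=deg)

    @cached_property
    def sense_codons(self) -> Tuple[str, ...]:
        """The 61 non-stop codons, sorted."""
        return tuple(c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] != STOP_SYMBOL)

    @cached_property
    def synonymous_codons(self) -> Tuple[str, ...]:
        """The 59 sense codons whose amino acid has degeneracy >= 2."""
        return tuple(c for c in self.sense_codons if self.degeneracy(c) >= 2)

    @cached_property
    def amino_acids(self) -> Tuple[str, ...]:
        """The 20 amino acids, sorted by one-letter symbol."""
        return tuple(aa for aa in sorted(self.families) if aa != STOP_SYMBOL)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[dna_to_rna(codon)]

    def family_of(self, codon: str) -> Tuple[str, ...]:
        """All codons synonymous with `codon` (including itself)."""
        return self.families[self.codon_to_aa[dna_to_rna(codon)]]

    def degeneracy(self, codon: str) -> int:
        """Number of synonymous codons for `codon`'s amino acid."""
        return len(self.family_of(codon))

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[dna_to_rna(codon)] == STOP_SYMBOL


STANDARD_CODE = GeneticCode.standard()
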