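"""CDS validation, FASTA I/O and codon counting.

A coding sequence (CDS) is valid when its length is a positive multiple of
three and it contains no internal stop codon (a terminal stop is allowed
and counted). Codons containing any non-ACGT character are excluded from
all counts; a gene is rejected outright when the excluded fraction exceeds
a configurable threshold (default 5%), which keeps the statistics
well-defined without discarding a whole gene over a single N.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STANDARD_CODE, GeneticCode, dna_to_rna, rna_to_dna

logger = logging.getLogger(__name__)

_DNA_BASES = frozenset("ACGT")


class InvalidSequenceError(ValueError):
    """Raised when a CDS fails validation under a hard-error policy."""


@dataclass(frozen=True)
class ValidationPolicy:
    """How to treat records that fail CDS validation.

    on_invalid: "error" raises InvalidSequenceError (library default);
    "skip" drops the record with a warning (batch/CLI default).
    max_ambiguous_fraction: reject a gene whose fraction of codons carrying
    non-ACGT characters exceeds this bound.
    """

    on_invalid: str = "error"
    max_ambiguous_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.on_invalid not in ("error", "skip"):
            raise ValueError(f"on_invalid must be 'error' or 'skip', got {self.on_invalid!r}")


STRICT = ValidationPolicy(on_invalid="error")
SKIP_INVALID = ValidationPolicy(on_invalid="skip")


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: an identifier plus an upper-case DNA string."""

    gene_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> List[str]:
        """DNA codons in order."""
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def rna_codons(self) -> List[str]:
        return [dna_to_rna(c) for c in self.codons()]


def validate_cds(
    gene_id: str,
    sequence: str,
    policy: ValidationPolicy = STRICT,
    code: GeneticCode = STANDARD_CODE,
) -> CodingSequence:
    """Validate one raw sequence, raising InvalidSequenceError on failure.

    The returned CodingSequence keeps ambiguous codons in place (they are
    skipped at counting time), but the gene is rejected when they exceed
    ``policy.max_ambiguous_fraction`` of its codons.
    """
    seq = sequence.upper()
    if not seq or len(seq) % 3 != 0:
        raise InvalidSequenceError(f"{gene_id}: length {len(seq)} is not a positive multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    ambiguous = [c for c in codons if not _DNA_BASES.issuperset(c)]
    if len(ambiguous) / len(codons) > policy.max_ambiguous_fraction:
        raise InvalidSequenceError(
            f"{gene_id}: {len(ambiguous)}/{len(codons)} codons contain non-ACGT characters "
            f"(threshold {policy.max_ambiguous_fraction:.0%})"
        )
    for i, codon in enumerate(codons[:-1]):
        if _DNA_BASES.issuperset(codon) and code.is_stop(codon):
            raise InvalidSequenceError(f"{gene_id}: internal stop codon {codon} at codon {i + 1}")
    return CodingSequence(gene_id=gene_id, sequence=seq)


def read_cds_fasta(
    path: str | Path,
    policy: ValidationPolicy = STRICT,
    code: GeneticCode = STANDARD_CODE,
) -> List[CodingSequence]:
    """Read a (possibly gzipped) multi-FASTA of CDSs and validate each record.

    The record id is the first whitespace-delimited token of the header.
    Under ``policy.on_invalid == "skip"`` failing records are dropped with a
    warning; under "error" the first failure raises. An empty file, or a
    file whose records all fail under the skip policy, is an error.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: List[CodingSequence] = []
    n_seen = 0
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            n_seen += 1
            try:
                records.append(validate_cds(rec.id, str(rec.seq), policy=policy, code=code))
            except InvalidSequenceError as exc:
                if policy.on_invalid == "error":
                    raise
                logger.warning("skipping invalid record: %s", exc)
    if n_seen == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if not records:
        raise ValueError(f"{path}: all {n_seen} records failed validation")
    return records


def write_cds_fasta(sequences: Iterable[CodingSequence], path: str | Path) -> None:
    """Write CodingSequences back to plain multi-FASTA."""
    recs = [
        SeqRecord(Seq(cds.sequence), id=cds.gene_id, description="") for cds in sequences
    ]
    SeqIO.write(recs, str(path), "fasta")


class CodonCountTable:
    """Integer occurrence counts for the 64 codons (RNA-alphabet keys).

    Supports elementwise pooling with ``+``. ``total_codons`` is the sum of
    all counts (stops included); ``sense_total`` excludes stop codons.
    """

    __slots__ = ("counts", "code")

    def __init__(self, counts: Mapping[str, int] | None = None, code: GeneticCode = STANDARD_CODE):
        self.code = code
        self.counts = {c: 0 for c in sorted(code.codon_to_aa)}
        if counts:
            for codon, n in counts.items():
                key = dna_to_rna(codon)
                if key not in self.counts:
                    raise KeyError(f"not a codon: {codon!r}")
                if n < 0:
                    raise ValueError(f"negative count for {codon}: {n}")
                self.counts[key] += int(n)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def sense_total(self) -> int:
        return sum(n for c, n in self.counts.items() if not self.code.is_stop(c))

    def __getitem__(self, codon: str) -> int:
        return self.counts[dna_to_rna(codon)]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        out = CodonCountTable(code=self.code)
        for c in out.counts:
            out.counts[c] = self.counts[c] + other.counts[c]
        return out

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CodonCountTable) and self.counts == other.counts

    def __repr__(self) -> str:
        nonzero = sum(1 for n in self.counts.values() if n)
        return f"CodonCountTable(total={self.total_codons}, codons_used={nonzero})"

    def family_total(self, amino_acid: str) -> int:
        return sum(self.counts[c] for c in self.code.families[amino_acid])

    def scaled(self, factor: int) -> "CodonCountTable":
        """All counts multiplied by a positive integer (for invariance checks)."""
        if factor < 1:
            raise ValueError("factor must be a positive integer")
        return CodonCountTable({c: n * factor for c, n in self.counts.items()}, code=self.code)


def count_codons(cds: CodingSequence, code: GeneticCode = STANDARD_CODE) -> CodonCountTable:
    """Count codon occurrences in one CDS; ambiguous codons are skipped."""
    table = CodonCountTable(code=code)
    for codon in cds.codons():
        if _DNA_BASES.issuperset(codon):
            table.counts[dna_to_rna(codon)] += 1
    return table


def pool_counts(tables: Sequence[CodonCountTable]) -> CodonCountTable:
    """Elementwise sum of a non-empty collection of count tables."""
    if not tables:
        raise ValueError("cannot pool an empty collection of count tables")
    out = CodonCountTable(code=tables[0].code)
    for t in tables:
        out = out + t
    return out


def counts_to_tsv(
    tables: Mapping[str, CodonCountTable], path: str | Path, code: GeneticCode = STANDARD_CODE
) -> None:
    """Write per-gene codon counts as TSV (gene_id, codon, amino_acid, count)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcodon\tamino_acid\tcount\n")
        for gene_id, table in tables.items():
            for codon in sorted(code.codon_to_aa):
                fh.write(f"{gene_id}\t{codon}\t{code.codon_to_aa[codon]}\t{table.counts[codon]}\n")
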