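"""Bundled reference codon-count tables.

These are genome-wide pooled codon occurrence counts for the WRKY
transcription-factor gene family of sunflower (*Helianthus annuus*; 115
coding sequences), together with the pooled counts of the two 5% ENC-extreme
gene subsets of that family (the low-ENC "high-expression" pool and the
high-ENC "low-expression" pool). They serve two purposes: a realistic
amino-acid composition for the synthetic-data generator, and worked-example
inputs whose RSCU / delta-RSCU outputs are known.
"""

from __future__ import annotations

from .sequences import CodonCountTable

#: Pooled codon counts over all 115 sunflower WRKY CDSs.
SUNFLOWER_WRKY_COUNTS: dict[str, int] = {
    # Ala
    "GCA": 515, "GCC": 343, "GCG": 290, "GCU": 537,
    # Cys
    "UGC": 349, "UGU": 412,
    # Asp
    "GAC": 502, "GAU": 1277,
    # Glu
    "GAA": 1148, "GAG": 702,
    # Phe
    "UUC": 548, "UUU": 793,
    # Gly
    "GGA": 653, "GGC": 295, "GGG": 440, "GGU": 647,
    # His
    "CAC": 631, "CAU": 830,
    # Ile
    "AUA": 650, "AUC": 743, "AUU": 751,
    # Lys
    "AAA": 1485, "AAG": 1223,
    # Leu
    "CUA": 546, "CUC": 506, "CUG": 509, "CUU": 704, "UUA": 578, "UUG": 730,
    # Met
    "AUG": 1245,
    # Asn
    "AAC": 1027, "AAU": 1099,
    # Pro
    "CCA": 899, "CCC": 338, "CCG": 649, "CCU": 580,
    # Gln
    "CAA": 1409, "CAG": 612,
    # Arg
    "AGA": 854, "AGG": 551, "CGA": 358, "CGC": 186, "CGG": 394, "CGU": 282,
    # Ser
    "AGC": 514, "AGU": 671, "UCA": 963, "UCC": 458, "UCG": 501, "UCU": 827,
    # Thr
    "ACA": 984, "ACC": 731, "ACG": 473, "ACU": 630,
    # Val
    "GUA": 413, "GUC": 369, "GUG": 672, "GUU": 822,
    # Trp
    "UGG": 559,
    # Tyr
    "UAC": 473, "UAU": 582,
    # stops
    "UAA": 228, "UAG": 210, "UGA": 335,
}

#: Pooled counts of the 5% lowest-ENC ("high-expression") WRKY genes.
SUNFLOWER_WRKY_HIGH_EXPRESSION_COUNTS: dict[str, int] = {
    "GCU": 24, "GCC": 11, "GCA": 20, "GCG": 2,
    "UGU": 24, "UGC": 11,
    "GAU": 92, "GAC": 21,
    "GAA": 77, "GAG": 38,
    "UUU": 40, "UUC": 22,
    "GGU": 32, "GGC": 7, "GGA": 24, "GGG": 14,
    "CAU": 36, "CAC": 9,
    "AUU": 29, "AUC": 28, "AUA": 15,
    "AAA": 72, "AAG": 67,
    "UUA": 27, "UUG": 23, "CUU": 31, "CUC": 10, "CUA": 20, "CUG": 5,
    "AUG": 46,
    "AAU": 52, "AAC": 34,
    "CCU": 34, "CCC": 14, "CCA": 45, "CCG": 14,
    "CAA": 69, "CAG": 19,
    "AGA": 52, "AGG": 13, "CGU": 3, "CGC": 0, "CGA": 6, "CGG": 4,
    "AGU": 46, "AGC": 18, "UCU": 39, "UCC": 20, "UCA": 39, "UCG": 25,
    "ACU": 34, "ACC": 26, "ACA": 34, "ACG": 5,
    "GUU": 37, "GUC": 14, "GUA": 23, "GUG": 31,
    "UGG": 16,
    "UAU": 34, "UAC": 21,
    "UAA": 5, "UAG": 0, "UGA": 1,
}

#: Pooled counts of the 5% highest-ENC ("low-expression") WRKY genes.
SUNFLOWER_WRKY_LOW_EXPRESSION_COUNTS: dict[str, int] = {
    "GCU": 39, "GCC": 36, "GCA": 31, "GCG": 19,
    "UGU": 21, "UGC": 14,
    "GAU": 83, "GAC": 58,
    "GAA": 82, "GAG": 63,
    "UUU": 43, "UUC": 29,
    "GGU": 46, "GGC": 20, "GGA": 37, "GGG": 24,
    "CAU": 43, "CAC": 33,
    "AUU": 33, "AUC": 32, "AUA": 26,
    "AAA": 90, "AAG": 66,
    "UUA": 25, "UUG": 30, "CUU": 27, "CUC": 19, "CUA": 23, "CUG": 6,
    "AUG": 53,
    "AAU": 65, "AAC": 64,
    "CCU": 44, "CCC": 27, "CCA": 54, "CCG": 41,
    "CAA": 88, "CAG": 30,
    "AGA": 26, "AGG": 30, "CGU": 15, "CGC": 7, "CGA": 21, "CGG": 18,
    "AGU": 35, "AGC": 31, "UCU": 68, "UCC": 40, "UCA": 68, "UCG": 32,
    "ACU": 43, "ACC": 56, "ACA": 44, "ACG": 30,
    "GUU": 44, "GUC": 22, "GUA": 17, "GUG": 40,
    "UGG": 12,
    "UAU": 39, "UAC": 34,
    "UAA": 3, "UAG": 2, "UGA": 2,
}


def sunflower_wrky_counts() -> CodonCountTable:
    """Genome-wide pooled codon counts of the sunflower WRKY family."""
    return CodonCountTable(SUNFLOWER_WRKY_COUNTS)


def sunflower_wrky_expression_pools() -> tuple[CodonCountTable, CodonCountTable]:
    """(high-expression pool, low-expression pool) codon counts."""
    return (
        CodonCountTable(SUNFLOWER_WRKY_HIGH_EXPRESSION_COUNTS),
        CodonCountTable(SUNFLOWER_WRKY_LOW_EXPRESSION_COUNTS),
    )
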