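"""RSCU of the bundled sunflower WRKY pooled codon counts.

Computes relative synonymous codon usage for the genome-wide pooled counts
of the 115 sunflower WRKY coding sequences and lists the codons whose usage
departs strongly from uniformity.
"""

import codonbias as cb
from codonbias import datasets

pooled = datasets.sunflower_wrky_counts()
table = cb.rscu(pooled)

print("RSCU of selected codons (1 = unbiased within the family):")
for codon in ("GCA", "AGA", "GAU", "CGC"):
    row = table.loc[codon]
    print(f"  {codon} ({row.amino_acid}): count={row['count']:5d}  RSCU={row.rscu:.2f}")

preferred = table.index[table.preferred]
print(f"\npreferred codons (RSCU > 1): {len(preferred)}")
print(f"over-represented  (RSCU > 1.6): {', '.join(table.index[table.over_represented])}")
print(f"under-represented (RSCU < 0.6): {', '.join(table.index[table.under_represented])}")
print("\nAn over-represented codon is used far beyond its family share;")
print("an under-represented one is strongly avoided.")
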