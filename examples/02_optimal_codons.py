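"""Optimal-codon determination from ENC-extreme expression pools.

Compares RSCU between the bundled high-expression (low-ENC, strongly
biased) and low-expression (high-ENC) pooled counts of the sunflower WRKY
family, and applies the delta-RSCU rule: a codon is optimal when
delta-RSCU >= 0.3 with RSCU > 1 in the high-bias pool and < 1 in the
low-bias pool.
"""

import codonbias as cb
from codonbias import datasets

high, low = datasets.sunflower_wrky_expression_pools()
report = cb.delta_rscu_report(high, low)

print("codon  aa  RSCU(high)  RSCU(low)  dRSCU  optimal")
for codon in ("GCA", "AGU", "ACU", "GCU", "AGA"):
    r = report.loc[codon]
    print(f"{codon:>5}  {r.amino_acid:>2}  {r.rscu_high:10.2f}  {r.rscu_low:9.2f}"
          f"  {r.delta_rscu:5.2f}  {bool(r.optimal)}")

print(f"\noptimal codons: {', '.join(cb.optimal_codons(report))}")
print("GCU and AGA clear the delta threshold but stay preferred (RSCU > 1)")
print("even in weakly biased genes, so they are not called optimal.")
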