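"""The end-to-end pipeline: FASTA in, seven analysis tables out.

Simulates a mixed-regime gene set, writes it to FASTA, runs the complete
analysis and prints the headline results. Equivalent shell commands:

    codonbias simulate --out sim --seed 23 --regime mixed
    codonbias analyze --cds sim/synthetic.fasta --out results
"""

import tempfile
from pathlib import Path

import codonbias as cb
from codonbias.pipeline import run_analysis, run_simulate

workdir = Path(tempfile.mkdtemp(prefix="codonbias_"))
paths = run_simulate(cb.SyntheticConfig(seed=23, regime="mixed"), workdir / "sim")
report = run_analysis(paths["fasta"], workdir / "results")

print(f"analyzed {report.n_genes} genes; tables in {report.out_dir}:")
for name, path in report.tables.items():
    print(f"  {name:>14}: {path.name}")

fit = report.neutrality
print(f"\nmean GC  = {report.gene_indices['gc'].mean():.3f}")
print(f"mean ENC = {report.gene_indices['enc'].mean():.2f}")
print(f"neutrality slope = {fit.slope:.2f} (R^2 = {fit.r_squared:.3f})")
print(f"genes below the expected ENC curve: "
      f"{report.enc_plot_summary['fraction_above_zero']:.0%}")
print(f"optimal codons: {', '.join(report.optimal) if report.optimal else 'none'}")
print("\nThe mixed regime layers per-gene preferred codons on top of GC")
print("pressure, so ENC drops below the mutation-only expectation.")
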