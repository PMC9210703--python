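# Methods

## Scope and model

The package quantifies synonymous codon usage bias in a set of coding
sequences and attributes it to the two classical forces: directional
mutation pressure (GC content drift, acting identically at all codon
positions but visible most clearly at the third) and translational
selection (preference for specific codons independent of composition). All
statistics are defined over the synonymous-family partition of the standard
genetic code (61 sense codons; degeneracies 1, 2, 3, 4, 6), built from
Biopython's codon table.

## Sequence handling

A CDS is valid when its length is a positive multiple of three and it has
no internal stop; the terminal stop is kept and tabulated but excluded from
every downstream index except the raw RSCU/ΔRSCU tables' terminator rows.
Codons containing non-ACGT characters are dropped from counts; a gene is
rejected when such codons exceed a configurable fraction (default 5%) —
this keeps statistics well defined without discarding a gene over a single
N, and the threshold is the package's own choice since upstream tools do
not document theirs. The library API fails hard on invalid records by
default; the CLI skips them with a logged warning (batch robustness).

## Index conventions

* **Positional GC.** GC1/GC2/GC3 are computed over sense codons; GC12 is
  their mean over positions 1–2 and GC the mean over all three (equal to
  the G+C fraction of the stop-stripped sequence).
* **X3s.** Two dialects are provided. The default ("simple") reports the
  proportion of synonymous third positions equal to each base, so
  T3s+C3s+A3s+G3s = 1 and GC3s = G3s+C3s exactly. The "codonw" switch
  reproduces the classic tool's per-base denominators (counts of synonymous
  codons whose family offers that base at position 3). GC3s is identical
  under both; no downstream result depends on the choice.
* **ENC.** Wright's estimator with codonW conventions: families with fewer
  than two observed codons are skipped; a degeneracy class whose mean
  homozygosity is missing or zero is imputed — the Ile class as the mean of
  the 2- and 4-fold class means, any other as the mean of the available
  classes — and the result is capped at 61. A gene offering no usable
  family (e.g. Met/Trp only) is reported as undefined (NaN). Note that the
  finite-count estimator F̂ = (nΣp̂² − 1)/(n − 1) lies below Σp², so ENC
  *decreases* monotonically toward its infinite-count value as counts
  scale; the test suite asserts this direction.
* **CAI.** Relative adaptiveness weights w = RSCU/max RSCU within each
  family, from a reference count table. No organism-wide highly-expressed
  reference is bundled, so the default reference is the pooled counts of
  the input's own low-ENC 5% ("high expression") subset; an external usage
  table can be supplied. Zero-count reference codons receive w = 0.01
  before the geometric mean. CAI magnitudes are therefore comparable only
  within a run sharing one reference.
* **Rounding.** Classification (preferred/over/under-represented, optimal)
  always uses unrounded values; table outputs display 2 decimals, rounded
  half-up as printed codon tables conventionally are.

## Evolutionary diagnostics

The neutrality fit is ordinary least squares of GC12 on GC3 with Pearson r
and a two-tailed p-value; a constant-GC3 input is rejected as undefined.
The ENC plot reports per-gene relative deviation (ENCexp − ENCobs)/ENCexp —
positive values are genes *below* the curve (extra bias beyond composition)
— plus the fractions below/above zero and within a ±0.12 band, and a
histogram (default bin width 0.04; the band fractions are computed from the
per-gene values, never from bins). PR2 coordinates pool third-position
counts over exactly the eight four-codon families listed above (AGA/AGG,
AGU/AGC and UUA/UUG are excluded); the dataset summary is the unweighted
mean of per-gene coordinates by default, matching what a PR2 scatter plot
displays, with a pooled-count alternative. Correlations are pairwise
Pearson r with t-distribution p-values (n − 2 df), flagged at 0.05/0.01
without multiple-testing correction, as is conventional for these
descriptive tables.

## Optimal codons

Genes are ranked by ENC; each extreme set has round-half-up(fraction × n)
members (5% of 115 → 6), ties broken by gene id for determinism. RSCU is
computed on the pooled counts of each set and a codon is optimal when
ΔRSCU ≥ 0.3, RSCU > 1 in the low-ENC pool and RSCU < 1 in the high-ENC
pool. The report always covers all 59 synonymous codons; families absent
from either pool stay unclassified rather than silently dropped.

## Synthetic data

The generator emulates a plant gene family: 115 genes of ~375 ± 60 codons
(minimum 30), amino-acid composition taken from the bundled sunflower WRKY
family totals, per-gene third-position GC pressure g drawn uniformly from
(0.29, 0.53).

* Within every synonymous family the third position is G/C with probability
  exactly g (mass split evenly among the family's G/C-ending and A/U-ending
  codons), so mean GC3s tracks g and mutation-only genes sit on the
  expected ENC curve up to sampling noise.
* The neutrality coupling (default slope 0.35) is realised by exponential
  tilting of the amino-acid composition: each gene's target GC12 is an
  affine function of its expected measured GC3, and the tilt parameter is
  solved exactly (Brent root find) against the gene's own within-family
  codon distribution, anchored at GC12 = 0.4533 mid-range. Because measured
  GC3 is a noisy realisation of g at finite gene length, the latent
  coupling is inflated by the analytic errors-in-variables factor
  1 + σ²noise/σ²signal (capped at 2 for near-degenerate pressure ranges);
  with the default conditions the regression of measured GC12 on measured
  GC3 recovers the configured slope in expectation (checked over replicate
  seeds).
* The selection regime draws one preferred codon per family per gene and
  weights it by exp(selection_strength) (default 3; ENC → 20 as the
  strength grows); "mixed" interpolates the log-weights halfway.
* Stops are drawn with the same third-position rule; all randomness flows
  from one seeded NumPy generator, so identical seed + config is
  byte-identical.

What the generator does **not** emulate: codon autocorrelation along a
gene, amino-acid composition differences between genes beyond the GC tilt,
paralog structure, indels, or sequencing artefacts. Passing tests on
synthetic data therefore validate the statistical machinery and the
direction/magnitude of regime signatures, not the biology of any real gene
family.

## Problem sizes and numerics

Default analyses and tests run on 115-gene sets of ~375 codons — the scale
the package targets — and complete in seconds; the ENC oracle
cross-check uses 200 random count tables at 1e-9 agreement. Degenerate
inputs (no sense codons, no synonymous codons, constant regressors, empty
PR2 family sets, empty pools) raise ValueError or return NaN rather than
fabricate numbers; division guards report undefined PR2 axes as NaN so a
gene with, say, no G/C third positions still contributes its defined
coordinate.

## Known limitations

* ENC/CAI conventions follow codonW; other tools (e.g. EMBOSS chips) differ
  in sparse-family handling, so third-decimal differences against other
  software are expected.
* The self-referential default CAI reference makes CAI a relative, not
  absolute, expression proxy.
* The ENC-as-expression proxy behind the optimal-codon rule is assumed, not
  validated against expression data.
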