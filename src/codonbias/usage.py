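"""Codon usage indices: RSCU, Wright's effective number of codons, CAI.

RSCU (relative synonymous codon usage) for codon i in a family of size k
with family total n is ``count_i / (n / k)``: the observed count over the
count expected if all synonymous codons were used equally. RSCU = 1 means
unbiased usage; values above 1.6 / below 0.6 flag over- / under-represented
codons.

ENC (effective number of codons, 20..61) summarises how far a gene departs
from uniform synonymous usage. Per amino acid with family size k and n >= 2
observed codons, the codon homozygosity is estimated as
``F = (n * sum(p_i^2) - 1) / (n - 1)`` with ``p_i = count_i / n``; then
``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` where ``Fk`` is the mean F over the
degeneracy-k class. Conventions follow the classic codonW tool: families
with n < 2 are skipped; a missing Ile class (F3) is imputed as the mean of
F2 and F4, any other missing class as the mean of the available ones; the
result is capped at 61.

CAI (codon adaptation index) is the count-weighted geometric mean of
relative adaptiveness weights ``w_i = RSCU_ref(i) / max RSCU_ref`` within
each family, over the gene's synonymous codons.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genetic_code import STANDARD_CODE, GeneticCode, STOP_SYMBOL
from .sequences import CodonCountTable

OVER_REPRESENTED_RSCU = 1.6
UNDER_REPRESENTED_RSCU = 0.6
ENC_MAX = 61.0
CAI_ZERO_WEIGHT = 0.01  # floor for reference codons never observed


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed codon tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rscu(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    include_stops: bool = True,
) -> pd.DataFrame:
    """RSCU table for one (per-gene or pooled) codon count table.

    Returns a DataFrame indexed by codon with columns ``amino_acid``,
    ``count``, ``freq_per_1000``, ``rscu`` and boolean flags ``preferred``
    (RSCU > 1), ``over_represented`` (> 1.6) and ``under_represented``
    (< 0.6). Stop codons (when included) and the single-codon amino acids
    AUG (Met) / UGG (Trp) are never flagged; AUG/UGG carry RSCU = 1 by
    definition, and families with zero observations yield NaN.
    """
    rows = []
    tabulated = [
        c for c in sorted(code.codon_to_aa)
        if include_stops or not code.is_stop(c)
    ]
    grand_total = sum(counts.counts[c] for c in tabulated)
    for codon in tabulated:
        aa = code.codon_to_aa[codon]
        family = code.families[aa]
        k = len(family)
        n_family = sum(counts.counts[c] for c in family)
        count = counts.counts[codon]
        if n_family == 0:
            value = math.nan
        elif k == 1:
            value = 1.0
        else:
            value = count / (n_family / k)
        classifiable = aa != STOP_SYMBOL and k > 1 and not math.isnan(value)
        rows.append(
            {
                "codon": codon,
                "amino_acid": aa,
                "count": count,
                "freq_per_1000": 1000.0 * count / grand_total if grand_total else math.nan,
                "rscu": value,
                "preferred": bool(classifiable and value > 1.0),
                "over_represented": bool(classifiable and value > OVER_REPRESENTED_RSCU),
                "under_represented": bool(classifiable and value < UNDER_REPRESENTED_RSCU),
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def _family_homozygosity(counts: Sequence[int]) -> Optional[float]:
    """F-hat = (n * sum p^2 - 1) / (n - 1); None when n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float:
    """Wright's effective number of codons for one gene (NaN if undefined).

    See the module docstring for the estimator and the codonW conventions
    used for sparse families and missing degeneracy classes.
    """
    class_means: Dict[int, Optional[float]] = {}
    for k, aas in code.degeneracy_classes.items():
        if k == 1:
            continue
        fs = []
        for aa in aas:
            f = _family_homozygosity([counts.counts[c] for c in code.families[aa]])
            if f is not None:
                fs.append(f)
        mean = sum(fs) / len(fs) if fs else None
        if mean is not None and mean <= 0.0:
            mean = None  # an all-singletons class carries no usable signal
        class_means[k] = mean
    available = [m for m in class_means.values() if m is not None]
    if not available:
        return math.nan
    if class_means.get(3) is None and class_means.get(2) is not None and class_means.get(4) is not None:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    for k in class_means:
        if class_means[k] is None:
            class_means[k] = sum(available) / len(available)
    value = 2.0 + 9.0 / class_means[2] + 1.0 / class_means[3] + 5.0 / class_means[4] + 3.0 / class_means[6]
    return min(value, ENC_MAX)


def expected_enc(gc3s: float) -> float:
    """Expected ENC under pure compositional (GC3s-driven) constraint.

    ``ENC = 2 + GC3s + 29 / (GC3s^2 + (1 - GC3s)^2)``, capped at 61. The
    curve is the null expectation of the ENC-plot: genes whose codon choice
    is set by third-position G+C alone fall on it.
    """
    if not 0.0 < gc3s < 1.0:
        raise ValueError(f"gc3s must lie in (0, 1), got {gc3s}")
    value = 2.0 + gc3s + 29.0 / (gc3s ** 2 + (1.0 - gc3s) ** 2)
    return min(value, ENC_MAX)


def cai_weights(
    reference_counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
) -> Dict[str, float]:
    """Relative adaptiveness weights for the 59 synonymous codons.

    ``w_i = RSCU_ref(i) / max RSCU_ref`` within i's family; reference codons
    with zero count receive a small positive floor so the geometric mean
    stays defined. A family entirely absent from the reference is an error.
    """
    ref = rscu(reference_counts, code=code, include_stops=False)
    weights: Dict[str, float] = {}
    for aa in code.amino_acids:
        family = code.families[aa]
        if len(family) < 2:
            continue
        values = ref.loc[list(family), "rscu"]
        if values.isna().any():
            raise ValueError(f"reference has no observations for amino acid {aa}")
        top = float(values.max())
        for codon in family:
            w = float(values[codon]) / top
            weights[codon] = max(w, CAI_ZERO_WEIGHT)
    return weights


def cai(
    counts: CodonCountTable,
    weights: Mapping[str, float],
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Codon adaptation index of one gene given reference weights.

    Count-weighted geometric mean of w over the gene's synonymous codons;
    AUG, UGG and stops are excluded. Lies in (0, 1]; 1 means the gene uses
    only reference-maximal codons.
    """
    log_sum = 0.0
    n = 0
    for codon in code.synonymous_codons:
        c = counts.counts[codon]
        if c == 0:
            continue
        log_sum += c * math.log(weights[codon])
        n += c
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def gene_usage_indices(
    gene_counts: Mapping[str, CodonCountTable],
    cai_reference: Optional[CodonCountTable] = None,
    extreme_fraction: float = 0.05,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-gene ENC and CAI as a DataFrame indexed by gene_id.

    When no external CAI reference is supplied, weights are derived from
    the pooled counts of the low-ENC extreme (putatively highly expressed)
    ``extreme_fraction`` of the genes themselves — a self-contained stand-in
    for an organism-specific highly-expressed reference set.
    """
    from .optimal import select_extreme_sets  # deferred: optimal imports usage

    enc_series = pd.Series(
        {gid: enc(t, code=code) for gid, t in gene_counts.items()}, name="enc"
    )
    if cai_reference is None:
        high_bias, _ = select_extreme_sets(enc_series, fraction=extreme_fraction)
        pooled = None
        for gid in high_bias:
            pooled = gene_counts[gid] if pooled is None else pooled + gene_counts[gid]
        cai_reference = pooled
    weights = cai_weights(cai_reference, code=code)
    cai_series = pd.Series(
        {gid: cai(t, weights, code=code) for gid, t in gene_counts.items()}, name="cai"
    )
    df = pd.concat([enc_series, cai_series], axis=1)
    df.index.name = "gene_id"
    return df


def write_rscu_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """RSCU table as TSV with 2-dp display columns (classification stays unrounded)."""
    out = table.copy()
    out["freq_per_1000"] = out["freq_per_1000"].map(lambda v: round_half_up(v, 2) if not math.isnan(v) else v)
    out["rscu"] = out["rscu"].map(lambda v: round_half_up(v, 2) if not math.isnan(v) else v)
    out.to_csv(path, sep="\t")
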