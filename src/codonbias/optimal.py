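"""Optimal-codon determination from ENC-extreme gene sets.

Genes are ranked by ENC; the lowest-ENC fraction (strong bias, putatively
highly expressed) and the highest-ENC fraction (weak bias) form two pools.
A codon is called optimal when its RSCU difference between the pools,
delta-RSCU = RSCU(high-bias) - RSCU(low-bias), is at least 0.3 while its
RSCU exceeds 1 in the high-bias pool and falls below 1 in the low-bias
pool. Classification always uses unrounded values; rounding is display-only.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Sequence, Tuple

import pandas as pd

from .genetic_code import STANDARD_CODE, GeneticCode, STOP_SYMBOL
from .sequences import CodonCountTable
from .usage import round_half_up, rscu

DELTA_RSCU_THRESHOLD = 0.3


def select_extreme_sets(
    enc_by_gene: pd.Series,
    fraction: float = 0.05,
) -> Tuple[List[str], List[str]]:
    """(high_bias_ids, low_bias_ids): the ENC-extreme `fraction` of genes.

    high_bias = lowest ENC ("high expression"), low_bias = highest ENC.
    Set size is round-half-up of fraction * n with a minimum of 1; ties in
    ENC are broken by ascending gene_id for determinism.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5), got {fraction}")
    enc_by_gene = enc_by_gene.dropna()
    n = len(enc_by_gene)
    size = max(1, int(math.floor(fraction * n + 0.5)))
    if n < 2 * size:
        raise ValueError(f"{n} genes cannot supply two disjoint sets of {size}")
    order = sorted(enc_by_gene.items(), key=lambda kv: (kv[1], kv[0]))
    high_bias = [gid for gid, _ in order[:size]]
    low_bias = [gid for gid, _ in sorted(order[-size:], key=lambda kv: (-kv[1], kv[0]))]
    return high_bias, low_bias


def delta_rscu_report(
    high_counts: CodonCountTable,
    low_counts: CodonCountTable,
    threshold: float = DELTA_RSCU_THRESHOLD,
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Codon-by-codon RSCU comparison of the two pools.

    Returns a DataFrame indexed by codon with columns amino_acid,
    count_high, rscu_high, count_low, rscu_low, delta_rscu and the boolean
    ``optimal`` flag. All 59 synonymous codons are present (plus AUG, UGG
    and stops as unclassified rows); a family absent from either pool keeps
    NaN RSCU and is never flagged.
    """
    if high_counts.total_codons == 0 or low_counts.total_codons == 0:
        raise ValueError("both pools must be non-empty")
    hi = rscu(high_counts, code=code, include_stops=True)
    lo = rscu(low_counts, code=code, include_stops=True)
    df = pd.DataFrame(
        {
            "amino_acid": hi["amino_acid"],
            "count_high": hi["count"],
            "rscu_high": hi["rscu"],
            "count_low": lo["count"],
            "rscu_low": lo["rscu"],
        }
    )
    df["delta_rscu"] = df["rscu_high"] - df["rscu_low"]
    classifiable = df["amino_acid"].map(
        lambda aa: aa != STOP_SYMBOL and len(code.families[aa]) > 1
    ) & df["delta_rscu"].notna()
    df["optimal"] = (
        classifiable
        & (df["delta_rscu"] >= threshold)
        & (df["rscu_high"] > 1.0)
        & (df["rscu_low"] < 1.0)
    )
    return df


def optimal_codons(report: pd.DataFrame) -> List[str]:
    """The codons flagged optimal, sorted."""
    return sorted(report.index[report["optimal"]])


def write_optimal_tsv(report: pd.DataFrame, path: str | Path) -> None:
    """Optimal-codon report as TSV; RSCU columns displayed at 2 dp."""
    out = report.copy()
    for col in ("rscu_high", "rscu_low", "delta_rscu"):
        out[col] = out[col].map(lambda v: round_half_up(v, 2) if pd.notna(v) else v)
    out.to_csv(path, sep="\t")
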