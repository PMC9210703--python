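"""Evolutionary-force diagnostics built on the per-gene indices.

* Neutrality plot: OLS of GC12 on GC3 across genes. A slope near 1 means
  directional mutation pressure acts on all codon positions alike; a slope
  near 0 means selection holds positions 1-2 while position 3 drifts.
* ENC plot: observed ENC against GC3s, compared with the expected curve
  under pure compositional constraint; the relative deviation
  (ENCexp - ENCobs) / ENCexp summarises how far each gene sits below (> 0)
  or above (< 0) the curve.
* PR2 plot: within eight four-codon families, A3/(A3+T3) against
  G3/(G3+C3); (0.5, 0.5) is the parity expectation when mutation alone,
  acting symmetrically on the two strands, sets third-position usage.
* Pearson correlation matrix across all composition and usage indices,
  with two-tailed p-values from the t-distribution (n - 2 df).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import STANDARD_CODE, GeneticCode
from .sequences import CodonCountTable
from .usage import expected_enc

#: Four-codon families entering the PR2 plot: the six four-fold amino acids
#: plus the four-codon (C/U-starting) subsets of Arg, Leu and Ser.
PR2_FAMILIES: Dict[str, Tuple[str, ...]] = {
    "Ala": ("GCA", "GCC", "GCG", "GCU"),
    "Gly": ("GGA", "GGC", "GGG", "GGU"),
    "Pro": ("CCA", "CCC", "CCG", "CCU"),
    "Thr": ("ACA", "ACC", "ACG", "ACU"),
    "Val": ("GUA", "GUC", "GUG", "GUU"),
    "Arg": ("CGA", "CGC", "CGG", "CGU"),
    "Leu": ("CUA", "CUC", "CUG", "CUU"),
    "Ser": ("UCA", "UCC", "UCG", "UCU"),
}


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with its Pearson correlation."""

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int

    def interpretation(self, alpha: float = 0.05) -> str:
        """Plain-language reading of the fitted slope."""
        if self.p_value > alpha:
            return "no significant GC12-GC3 coupling: selection-dominated codon usage"
        if self.slope >= 0.5:
            return "slope near 1: mutation pressure dominates codon usage"
        return "significant but shallow slope: mutation pressure present, tempered by selection"


def neutrality_fit(gc3: Sequence[float], gc12: Sequence[float]) -> NeutralityFit:
    """Fit the neutrality plot (GC12 ~ GC3) by ordinary least squares."""
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.size < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    if np.allclose(x, x[0]):
        raise ValueError("GC3 is constant across genes: slope undefined")
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def enc_plot(
    indices: pd.DataFrame,
    deviation_band: float = 0.12,
    bin_width: float = 0.04,
) -> Tuple[pd.DataFrame, Dict[str, float], pd.DataFrame]:
    """ENC-plot records and the relative-deviation summary.

    `indices` must carry per-gene columns ``enc`` and ``gc3s`` (index =
    gene_id). Returns (records, summary, histogram): records add ``enc_exp``
    and ``rel_deviation`` = (enc_exp - enc_obs)/enc_exp per gene; the
    summary reports the fractions of genes below / above zero deviation and
    within ±`deviation_band`; the histogram bins rel_deviation at
    `bin_width` for plotting.
    """
    df = indices[["enc", "gc3s"]].dropna().copy()
    df["enc_exp"] = df["gc3s"].map(expected_enc)
    df["rel_deviation"] = (df["enc_exp"] - df["enc"]) / df["enc_exp"]
    d = df["rel_deviation"]
    n = len(df)
    summary = {
        "n": float(n),
        "fraction_below_zero": float((d < 0).sum() / n),
        "fraction_above_zero": float((d > 0).sum() / n),
        "fraction_within_band": float(d.between(-deviation_band, deviation_band).sum() / n),
        "band": deviation_band,
        "median_abs_deviation": float(d.abs().median()),
    }
    lo = math.floor(d.min() / bin_width) * bin_width
    hi = math.ceil(d.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    hist, edges = np.histogram(d.to_numpy(), bins=edges)
    hist_df = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_genes": hist}
    )
    df = df.rename(columns={"enc": "enc_obs"})
    return df[["gc3s", "enc_obs", "enc_exp", "rel_deviation"]], summary, hist_df


@dataclass(frozen=True)
class PR2Point:
    """Third-position parity coordinates of one gene.

    at_bias = A3/(A3+T3) and gc_bias = G3/(G3+C3), tallied over the eight
    four-codon families; NaN where the denominator is empty.
    """

    gene_id: str
    at_bias: float
    gc_bias: float
    at3_fraction: float
    gc3_fraction: float
    a3: int
    t3: int
    g3: int
    c3: int


def pr2(
    counts: CodonCountTable,
    gene_id: str = "",
    families: Mapping[str, Sequence[str]] = PR2_FAMILIES,
) -> PR2Point:
    """PR2 coordinates from the third positions of the four-codon families."""
    tallies = {b: 0 for b in "ACGU"}
    for codons in families.values():
        for codon in codons:
            tallies[codon[2]] += counts.counts[codon]
    a3, t3, g3, c3 = tallies["A"], tallies["U"], tallies["G"], tallies["C"]
    total = a3 + t3 + g3 + c3
    if total == 0:
        raise ValueError(f"{gene_id or 'gene'}: no codons in the PR2 family set")
    return PR2Point(
        gene_id=gene_id,
        at_bias=a3 / (a3 + t3) if a3 + t3 else math.nan,
        gc_bias=g3 / (g3 + c3) if g3 + c3 else math.nan,
        at3_fraction=(a3 + t3) / total,
        gc3_fraction=(g3 + c3) / total,
        a3=a3, t3=t3, g3=g3, c3=c3,
    )


def pr2_frame(
    gene_counts: Mapping[str, CodonCountTable],
    families: Mapping[str, Sequence[str]] = PR2_FAMILIES,
) -> pd.DataFrame:
    """Per-gene PR2 points (genes with no qualifying codons are dropped)."""
    rows = []
    for gid, table in gene_counts.items():
        try:
            p = pr2(table, gene_id=gid, families=families)
        except ValueError:
            continue
        rows.append(p.__dict__)
    if not rows:
        raise ValueError("no gene has codons in the PR2 family set")
    return pd.DataFrame(rows).set_index("gene_id")


def pr2_summary(points: pd.DataFrame, method: str = "per_gene") -> Dict[str, float]:
    """Dataset-level PR2 averages.

    ``per_gene`` (default) takes unweighted means of the per-gene
    coordinates, matching a plot of per-gene points; ``pooled`` recomputes
    the coordinates from the summed third-position tallies.
    """
    if method == "per_gene":
        return {
            "mean_at_bias": float(points["at_bias"].mean()),
            "mean_gc_bias": float(points["gc_bias"].mean()),
            "mean_at3_fraction": float(points["at3_fraction"].mean()),
            "mean_gc3_fraction": float(points["gc3_fraction"].mean()),
        }
    if method == "pooled":
        a3, t3 = points["a3"].sum(), points["t3"].sum()
        g3, c3 = points["g3"].sum(), points["c3"].sum()
        total = a3 + t3 + g3 + c3
        return {
            "mean_at_bias": float(a3 / (a3 + t3)),
            "mean_gc_bias": float(g3 / (g3 + c3)),
            "mean_at3_fraction": float((a3 + t3) / total),
            "mean_gc3_fraction": float((g3 + c3) / total),
        }
    raise ValueError(f"unknown PR2 summary method: {method!r}")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson r, two-tailed p-values and significance flags across indices."""

    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame  # '' / '*' (p<0.05) / '**' (p<0.01)


def correlation_matrix(indices: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations over the columns of `indices`.

    Constant columns yield NaN correlations (flagged empty) rather than an
    error. p-values are two-tailed from the t-distribution with n - 2 df.
    """
    cols = list(indices.columns)
    n_cols = len(cols)
    r = pd.DataFrame(np.eye(n_cols), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((n_cols, n_cols)), index=cols, columns=cols)
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            pair = indices[[cols[i], cols[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(x) < 3 or np.allclose(x, x[0]) or np.allclose(y, y[0]):
                rv, pv = math.nan, math.nan
            else:
                rv, pv = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rv
            p.iloc[i, j] = p.iloc[j, i] = pv
    flags = p.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    np.fill_diagonal(flags.values, "")
    return CorrelationMatrix(r=r, p=p, flags=flags)
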