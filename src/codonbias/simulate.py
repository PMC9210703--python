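"""Synthetic CDS sets with controlled codon-usage structure.

The generator emulates a plant gene family of ~115 coding sequences of
~350-400 codons, and exposes the two forces the analysis is designed to
separate:

* ``mutation_only`` — each gene draws a third-position GC pressure ``g``
  uniformly from ``gc3_range``; within every synonymous family the third
  position is G or C with probability exactly g (mass split evenly among
  the family's G/C-ending, respectively A/U-ending, codons). Such genes sit
  on the expected ENC curve up to sampling noise, and mean GC3s tracks g.
* ``selection`` — each gene draws one preferred codon per family and
  concentrates usage on it with weight exp(selection_strength); such genes
  fall well below the expected ENC curve.
* ``mixed`` — log-linear interpolation midway between the two weight sets.

The neutrality coupling is built in by exponential tilting of the
amino-acid composition: each gene's target GC12 is an affine function of
its expected measured GC3, and the tilt parameter is solved exactly against
the gene's own within-family codon distribution. Because measured GC3 is a
noisy realisation of the latent pressure (finite gene length), the latent
coupling is inflated by the analytic errors-in-variables factor
``1 + noise_var / signal_var`` so that the regression of measured GC12 on
measured GC3 has slope ``neutrality_slope`` in expectation. Identical
seed + config gives byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import datasets
from .genetic_code import STANDARD_CODE, GeneticCode, STOP_CODONS, rna_to_dna
from .sequences import CodingSequence

REGIMES = ("mutation_only", "selection", "mixed")
_REGIME_MIX = {"mutation_only": 0.0, "mixed": 0.5, "selection": 1.0}


def _default_aa_freqs(code: GeneticCode = STANDARD_CODE) -> Dict[str, float]:
    """Amino-acid frequencies from the bundled sunflower WRKY family totals."""
    pooled = datasets.sunflower_wrky_counts()
    totals = {aa: pooled.family_total(aa) for aa in code.amino_acids}
    grand = sum(totals.values())
    return {aa: totals[aa] / grand for aa in code.amino_acids}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic gene set.

    Defaults mirror the sunflower WRKY family: 115 genes, ~375 codons each,
    per-gene GC3 pressure spanning 0.29-0.53, neutrality slope 0.35, and an
    amino-acid composition taken from the bundled reference counts.
    """

    seed: int
    n_genes: int = 115
    mean_length: int = 375       # codons
    length_sd: float = 60.0      # codons
    min_length: int = 30         # codons
    regime: str = "mutation_only"
    gc3_range: Tuple[float, float] = (0.29, 0.53)
    neutrality_slope: float = 0.35
    base_gc12: float = 0.4533
    selection_strength: float = 3.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        lo, hi = self.gc3_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"gc3_range must be a non-degenerate interval in (0,1), got {self.gc3_range}")
        if self.min_length < 30:
            raise ValueError("min_length must be >= 30 codons")

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _codon_probs(
    code: GeneticCode,
    g: float,
    mix: float,
    selection_strength: float,
    preferred: Dict[str, str],
) -> Dict[str, Tuple[Tuple[str, ...], np.ndarray]]:
    """Per-amino-acid (codons, probabilities) under the regime weights."""
    out = {}
    for aa in code.amino_acids:
        codons = code.families[aa]
        n_gc = sum(1 for c in codons if c[2] in "GC") or 1
        n_au = sum(1 for c in codons if c[2] not in "GC") or 1
        logw = np.zeros(len(codons))
        for i, codon in enumerate(codons):
            # P(third position in GC | family) = g for every synonymous family
            w_mut = g / n_gc if codon[2] in "GC" else (1.0 - g) / n_au
            logw[i] = (1.0 - mix) * math.log(w_mut)
            if mix > 0.0 and preferred.get(aa) == codon:
                logw[i] += mix * selection_strength
        p = np.exp(logw - logw.max())
        out[aa] = (codons, p / p.sum())
    return out


def _expected_gc3(probs, p0: np.ndarray, aas: List[str]) -> float:
    """Expected measured GC3 (over sense codons) under amino-acid freqs p0."""
    total = 0.0
    for p_aa, aa in zip(p0, aas):
        fam, p = probs[aa]
        total += p_aa * sum(pi for codon, pi in zip(fam, p) if codon[2] in "GC")
    return float(total)


def _pos12_gc_expectation(probs) -> Dict[str, float]:
    """Expected GC fraction at positions 1-2 for each amino acid."""
    e = {}
    for aa, (codons, p) in probs.items():
        e[aa] = float(sum(
            pi * sum(b in "GC" for b in codon[:2]) / 2.0 for codon, pi in zip(codons, p)
        ))
    return e


def _solve_tilt(p0: np.ndarray, e: np.ndarray, target: float) -> float:
    """Tilt theta such that the exp-tilted mean of e equals target."""
    lo_val, hi_val = float(e.min()), float(e.max())
    if hi_val - lo_val < 1e-12:
        return 0.0
    eps = 1e-4 * (hi_val - lo_val)
    target = min(max(target, lo_val + eps), hi_val - eps)

    def tilted_mean(theta: float) -> float:
        w = p0 * np.exp(theta * (e - hi_val))
        return float((w * e).sum() / w.sum())

    lo, hi = -60.0, 60.0
    while tilted_mean(lo) > target and lo > -500:
        lo *= 2
    while tilted_mean(hi) < target and hi < 500:
        hi *= 2
    if tilted_mean(lo) > target or tilted_mean(hi) < target:
        return lo if tilted_mean(lo) > target else hi
    return float(brentq(lambda t: tilted_mean(t) - target, lo, hi, xtol=1e-10))


def generate(
    config: SyntheticConfig, code: GeneticCode = STANDARD_CODE
) -> Tuple[List[CodingSequence], pd.DataFrame]:
    """Generate a CDS set plus its ground-truth record.

    Returns (sequences, truth) where truth carries one row per gene:
    gene_id, regime, g (the third-position GC pressure), target_gc12,
    tilt theta, length in codons, and the preferred-codon map (empty under
    mutation_only).
    """
    rng = np.random.default_rng(config.seed)
    mix = _REGIME_MIX[config.regime]
    aa_freqs = _default_aa_freqs(code)
    aas = list(code.amino_acids)
    p0 = np.array([aa_freqs[aa] for aa in aas])
    g_lo, g_hi = config.gc3_range
    g_mid = (g_lo + g_hi) / 2.0
    width = max(2, len(str(config.n_genes)))

    # GC12 couples to the gene's expected measured GC3 (mutation weights).
    # Measured GC3 carries sampling noise of order sqrt(s(1-s)/L), which
    # would attenuate the fitted slope; inflate the latent coupling by the
    # errors-in-variables factor (capped for near-degenerate pressure
    # ranges, where no finite coupling can defeat the noise).
    def ghat(x: float) -> float:
        return _expected_gc3(_codon_probs(code, x, 0.0, 0.0, {}), p0, aas)

    ghat_mid = ghat(g_mid)
    response = (ghat(g_hi) - ghat(g_lo)) / (g_hi - g_lo)
    signal_var = response ** 2 * (g_hi - g_lo) ** 2 / 12.0
    noise_var = ghat_mid * (1.0 - ghat_mid) / config.mean_length
    inflation = min(1.0 + noise_var / signal_var, 2.0) if signal_var > 0 else 1.0
    coupling = config.neutrality_slope * inflation

    sequences: List[CodingSequence] = []
    truth_rows = []
    for idx in range(config.n_genes):
        gene_id = f"synth_{idx + 1:0{width}d}"
        g = float(rng.uniform(*config.gc3_range))
        length = max(config.min_length, int(round(rng.normal(config.mean_length, config.length_sd))))
        preferred: Dict[str, str] = {}
        if mix > 0.0:
            for aa in aas:
                fam = code.families[aa]
                if len(fam) > 1:
                    preferred[aa] = fam[rng.integers(len(fam))]
        probs = _codon_probs(code, g, mix, config.selection_strength, preferred)
        e_map = _pos12_gc_expectation(probs)
        e = np.array([e_map[aa] for aa in aas])
        expected_gc3 = ghat(g)
        target_gc12 = config.base_gc12 + coupling * (expected_gc3 - ghat_mid)
        theta = _solve_tilt(p0, e, target_gc12)
        w = p0 * np.exp(theta * (e - e.max()))
        p_tilt = w / w.sum()

        aa_idx = rng.choice(len(aas), size=length, p=p_tilt)
        codons = []
        for ai in aa_idx:
            fam, fam_p = probs[aas[ai]]
            codons.append(fam[rng.choice(len(fam), p=fam_p)])
        stop_w = np.array([g if s[2] in "GC" else (1.0 - g) / 2.0 for s in STOP_CODONS])
        stop = STOP_CODONS[rng.choice(len(STOP_CODONS), p=stop_w / stop_w.sum())]
        dna = rna_to_dna("".join(codons) + stop)
        sequences.append(CodingSequence(gene_id=gene_id, sequence=dna))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "regime": config.regime,
                "g": g,
                "expected_gc3": expected_gc3,
                "target_gc12": target_gc12,
                "theta": theta,
                "n_codons": length,
                "preferred_codons": ";".join(
                    f"{aa}={c}" for aa, c in sorted(preferred.items())
                ),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return sequences, truth
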