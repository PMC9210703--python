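"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import codonbias as cb
from codonbias import datasets
from codonbias.genetic_code import STANDARD_CODE


@pytest.fixture(scope="session")
def code():
    return STANDARD_CODE


@pytest.fixture(scope="session")
def pooled_reference():
    """Genome-wide pooled codon counts of the bundled sunflower WRKY set."""
    return datasets.sunflower_wrky_counts()


@pytest.fixture(scope="session")
def expression_pools():
    """(high-expression, low-expression) pooled counts from the bundled set."""
    return datasets.sunflower_wrky_expression_pools()


@pytest.fixture(scope="session")
def mutation_set():
    """Default 115-gene mutation-pressure synthetic set with ground truth."""
    cfg = cb.SyntheticConfig(seed=20260930)
    seqs, truth = cb.generate(cfg)
    return cfg, seqs, truth


@pytest.fixture(scope="session")
def selection_set():
    """115-gene selection-regime synthetic set."""
    cfg = cb.SyntheticConfig(seed=7151, regime="selection")
    seqs, truth = cb.generate(cfg)
    return cfg, seqs, truth


def random_count_table(rng: np.random.Generator, max_count: int = 30) -> cb.CodonCountTable:
    """A random per-gene codon count table over all 61 sense codons."""
    return cb.CodonCountTable(
        {c: int(rng.integers(0, max_count + 1)) for c in STANDARD_CODE.sense_codons}
    )


def oracle_enc(table: cb.CodonCountTable) -> float:
    """Independent ENC re-implementation (pandas route) used as an oracle.

    Same estimator and conventions as the library — per-family homozygosity
    F = (n * sum p^2 - 1)/(n - 1) for n >= 2, class means, Ile imputed as
    (F2 + F4)/2, other missing classes as the mean of available ones, cap at
    61 — but written independently over a tidy DataFrame.
    """
    rows = [
        {"codon": c, "aa": STANDARD_CODE.codon_to_aa[c], "n": table.counts[c]}
        for c in STANDARD_CODE.sense_codons
    ]
    df = pd.DataFrame(rows)
    df["k"] = df["aa"].map(lambda a: len(STANDARD_CODE.families[a]))
    df = df[df["k"] >= 2]
    fam = df.groupby("aa").agg(k=("k", "first"), n=("n", "sum"))
    per_fam = {}
    for aa, grp in df.groupby("aa"):
        n = grp["n"].sum()
        if n < 2:
            continue
        p2 = ((grp["n"] / n) ** 2).sum()
        per_fam[aa] = (n * p2 - 1.0) / (n - 1.0)
    class_f = {}
    for k in (2, 3, 4, 6):
        vals = [f for aa, f in per_fam.items() if fam.loc[aa, "k"] == k]
        m = float(np.mean(vals)) if vals else None
        class_f[k] = m if (m is None or m > 0) else None
    have = [v for v in class_f.values() if v is not None]
    if not have:
        return float("nan")
    if class_f[3] is None and class_f[2] is not None and class_f[4] is not None:
        class_f[3] = (class_f[2] + class_f[4]) / 2.0
    for k in class_f:
        if class_f[k] is None:
            class_f[k] = float(np.mean(have))
    value = 2 + 9 / class_f[2] + 1 / class_f[3] + 5 / class_f[4] + 3 / class_f[6]
    return min(value, 61.0)
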