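"""Neutrality fit, ENC plot, PR2 coordinates and index correlations."""

import math

import numpy as np
import pandas as pd
import pytest

import codonbias as cb
from codonbias.evolution import PR2_FAMILIES, correlation_matrix, enc_plot, neutrality_fit, pr2


# ---------------------------------------------------------------- neutrality

def test_perfect_line_recovered_exactly():
    x = np.linspace(0.2, 0.6, 20)
    fit = neutrality_fit(x, 0.5 * x + 0.2)
    assert fit.slope == pytest.approx(0.5)
    assert fit.intercept == pytest.approx(0.2)
    assert fit.pearson_r == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(fit.pearson_r ** 2)


def test_identity_points_give_unit_slope():
    x = np.linspace(0.1, 0.9, 10)
    fit = neutrality_fit(x, x)
    assert fit.slope == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_independent_columns_show_no_coupling():
    rng = np.random.default_rng(11)
    fit = neutrality_fit(rng.uniform(0.3, 0.5, 300), rng.uniform(0.4, 0.5, 300))
    assert abs(fit.pearson_r) < 0.15
    assert fit.p_value > 0.01


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        neutrality_fit([0.4, 0.4, 0.4], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        neutrality_fit([0.4, 0.5], [0.1, 0.2])


def test_interpretation_labels():
    x = np.linspace(0.2, 0.6, 50)
    rng = np.random.default_rng(0)
    steep = neutrality_fit(x, 0.9 * x + 0.01 * rng.normal(size=50))
    assert "mutation" in steep.interpretation()
    flat = neutrality_fit(x, 0.45 + 0.01 * rng.normal(size=50))
    assert "selection" in flat.interpretation()


# ---------------------------------------------------------------- ENC plot

def _indices_frame(enc_values, gc3s_values):
    return pd.DataFrame(
        {"enc": enc_values, "gc3s": gc3s_values},
        index=[f"g{i}" for i in range(len(enc_values))],
    )


def test_gene_on_curve_has_zero_deviation():
    df = _indices_frame([cb.expected_enc(0.4)], [0.4])
    records, summary, _ = enc_plot(df)
    assert records["rel_deviation"].iloc[0] == pytest.approx(0.0)
    assert summary["fraction_within_band"] == 1.0


def test_summary_fractions_partition():
    gc3s = [0.3, 0.35, 0.4, 0.45]
    encs = [cb.expected_enc(s) for s in gc3s]
    encs[0] -= 10.0   # below curve -> rel_deviation > 0
    encs[1] += 3.0    # above curve -> rel_deviation < 0
    records, summary, hist = enc_plot(_indices_frame(encs, gc3s))
    frac_zero = (records["rel_deviation"] == 0).mean()
    assert summary["fraction_below_zero"] + summary["fraction_above_zero"] == pytest.approx(
        1.0 - frac_zero
    )
    assert records["rel_deviation"].lt(1.0).all()
    assert hist["n_genes"].sum() == len(records)


# ---------------------------------------------------------------- PR2

def test_pr2_center_for_balanced_usage():
    table = cb.CodonCountTable(
        {c: 2 for fam in PR2_FAMILIES.values() for c in fam}
    )
    point = pr2(table, gene_id="balanced")
    assert point.at_bias == pytest.approx(0.5)
    assert point.gc_bias == pytest.approx(0.5)
    assert point.at3_fraction + point.gc3_fraction == pytest.approx(1.0)


def test_pr2_undefined_axis_flagged():
    # Ala only, GCU and GCA equally: no G/C third positions at all
    point = pr2(cb.CodonCountTable({"GCU": 3, "GCA": 3}))
    assert point.at_bias == pytest.approx(0.5)
    assert math.isnan(point.gc_bias)


def test_pr2_hand_tally():
    # 12 qualifying codons with known third-position tallies:
    # A3 = 3 (GCA 2, CCA 1), T3 = 4 (ACU), G3 = 3 (GUG), C3 = 2 (CGC)
    table = cb.CodonCountTable({"GCA": 2, "CCA": 1, "ACU": 4, "GUG": 3, "CGC": 2})
    p = pr2(table)
    assert (p.a3, p.t3, p.g3, p.c3) == (3, 4, 3, 2)
    assert p.at_bias == pytest.approx(3 / 7)
    assert p.gc_bias == pytest.approx(3 / 5)
    assert p.at3_fraction == pytest.approx(7 / 12)


def test_pr2_excludes_non_four_codon_subfamilies():
    # AGA/AGG (Arg), AGU/AGC (Ser), UUA/UUG (Leu) are outside the PR2 set
    table = cb.CodonCountTable({"AGA": 5, "AGU": 5, "UUA": 5})
    with pytest.raises(ValueError):
        pr2(table, gene_id="excluded")


def test_pr2_pooling_is_count_weighted():
    t1 = cb.CodonCountTable({"GCA": 4, "GCG": 1})
    t2 = cb.CodonCountTable({"GCU": 2, "GCC": 3})
    pooled = pr2(t1 + t2)
    assert (pooled.a3, pooled.t3, pooled.g3, pooled.c3) == (4, 2, 1, 3)


def test_pr2_summary_methods(mutation_set):
    _, seqs, _ = mutation_set
    points = cb.pr2_frame({s.gene_id: cb.count_codons(s) for s in seqs[:30]})
    per_gene = cb.pr2_summary(points, method="per_gene")
    pooled = cb.pr2_summary(points, method="pooled")
    for summary in (per_gene, pooled):
        assert summary["mean_at3_fraction"] + summary["mean_gc3_fraction"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cb.pr2_summary(points, method="median")


# ---------------------------------------------------------------- correlations

def test_duplicated_column_perfectly_correlated():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
    corr = correlation_matrix(df)
    assert corr.r.loc["a", "b"] == pytest.approx(1.0)
    assert corr.flags.loc["a", "b"] == "**"
    assert np.allclose(corr.r.values, corr.r.values.T, equal_nan=True)
    assert (np.diag(corr.r.values) == 1.0).all()


def test_affine_rescaling_invariance():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
    scaled = df.copy()
    scaled["y"] = 3.5 * scaled["y"] - 2.0
    a, b = correlation_matrix(df), correlation_matrix(scaled)
    assert np.allclose(a.r.values, b.r.values)


def test_constant_column_flagged_undefined():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "k": [5.0] * 4})
    corr = correlation_matrix(df)
    assert math.isnan(corr.r.loc["x", "k"])
    assert corr.flags.loc["x", "k"] == ""


def test_gc3_and_gc3s_structurally_correlated(mutation_set):
    _, seqs, _ = mutation_set
    df = cb.profile_frame(seqs)
    corr = correlation_matrix(df[["gc3", "gc3s"]])
    assert corr.r.loc["gc3", "gc3s"] > 0.9


def test_type_one_error_rate_near_nominal():
    # independent columns at n = 115: ~5% of pairs flagged at the 0.05 level
    rng = np.random.default_rng(17)
    flagged = total = 0
    for _ in range(40):
        df = pd.DataFrame(rng.normal(size=(115, 5)))
        corr = correlation_matrix(df)
        upper = np.triu_indices(5, k=1)
        flagged += (corr.p.values[upper] < 0.05).sum()
        total += len(upper[0])
    rate = flagged / total
    assert 0.01 < rate < 0.10
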