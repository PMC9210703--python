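"""RSCU, ENC and CAI behaviour beyond the worked-example checks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import codonbias as cb
from codonbias.genetic_code import STANDARD_CODE
from codonbias.usage import _family_homozygosity, cai, cai_weights, enc, expected_enc, rscu

from conftest import oracle_enc, random_count_table


# ---------------------------------------------------------------- RSCU

def test_uniform_family_usage_gives_rscu_one(code):
    table = cb.CodonCountTable({c: 7 for c in code.synonymous_codons})
    t = rscu(table)
    syn = t.loc[list(code.synonymous_codons)]
    assert (syn["rscu"] == 1.0).all()
    assert not syn["preferred"].any()


def test_single_codon_amino_acids_fixed_at_one_and_unclassified():
    t = rscu(cb.CodonCountTable({"AUG": 10, "UGG": 3, "GCA": 4}))
    assert t.loc["AUG", "rscu"] == 1.0 == t.loc["UGG", "rscu"]
    assert not t.loc["AUG", "preferred"]
    # GCA is the only Ala codon observed: RSCU = 4 / (4/4) = 4
    assert t.loc["GCA", "rscu"] == pytest.approx(4.0)
    assert t.loc["GCA", "over_represented"]


def test_unobserved_family_reported_missing():
    t = rscu(cb.CodonCountTable({"GCA": 3}))
    assert math.isnan(t.loc["AAA", "rscu"])
    assert not t.loc["AAA", "preferred"]


def test_freq_per_1000_sums_to_1000(pooled_reference):
    t = rscu(pooled_reference, include_stops=True)
    assert t["freq_per_1000"].sum() == pytest.approx(1000.0)
    assert len(t) == 64
    assert len(rscu(pooled_reference, include_stops=False)) == 61


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_rscu_family_sums_equal_degeneracy(seed):
    rng = np.random.default_rng(seed)
    table = random_count_table(rng)
    t = rscu(table)
    for aa in STANDARD_CODE.amino_acids:
        family = list(STANDARD_CODE.families[aa])
        if table.family_total(aa) > 0:
            assert t.loc[family, "rscu"].sum() == pytest.approx(len(family))


def test_rscu_scale_invariance():
    rng = np.random.default_rng(5)
    table = random_count_table(rng)
    a = rscu(table)["rscu"].fillna(-1.0)
    b = rscu(table.scaled(7))["rscu"].fillna(-1.0)
    assert np.allclose(a, b, atol=1e-12)


# ---------------------------------------------------------------- ENC

def test_family_homozygosity_hand_case():
    # two-codon family with counts (3, 1): F = (4*(9/16 + 1/16) - 1)/3 = 0.5
    assert _family_homozygosity([3, 1]) == pytest.approx(0.5)
    assert _family_homozygosity([1, 0]) is None  # n < 2 unusable


def test_enc_endpoints(code):
    one_per_family = cb.CodonCountTable(
        {code.families[aa][0]: 5 for aa in code.amino_acids}
    )
    assert enc(one_per_family) == pytest.approx(20.0)
    equal_usage = cb.CodonCountTable({c: 10 for c in code.sense_codons})
    assert enc(equal_usage) == pytest.approx(61.0)


def test_enc_undefined_for_met_trp_only_gene():
    assert math.isnan(enc(cb.CodonCountTable({"AUG": 5, "UGG": 5})))


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_enc_bounds_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    value = enc(random_count_table(rng))
    assert math.isnan(value) or 20.0 - 1e-9 <= value <= 61.0


def test_enc_monotone_under_concentration(code):
    # shifting a two-codon family's usage onto one codon never raises ENC
    base = {c: 6 for c in code.sense_codons}
    values = []
    for split in [(3, 3), (4, 2), (5, 1), (6, 0)]:
        table = cb.CodonCountTable({**base, "AAA": split[0], "AAG": split[1]})
        values.append(oracle_enc(table))
        assert enc(table) == pytest.approx(values[-1], abs=1e-9)
    assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


def test_enc_matches_independent_oracle():
    rng = np.random.default_rng(1234)
    for _ in range(200):
        table = random_count_table(rng)
        mine, theirs = enc(table), oracle_enc(table)
        if math.isnan(mine):
            assert math.isnan(theirs)
        else:
            assert mine == pytest.approx(theirs, abs=1e-9)


def test_enc_scaling_converges_to_large_count_limit():
    # F-hat = (n*sum p^2 - 1)/(n - 1) rises toward sum p^2 as counts scale,
    # so ENC decreases monotonically toward its infinite-count value
    rng = np.random.default_rng(99)
    table = random_count_table(rng)
    e1, e10, e100 = enc(table), enc(table.scaled(10)), enc(table.scaled(100))
    assert e1 + 1e-9 >= e10 >= e100 - 1e-9
    assert abs(e100 - e10) < abs(e1 - e10)


# ---------------------------------------------------------------- expected ENC

def test_expected_enc_printed_formula_values():
    assert expected_enc(0.5) == pytest.approx(60.5)
    # near the composition extremes the curve drops toward ~31 / ~32
    assert expected_enc(1e-6) == pytest.approx(31.0, abs=0.01)
    assert expected_enc(1 - 1e-6) == pytest.approx(32.0, abs=0.01)


def test_expected_enc_symmetric_homozygosity_term():
    for x in (0.1, 0.25, 0.4):
        left = expected_enc(x) - 2 - x
        right = expected_enc(1 - x) - 2 - (1 - x)
        assert left == pytest.approx(right)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
def test_expected_enc_domain(bad):
    with pytest.raises(ValueError):
        expected_enc(bad)


# ---------------------------------------------------------------- CAI

def test_cai_one_for_reference_maximal_usage(pooled_reference, code):
    weights = cai_weights(pooled_reference)
    best = {}
    for aa in code.amino_acids:
        fam = code.families[aa]
        if len(fam) > 1:
            best[max(fam, key=lambda c: weights[c])] = 10
    assert cai(cb.CodonCountTable(best), weights) == pytest.approx(1.0)


def test_cai_single_codon_gene_equals_its_weight(pooled_reference):
    weights = cai_weights(pooled_reference)
    gene = cb.CodonCountTable({"GCA": 1})
    assert cai(gene, weights) == pytest.approx(weights["GCA"])


def test_cai_matches_direct_geometric_mean(pooled_reference):
    weights = cai_weights(pooled_reference)
    gene = cb.CodonCountTable({"GCA": 3, "GCC": 1, "AAA": 2, "AUG": 5})
    expected = math.exp(
        (3 * math.log(weights["GCA"]) + math.log(weights["GCC"]) + 2 * math.log(weights["AAA"])) / 6
    )
    assert cai(gene, weights) == pytest.approx(expected)


def test_cai_scale_invariance_and_range(pooled_reference):
    weights = cai_weights(pooled_reference)
    rng = np.random.default_rng(3)
    table = random_count_table(rng)
    v = cai(table, weights)
    assert 0.0 < v <= 1.0
    assert cai(table.scaled(9), weights) == pytest.approx(v)


def test_cai_weights_floor_for_unseen_codons(code):
    # reference observing one codon per family floors the others at 0.01
    ref = cb.CodonCountTable({code.families[aa][0]: 50 for aa in code.amino_acids})
    weights = cai_weights(ref)
    assert weights[code.families["A"][0]] == pytest.approx(1.0)
    assert weights[code.families["A"][1]] == pytest.approx(0.01)


def test_cai_weights_require_every_family():
    with pytest.raises(ValueError):
        cai_weights(cb.CodonCountTable({"GCA": 5}))
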