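"""Unit and property tests for the abundance-based metrics."""

import math

import numpy as np
import pandas as pd
import pytest
import skbio.diversity.alpha as ska
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from alphadiv import alpha_metrics as am
from conftest import random_count_vector

HAND_VALUES = [
    (am.observed_features, [5, 1, 0, 2], 3),
    (am.observed_features, [7], 1),
    (am.singleton_count, [1, 1, 2, 5], 2),
    (am.doubleton_count, [1, 1, 2, 5], 1),
    (am.singleton_count, [3, 4], 0),
    (am.chao1, [4, 3, 2], 3.0),
    (am.chao1, [4, 3, 2, 2, 1, 1, 1, 1], 12.0),
    (am.chao1, [1, 1], 3.0),  # bias-corrected fallback at F2=0
    (am.ace, [15, 12, 1, 1, 2], 8.0),
    (am.margalef, [50, 30, 20], 2 / math.log(100)),
    (am.margalef, [9], 0.0),
    (am.menhinick, [8, 4, 2, 2], 1.0),
    (am.menhinick, [1], 1.0),
    (am.robbins, [1, 1, 1, 5], 3 / 9),
    (am.berger_parker, [8, 1, 1], 0.8),
    (am.berger_parker, [7], 1.0),
    (am.simpson, [8, 1, 1], 0.34),
    (am.simpson, [2, 2], 0.5),
    (am.simpson, [7], 0.0),
    (am.dominance_index, [8, 1, 1], 0.66),
    (am.dominance_index, [7], 1.0),
    (am.enspie, [8, 1, 1], 1 / 0.66),
    (am.enspie, [7], 1.0),
    (am.gini, [3, 1], 0.25),
    (am.gini, [9], 0.0),
    (am.mcintosh_dominance, [8, 1, 1], (10 - math.sqrt(66)) / (10 - math.sqrt(10))),
    (am.mcintosh_dominance, [1, 1, 1, 1], 1.0),
    (am.strong, [8, 1, 1], 0.8 - 1 / 3),
    (am.strong, [9], 0.0),
    (am.shannon, [1, 1, 1, 1], 2.0),
    (am.shannon, [7], 0.0),
    (am.brillouin, [1, 1], math.log(2) / 2),
    (am.brillouin, [9], 0.0),
    (am.pielou, [2, 2], 1.0),
]


@pytest.mark.parametrize("func,counts,expected", HAND_VALUES)
def test_hand_computed_values(func, counts, expected):
    assert func(counts) == pytest.approx(expected, abs=1e-12)


def test_robbins_features_variant():
    assert am.robbins([1, 1, 1, 5], denominator="features") == pytest.approx(0.6)
    assert am.robbins([3, 4]) == 0.0
    assert am.robbins([3, 4], denominator="features") == 0.0
    with pytest.raises(ValueError, match="denominator"):
        am.robbins([1, 2], denominator="taxa")


def test_shannon_natural_base_and_derived_evenness():
    h = am.shannon([8, 1, 1], base=math.e)
    assert h == pytest.approx(0.639032, abs=1e-6)
    assert am.heip([8, 1, 1]) == pytest.approx((math.exp(h) - 1) / 2, abs=1e-12)
    assert am.pielou([8, 1, 1]) == pytest.approx(h / math.log(3), abs=1e-12)


def test_pielou_base_invariance(rng):
    for _ in range(20):
        c = random_count_vector(rng)
        base2 = am.shannon(c, base=2) / math.log2(am.observed_features(c))
        assert am.pielou(c) == pytest.approx(base2, abs=1e-12)


@pytest.mark.parametrize("func", [
    am.observed_features, am.chao1, am.ace, am.margalef, am.menhinick,
    am.robbins, am.berger_parker, am.simpson, am.gini, am.strong,
    am.shannon, am.brillouin,
])
def test_all_zero_vector_rejected(func):
    with pytest.raises(ValueError):
        func([0, 0, 0])


def test_integer_requirement():
    for func in (am.chao1, am.ace, am.brillouin):
        with pytest.raises(ValueError, match="integer"):
            func([1.5, 2.0])


def test_ace_undefined_when_all_rare_are_singletons():
    with pytest.raises(ValueError, match="ACE undefined"):
        am.ace([1, 1, 1])


def test_ace_equals_s_without_rare_correction():
    # every taxon above the rare threshold: no correction applies
    assert am.ace([50, 40, 30, 20]) == 4.0


def test_fisher_alpha_bracketed_example():
    alpha = am.fisher_alpha([2, 2])
    assert 1.5 < alpha < 1.7
    assert abs(alpha * math.log(1 + 4 / alpha) - 2) < 1e-8


def test_fisher_alpha_residual_and_errors(rng):
    for _ in range(50):
        c = random_count_vector(rng)
        if am.observed_features(c) >= c.sum():
            continue
        alpha = am.fisher_alpha(c)
        s, n = am.observed_features(c), c.sum()
        assert abs(alpha * math.log(1 + n / alpha) - s) < 1e-8
    with pytest.raises(ValueError, match="diverges"):
        am.fisher_alpha([1, 1])
    with pytest.raises(ValueError):
        am.fisher_alpha([5])


def test_evenness_missing_for_single_taxon():
    assert math.isnan(am.heip([7]))
    assert math.isnan(am.pielou([7]))


def test_mcintosh_single_read_error():
    with pytest.raises(ValueError):
        am.mcintosh_dominance([1])


def test_simpson_complement_and_inverse_identities(rng):
    for _ in range(1000):
        c = random_count_vector(rng, max_s=30, max_count=500)
        d = am.dominance_index(c)
        assert am.simpson(c) + d == pytest.approx(1.0, abs=1e-12)
        assert am.enspie(c) * d == pytest.approx(1.0, abs=1e-12)


@given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=30)
       .filter(lambda c: sum(1 for x in c if x > 0) >= 2 and sum(c) > len([x for x in c if x > 0])))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_permutation_and_zero_padding_invariance(counts):
    reordered = list(reversed(counts))
    padded = list(counts) + [0, 0, 0]
    for func in (am.chao1, am.margalef, am.menhinick, am.berger_parker,
                 am.simpson, am.gini, am.strong, am.shannon, am.brillouin,
                 am.pielou, am.heip):
        v = func(counts)
        assert func(reordered) == pytest.approx(v, nan_ok=True, abs=1e-12)
        assert func(padded) == pytest.approx(v, nan_ok=True, abs=1e-12)


def test_scale_invariance_of_relative_metrics(rng):
    invariant = [am.berger_parker, am.simpson, am.dominance_index, am.enspie,
                 am.gini, am.strong, am.pielou, am.shannon]
    for _ in range(50):
        c = random_count_vector(rng, max_s=20, max_count=200)
        scaled = c * 7
        for func in invariant:
            assert func(scaled) == pytest.approx(func(c), abs=1e-12)


def test_scale_behavior_of_absolute_metrics(rng):
    # doubling all counts moves N-dependent metrics exactly as their formulas say
    for _ in range(20):
        c = random_count_vector(rng, max_s=20, max_count=200)
        s, n = am.observed_features(c), c.sum()
        assert am.menhinick(2 * c) == pytest.approx(am.menhinick(c) / math.sqrt(2))
        if s >= 2:
            assert am.margalef(2 * c) == pytest.approx((s - 1) / math.log(2 * n))


def test_uniform_community_closed_forms():
    for s in (2, 5, 16, 100):
        c = [7] * s
        assert am.shannon(c) == pytest.approx(math.log2(s), abs=1e-12)
        assert am.pielou(c) == pytest.approx(1.0, abs=1e-12)
        assert am.heip(c) == pytest.approx(1.0, abs=1e-12)
        assert am.berger_parker(c) == pytest.approx(1 / s, abs=1e-12)
        assert am.enspie(c) == pytest.approx(s, abs=1e-12)
        assert am.gini(c) == pytest.approx(0.0, abs=1e-12)
        assert am.strong(c) == pytest.approx(0.0, abs=1e-12)


def test_chao1_never_below_observed(rng):
    for _ in range(200):
        c = random_count_vector(rng)
        s = am.observed_features(c)
        assert am.chao1(c) >= s
        no_singletons = c[c != 1]
        if no_singletons.size and no_singletons.sum() > 0:
            assert am.chao1(no_singletons) == am.observed_features(no_singletons)


def test_brillouin_below_natural_shannon(rng):
    # finite-population entropy never exceeds the plug-in entropy
    for _ in range(200):
        c = random_count_vector(rng)
        assert am.brillouin(c) <= am.shannon(c, base=math.e) + 1e-12


def test_agreement_with_naive_oracles(rng):
    funcs = {
        "observed_features": am.observed_features, "chao1": am.chao1,
        "ace": am.ace, "fisher_alpha": am.fisher_alpha,
        "margalef": am.margalef, "menhinick": am.menhinick,
        "robbins": am.robbins, "berger_parker": am.berger_parker,
        "simpson": am.simpson, "dominance": am.dominance_index,
        "enspie": am.enspie, "gini": am.gini, "mcintosh": am.mcintosh_dominance,
        "strong": am.strong, "shannon": am.shannon, "brillouin": am.brillouin,
        "heip": am.heip, "pielou": am.pielou,
    }
    for _ in range(300):
        c = random_count_vector(rng, max_s=40, max_count=500)
        for name, func in funcs.items():
            oracle = oracles.ABUNDANCE_ORACLES[name]
            try:
                expected = oracle(c)
            except ValueError:
                with pytest.raises(ValueError):
                    func(c)
                continue
            tol = 1e-6 if name == "fisher_alpha" else 1e-9
            assert func(c) == pytest.approx(expected, rel=tol, abs=tol, nan_ok=True), name


def test_agreement_with_scikit_bio(rng):
    """Independent library cross-check (gini excluded: scikit-bio uses a
    Lorenz-curve integral, a different estimator)."""
    pairs = [
        (lambda c: am.margalef(c), ska.margalef),
        (am.menhinick, ska.menhinick), (am.berger_parker, ska.berger_parker_d),
        (am.simpson, ska.simpson), (am.dominance_index, ska.dominance),
        (am.enspie, ska.enspie), (am.mcintosh_dominance, ska.mcintosh_d),
        (am.strong, ska.strong), (lambda c: am.shannon(c, 2), lambda c: ska.shannon(c, base=2)),
        (am.brillouin, ska.brillouin_d), (am.heip, ska.heip_e),
        (am.pielou, ska.pielou_e),
    ]
    for _ in range(100):
        c = random_count_vector(rng, max_s=30, max_count=300)
        for mine, theirs in pairs:
            assert mine(c) == pytest.approx(float(theirs(c)), rel=1e-9, abs=1e-9)
        rare = c[(c > 0) & (c <= 10)]
        if rare.size == 0 or (rare > 1).any():  # ACE defined
            assert am.ace(c) == pytest.approx(float(ska.ace(c)), rel=1e-9, abs=1e-9)
        if am.doubleton_count(c) > 0:
            assert am.chao1(c) == pytest.approx(float(ska.chao1(c, bias_corrected=False)))
        if am.observed_features(c) < c.sum():  # fisher defined
            assert am.fisher_alpha(c) == pytest.approx(float(ska.fisher_alpha(c)), rel=1e-5)


def test_registry_partition():
    reg = am.default_registry()
    assert len(reg.entries) == 19
    by_cat = {}
    for e in reg.entries:
        by_cat.setdefault(e.category, []).append(e.name)
    assert len(by_cat["richness"]) == 7
    assert len(by_cat["dominance"]) == 7
    assert len(by_cat["information"]) == 4
    assert by_cat["phylogenetic"] == ["faith_pd"]
    assert len(reg.without_tree_metrics().entries) == 18


def test_compute_all_without_tree(small_table):
    matrix = am.compute_all(small_table)
    assert matrix.values.shape == (3, 18)
    assert matrix.values.loc["s1", "observed_features"] == 3
    assert matrix.values.loc["s2", "berger_parker"] == pytest.approx(0.8)
    # uniform sample s3: evenness exactly 1
    assert matrix.values.loc["s3", "pielou"] == pytest.approx(1.0)


def test_compute_all_with_tree(small_table, four_tip_tree):
    matrix = am.compute_all(small_table, tree=four_tip_tree)
    assert matrix.values.shape == (3, 19)
    assert matrix.values.loc["s3", "faith_pd"] == pytest.approx(6.0)
    assert matrix.categories["faith_pd"] == "phylogenetic"


def test_compute_all_tree_required_but_missing(small_table):
    reg = am.default_registry(include_tree_metrics=True)
    with pytest.raises(ValueError, match="tree"):
        am.compute_all(small_table, tree=None, registry=reg)


def test_compute_all_all_zero_sample_becomes_missing_row(caplog):
    table_counts = pd.DataFrame([[3, 4], [0, 0]], index=["ok", "empty"],
                                columns=["A", "B"])
    from alphadiv.feature_io import FeatureTable
    with caplog.at_level("WARNING"):
        matrix = am.compute_all(FeatureTable(counts=table_counts))
    assert matrix.values.loc["empty"].isna().all()
    assert not matrix.values.loc["ok", ["shannon", "simpson"]].isna().any()
    assert any("all-zero" in r.message for r in caplog.records)


def test_compute_all_records_per_sample_failures_as_missing():
    # every taxon a singleton: fisher diverges, ACE undefined — row keeps going
    from alphadiv.feature_io import FeatureTable
    counts = pd.DataFrame([[1, 1, 1]], index=["s"], columns=list("ABC"))
    matrix = am.compute_all(FeatureTable(counts=counts))
    assert math.isnan(matrix.values.loc["s", "fisher_alpha"])
    assert math.isnan(matrix.values.loc["s", "ace"])
    assert matrix.values.loc["s", "observed_features"] == 3
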