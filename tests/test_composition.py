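"""Composition metrics, risk calls and group statistics."""

import itertools
from collections import Counter

import numpy as np
import pytest

import marrowmap as mm


def exact_ranksum_p(a, b):
    """Brute-force exact two-sided rank-sum p: enumerate every assignment of
    the pooled ranks to group a and compare U statistics."""
    pooled = list(a) + list(b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    n1 = len(a)
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(ranks[pooled[i]] for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestFractions:
    def test_known_mix(self):
        tax = mm.default_taxonomy()
        frac = mm.fractions(["T", "T", "B", "NK"], tax)
        assert frac["T"] == 0.5 and frac["B"] == 0.25 and frac["NK"] == 0.25
        assert frac.drop(["T", "B", "NK"]).eq(0).all()

    def test_single_label_is_one(self):
        frac = mm.fractions(["HSPC"] * 7, mm.default_taxonomy())
        assert frac["HSPC"] == 1.0

    def test_matches_counting_oracle_and_sums_to_one(self):
        tax = mm.default_taxonomy()
        rng = np.random.default_rng(0)
        labels = list(rng.choice(tax.labels, size=1000))
        frac = mm.fractions(labels, tax)
        tally = Counter(labels)
        for l in tax.labels:
            assert frac[l] == pytest.approx(tally[l] / 1000)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_adding_a_cell_increases_its_fraction(self):
        tax = mm.default_taxonomy()
        labels = ["T", "B", "NK"]
        before = mm.fractions(labels, tax)["T"]
        after = mm.fractions(labels + ["T"], tax)["T"]
        assert after > before

    def test_empty_and_unknown_labels_error(self):
        tax = mm.default_taxonomy()
        with pytest.raises(ValueError, match="empty"):
            mm.fractions([], tax)
        with pytest.raises(ValueError, match="Gremlin"):
            mm.fractions(["T", "Gremlin"], tax)


class TestMlRatio:
    def test_balanced_example_is_one(self):
        tax = mm.default_taxonomy()
        v = {"Neutrophil": 0.2, "Monocyte": 0.2, "T": 0.2, "B": 0.2}
        assert mm.ml_ratio(v, tax) == pytest.approx(1.0)

    def test_lymphoid_only_is_zero(self):
        assert mm.ml_ratio({"T": 1.0}, mm.default_taxonomy()) == 0.0

    def test_reciprocal_identity_on_random_vectors(self):
        tax = mm.default_taxonomy()
        myeloid, lymphoid = mm.lineage_fraction_sets(tax)
        rng = np.random.default_rng(5)
        for _ in range(25):
            v = rng.dirichlet(np.ones(len(tax.labels)))
            vec = dict(zip(tax.labels, v))
            m = sum(vec[l] for l in myeloid)
            l = sum(vec[l] for l in lymphoid)
            assert mm.ml_ratio(vec, tax) * (l / m) == pytest.approx(1.0)

    def test_zero_lymphoid_flagged_infinity(self):
        with pytest.warns(UserWarning, match="undefined-denominator"):
            r = mm.ml_ratio({"Neutrophil": 1.0}, mm.default_taxonomy())
        assert r == float("inf")

    def test_both_zero_is_error(self):
        with pytest.raises(ValueError):
            mm.ml_ratio({"HSPC": 1.0}, mm.default_taxonomy())


class TestRiskAndBurden:
    @pytest.mark.parametrize("mature, expected", [
        (0.05, "MDS_high"), (0.30, "MDS_low"), (0.10, "MDS_low"),
        (0.0999, "MDS_high"),
    ])
    def test_threshold_is_strict(self, mature, expected):
        assert mm.classify_risk(mature, threshold=0.10) == expected

    def test_monotone_in_mature_fraction(self):
        calls = [mm.classify_risk(x) for x in np.linspace(0, 1, 101)]
        flips = sum(a != b for a, b in zip(calls, calls[1:]))
        assert flips == 1 and calls[0] == "MDS_high" and calls[-1] == "MDS_low"

    def test_mutation_burden_closed_form(self):
        assert mm.mutation_burden(50, 1000) == pytest.approx(0.05)
        assert mm.mutation_burden(0, 500) == 0.0
        assert mm.mutation_burden(84, 700) == pytest.approx(
            2 * mm.mutation_burden(42, 700))

    def test_mutation_burden_errors(self):
        with pytest.raises(ValueError):
            mm.mutation_burden(5, 0)
        with pytest.raises(ValueError):
            mm.mutation_burden(-1, 10)


class TestSignificance:
    @pytest.mark.parametrize("p, stars", [
        (0.03, "*"), (0.0005, "***"), (0.05, "n.s."), (5e-5, "****"),
        (0.009, "**"), (0.01, "*"), (1e-3, "**"), (1e-4, "***"),
        (0.2, "n.s."), (0.0, "****"), (1.0, "n.s."),
    ])
    def test_star_convention_strict_thresholds(self, p, stars):
        assert mm.format_significance(p) == stars

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mm.format_significance(1.5)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        c = mm.compare_groups({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert c.p_value > 0.9
        assert c.stars == "n.s."

    def test_fully_separated_3v3_exact_p(self):
        c = mm.compare_groups({"a": [1, 2, 3], "b": [10, 11, 12]})
        assert c.p_value == pytest.approx(0.1)
        assert c.test == "wilcoxon"

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for n1, n2 in [(3, 3), (4, 3), (4, 5), (5, 5)]:
            a = rng.normal(size=n1)
            b = rng.normal(loc=0.8, size=n2)
            c = mm.compare_groups({"a": a, "b": b})
            assert c.p_value == pytest.approx(exact_ranksum_p(a, b)), (n1, n2)

    def test_t_test_against_scipy_welch(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(loc=1, size=6)
        c = mm.compare_groups({"a": a, "b": b}, test="t")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert c.p_value == pytest.approx(ref.pvalue)
        assert c.stars == mm.format_significance(ref.pvalue)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mm.compare_groups({"a": [], "b": [1.0]})


class TestCompositionTable:
    def test_fractions_sum_to_one_and_mature_consistent(self, preset_annotations):
        tax = mm.default_taxonomy()
        anns = [ann for ann, _ in preset_annotations.values()]
        table = mm.composition_table(anns, tax)
        label_cols = list(tax.labels)
        sums = table[label_cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        mature = table[list(tax.mature_myeloid)].sum(axis=1)
        assert np.allclose(table["mature_myeloid_fraction"], mature)
        assert (table["n_cells"] > 0).all()

    def test_preset_risk_calls(self, preset_annotations):
        tax = mm.default_taxonomy()
        anns = [ann for ann, _ in preset_annotations.values()]
        table = mm.composition_table(anns, tax).set_index("sample_id")
        calls = {sid.split("-")[0]: call
                 for sid, call in table["risk_call"].items()}
        assert calls["MDS_high"] == "MDS_high"
        assert calls["MDS_low"] == "MDS_low"
        assert calls["healthy"] == "MDS_low"
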