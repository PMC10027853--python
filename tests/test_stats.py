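import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from allotrack.errors import ValidationError
from allotrack.stats import (
    FrequencyVector,
    classify_dynamics,
    clone_frequencies,
    fisher_exact_twosided,
    fold_expansion,
    inverse_simpson,
    morisita_horn,
)
from conftest import random_counts
from oracles import fisher_twosided_exact
from test_clonotypes import make_bulk


def fv(counts: dict, sample_id="s") -> FrequencyVector:
    return FrequencyVector(sample_id, pd.Series(counts))


class TestFrequencies:
    def test_simple_normalization(self):
        rep = make_bulk([
            ("AAA", "K", "TRBV9", "TRBJ1-1", 5, True),
            ("CCC", "P", "TRBV9", "TRBJ1-1", 3, True),
            ("GGG", "G", "TRBV9", "TRBJ1-1", 2, True),
        ])
        f = clone_frequencies(rep)
        assert sorted(f.frequencies.to_numpy()) == pytest.approx([0.2, 0.3, 0.5])
        assert f.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_clone(self):
        f = clone_frequencies(make_bulk([("AAA", "K", "TRBV9", "TRBJ1-1", 7, True)]))
        assert f.frequencies.tolist() == [1.0]

    def test_nonproductive_excluded_from_both_sides(self):
        rep = make_bulk([
            ("AAA", "K", "TRBV9", "TRBJ1-1", 5, True),
            ("CCC", "P", "TRBV9", "TRBJ1-1", 5, False),
        ])
        f = clone_frequencies(rep)
        assert len(f.counts) == 1
        assert f.frequencies.tolist() == [1.0]

    def test_no_productive_templates_is_error(self):
        rep = make_bulk([("AAA", "K", "TRBV9", "TRBJ1-1", 5, False)])
        with pytest.raises(ValidationError):
            clone_frequencies(rep)


class TestInverseSimpson:
    @pytest.mark.parametrize("k", [1, 2, 4, 7, 100, 1000])
    def test_uniform_repertoire_equals_clone_count(self, k):
        f = fv({f"c{i}": 3 for i in range(k)})
        assert inverse_simpson(f) == pytest.approx(k)

    def test_hand_computed_value(self):
        # p = (0.5, 0.3, 0.2): sum p^2 = 0.38
        assert inverse_simpson(fv({"a": 5, "b": 3, "c": 2})) == pytest.approx(1 / 0.38)

    def test_monoclonal_is_one(self):
        assert inverse_simpson(fv({"a": 42})) == pytest.approx(1.0)


class TestMorisitaHorn:
    def test_self_overlap_is_one(self):
        x = fv({"a": 4, "b": 2, "c": 1})
        assert morisita_horn(x, x) == pytest.approx(1.0)

    def test_disjoint_sets_are_zero(self):
        assert morisita_horn(fv({"a": 5}), fv({"b": 5})) == 0.0

    def test_hand_computed_union_case(self):
        # x={A:2,B:2}, y={A:2}: 2*4 / ((0.5+1.0)*4*2) = 2/3
        assert morisita_horn(fv({"A": 2, "B": 2}), fv({"A": 2})) == pytest.approx(2 / 3)

    def test_bounds_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            x = FrequencyVector("x", random_counts(rng, int(rng.integers(2, 40)), 500) + 1)
            y = FrequencyVector("y", random_counts(rng, int(rng.integers(2, 40)), 500) + 1)
            mh = morisita_horn(x, y)
            assert 0.0 <= mh <= 1.0 + 1e-12
            assert mh == pytest.approx(morisita_horn(y, x), abs=1e-12)

    def test_downsampling_changes_overlap_little(self):
        rng = np.random.default_rng(23)
        counts = random_counts(rng, 300, 5000)
        counts = counts[counts > 0]
        full = FrequencyVector("full", counts)
        half_counts = pd.Series(
            rng.multinomial(counts.sum() // 2, (counts / counts.sum()).to_numpy()),
            index=counts.index,
        )
        half = FrequencyVector("half", half_counts[half_counts > 0])
        assert morisita_horn(full, half) > 0.95

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.dictionaries(st.text(alphabet="abcdef", min_size=1, max_size=3),
                           st.integers(1, 100), min_size=1, max_size=10))
    def test_identical_composition_always_one(self, counts):
        x = fv(counts, "x")
        y = fv({k: v * 3 for k, v in counts.items()}, "y")  # same proportions
        assert morisita_horn(x, y) == pytest.approx(1.0)


class TestFoldExpansion:
    def test_simple_ratio(self):
        # 0.10 in MLR vs 0.005 in blood
        assert fold_expansion(100, 1000, 5, 1000) == pytest.approx(20.0)

    def test_pseudocount_rule_for_zero_reference(self):
        # 100/1000 vs 0/10000 with pseudocount 0.5: 0.1 / 5e-5 = 2000
        assert fold_expansion(100, 1000, 0, 10000) == pytest.approx(2000.0)

    def test_equal_frequencies_fold_one(self):
        assert fold_expansion(10, 1000, 100, 10000) == pytest.approx(1.0)

    def test_absent_everywhere_is_error(self):
        with pytest.raises(ValidationError):
            fold_expansion(0, 1000, 0, 1000)


class TestFisherExact:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            n1, n2 = rng.integers(1, 150, 2)
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            ours = fisher_exact_twosided(k1, n1, k2, n2)[0]
            ref = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])[1]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_exact_enumeration_small_margins(self):
        for n1 in range(13):
            for n2 in range(13):
                if n1 == 0 and n2 == 0:
                    continue
                for k1 in range(n1 + 1):
                    for k2 in range(n2 + 1):
                        ours = fisher_exact_twosided(k1, n1, k2, n2)[0]
                        ref = fisher_twosided_exact(k1, n1, k2, n2)
                        assert ours == pytest.approx(ref, abs=1e-10), (k1, n1, k2, n2)


class TestClassifyDynamics:
    def test_emerged_definition(self):
        dyn = classify_dynamics(pd.Series({"a": 0, "b": 10}), pd.Series({"a": 50, "b": 10}),
                                n_pre=10000, n_post=10000)
        assert dyn.loc["a", "status"] == "emerged"

    def test_stable_clone(self):
        dyn = classify_dynamics(pd.Series({"a": 10}), pd.Series({"a": 10}),
                                n_pre=10000, n_post=10000)
        assert dyn.loc["a", "status"] == "stable"
        assert dyn.loc["a", "fold_change"] == pytest.approx(1.0)

    def test_expanded_with_exact_test_oracle(self):
        dyn = classify_dynamics(pd.Series({"a": 2}), pd.Series({"a": 80}),
                                n_pre=10000, n_post=10000, alpha=0.05, fold_threshold=2)
        assert dyn.loc["a", "status"] == "expanded"
        assert dyn.loc["a", "p_value"] == pytest.approx(
            fisher_twosided_exact(2, 10000, 80, 10000), rel=1e-9
        )

    def test_post_singleton_called_absent(self):
        dyn = classify_dynamics(pd.Series({"a": 0, "b": 5}), pd.Series({"a": 1, "b": 5}),
                                n_pre=1000, n_post=1000, min_detect=2)
        assert dyn.loc["a", "status"] == "absent"

    def test_q_values_dominate_p_values(self):
        rng = np.random.default_rng(31)
        pre = random_counts(rng, 50, 2000)
        post = random_counts(rng, 50, 2000)
        dyn = classify_dynamics(pre, post)
        assert (dyn["q_value"] >= dyn["p_value"] - 1e-12).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            classify_dynamics(pd.Series({"a": -1}), pd.Series({"a": 3}), 10, 10)


class TestClonePercentages:
    def test_percent_cluster_matching(self):
        from allotrack.clonotypes import PairedClonotype
        from allotrack.stats import percent_cluster_matching
        from test_clonotypes import beta_key

        clones = [
            PairedClonotype(f"c{i}", None, beta_key(f"NT{i}", aa=f"A{i}"), 1)
            for i in range(10)
        ]
        bulk = make_bulk(
            [(f"NT{i}", f"A{i}", "TRBV9", "TRBJ1-1", 5, True) for i in range(4)]
            + [("X", "X", "TRBV9", "TRBJ1-1", 5, True)]
        )
        pct = percent_cluster_matching(clones, [bulk], mode="nt")
        assert pct["blood"] == pytest.approx(40.0)

    def test_clone_fraction_in_bulk(self):
        from allotrack.clonotypes import PairedClonotype
        from allotrack.stats import clone_fraction_in_bulk
        from test_clonotypes import beta_key

        bulk = make_bulk([
            ("AAA", "K", "TRBV9", "TRBJ1-1", 50, True),
            ("CCC", "P", "TRBV9", "TRBJ1-1", 950, True),
        ])
        clones = [
            PairedClonotype("hit", None, beta_key("AAA", aa="K"), 1),
            PairedClonotype("miss", None, beta_key("TTT", aa="F"), 1),
        ]
        frac = clone_fraction_in_bulk(clones, bulk, mode="nt")
        assert frac["hit"] == pytest.approx(5.0)
        assert frac["miss"] == 0.0

    def test_two_rows_matching_one_aa_clone_sum(self):
        from allotrack.clonotypes import PairedClonotype
        from allotrack.stats import clone_fraction_in_bulk
        from test_clonotypes import beta_key

        bulk = make_bulk([
            ("AAA", "K", "TRBV9", "TRBJ1-1", 10, True),
            ("AAG", "K", "TRBV5-1", "TRBJ1-1", 10, True),
            ("CCC", "P", "TRBV9", "TRBJ1-1", 980, True),
        ])
        clones = [PairedClonotype("c", None, beta_key("AAA", aa="K"), 1)]
        assert clone_fraction_in_bulk(clones, bulk, mode="aa")["c"] == pytest.approx(2.0)
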