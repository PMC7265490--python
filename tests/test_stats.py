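import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirtail.stats import (
    TailProfile,
    canonical_fraction,
    compare_groups,
    cumulative_tail_curve,
    modification_fractions,
    tail_nt_counts,
    u_score,
    weighted_mean_tail,
)

from oracles import exact_wilcoxon_two_sided, recount_cumulative_curve


def profile(classes, mirna_id="mir-1"):
    return TailProfile(mirna_id=mirna_id, class_counts=dict(classes))


# random (templ3, tail) -> count profiles for property tests
profiles_st = st.dictionaries(
    st.tuples(
        st.integers(-4, 3),
        st.text(alphabet="ACGU", min_size=0, max_size=6),
    ),
    st.integers(1, 50),
    min_size=1,
    max_size=12,
).map(lambda d: profile(d))


class TestCanonicalFraction:
    def test_all_canonical(self):
        assert canonical_fraction(profile({(0, ""): 42})) == 100.0

    def test_most_abundant_templated_read(self):
        p = profile({(0, ""): 60, (-1, ""): 25, (0, "U"): 15})
        assert canonical_fraction(p) == 60.0

    def test_tie_broken_toward_unmodified(self):
        p = profile({(0, ""): 50, (-1, ""): 50})
        assert canonical_fraction(p) == 50.0
        from mirtail.stats import canonical_class

        assert canonical_class(p) == (0, "")

    def test_trimmed_class_can_be_canonical(self):
        # the "most abundant templated read" need not be the full-length one
        p = profile({(-1, ""): 70, (0, ""): 20, (0, "U"): 10})
        from mirtail.stats import canonical_class

        assert canonical_class(p) == (-1, "")
        assert canonical_fraction(p) == 70.0

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError, match="empty"):
            canonical_fraction(profile({}))


class TestModificationFractions:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            ({(0, ""): 10}, {"trim_only": 0, "tail_only": 0,
                             "trim_and_tail": 0, "unmodified": 100}),
            ({(-2, "UU"): 10, (0, ""): 10},
             {"trim_only": 0, "tail_only": 0, "trim_and_tail": 50,
              "unmodified": 50}),
            ({(-1, ""): 5, (0, "A"): 5, (0, ""): 10},
             {"trim_only": 25, "tail_only": 25, "trim_and_tail": 0,
              "unmodified": 50}),
        ],
    )
    def test_examples(self, classes, expected):
        assert modification_fractions(profile(classes)) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=profiles_st)
    def test_sums_to_100(self, p):
        assert sum(modification_fractions(p).values()) == pytest.approx(100.0)


class TestTailNtCounts:
    def test_homopolymer(self):
        assert tail_nt_counts(profile({(0, "UUU"): 7}), "U") == {3: 7}

    def test_occurrences_not_run_length(self):
        p = profile({(0, "UAU"): 2})
        assert tail_nt_counts(p, "U") == {2: 2}
        assert tail_nt_counts(p, "A") == {1: 2}

    def test_no_tails(self):
        assert tail_nt_counts(profile({(0, ""): 5}), "U") == {}


class TestCumulativeCurve:
    def test_two_classes(self):
        p = profile({(0, "U"): 50, (0, "UUU"): 50})
        assert cumulative_tail_curve(p, "U") == [(1, 100.0), (2, 50.0), (3, 50.0)]

    def test_single_long_class(self):
        p = profile({(0, "UUUUU"): 10})
        assert cumulative_tail_curve(p, "U") == [(k, 100.0) for k in range(1, 6)]

    def test_no_qualifying_reads_warns_empty(self):
        with pytest.warns(UserWarning):
            assert cumulative_tail_curve(profile({(0, ""): 5}), "U") == []

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=profiles_st, nt=st.sampled_from("ACGU"))
    def test_matches_bruteforce_recount_and_monotone(self, p, nt):
        if not tail_nt_counts(p, nt):
            return
        curve = cumulative_tail_curve(p, nt)
        oracle = recount_cumulative_curve(p, nt)
        assert np.allclose(np.asarray(curve), np.asarray(oracle))
        values = [v for _, v in curve]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(100.0)


class TestWeightedMeanTail:
    def test_all_canonical_zero(self):
        assert weighted_mean_tail(profile({(0, ""): 9}), "U") == 0.0

    def test_pure_oligo_uu(self):
        assert weighted_mean_tail(profile({(0, "UU"): 10}), "U") == 2.0

    def test_min_oligo_zeroes_short_tails(self):
        p = profile({(0, "UUU"): 3, (0, ""): 1})
        assert weighted_mean_tail(p, "U", min_oligo=2) == pytest.approx(2.25)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=profiles_st, nt=st.sampled_from("ACGU"))
    def test_monotone_in_min_oligo(self, p, nt):
        assert weighted_mean_tail(p, nt, 1) >= weighted_mean_tail(p, nt, 2)


class TestUScore:
    def test_identical_profiles_zero(self):
        p = profile({(0, "UU"): 5, (0, ""): 5})
        assert u_score(p, p) == 0.0

    def test_oligo_u_versus_canonical(self):
        test = profile({(0, "UU"): 10})
        ctrl = profile({(0, ""): 10})
        assert u_score(test, ctrl) == 2.0

    def test_mismatched_mirna_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            u_score(profile({(0, ""): 1}, "a"), profile({(0, ""): 1}, "b"))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(pa=profiles_st, pb=profiles_st)
    def test_antisymmetric(self, pa, pb):
        assert u_score(pa, pb) == pytest.approx(-u_score(pb, pa))


class TestCompareGroups:
    def test_identical_paired_vectors_p1(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        stat, p = compare_groups(v, v, paired=True)
        assert p == 1.0

    def test_n5_all_positive_exact_p(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [0.9, 1.7, 2.4, 3.0, 3.5]  # distinct positive differences
        _, p = compare_groups(a, b, paired=True)
        assert p == pytest.approx(0.0625)

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError, match="at least 5"):
            compare_groups([1, 2, 3], [4, 5, 6], paired=True)

    @pytest.mark.parametrize("n", [5, 6, 8, 10])
    def test_exact_wilcoxon_matches_enumeration(self, n, rng):
        for _ in range(20):
            a = rng.normal(size=n)
            b = a + rng.normal(0.5, 1.0, size=n)
            # regenerate on (vanishingly rare) ties in |diff|
            d = np.abs(a - b)
            if len(np.unique(d)) < n:
                continue
            _, p = compare_groups(a, b, paired=True)
            assert p == pytest.approx(exact_wilcoxon_two_sided(a, b))

    def test_unpaired_is_welch(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(1, 2, size=25)
        stat, p = compare_groups(a, b, paired=False)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert (stat, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_p_decreases_with_planted_shift(self, rng):
        n = 116
        base = rng.normal(50, 10, size=n)
        ps = []
        for shift in (0.5, 2.0, 8.0):
            shifted = base + shift + rng.normal(0, 1, size=n)
            _, p = compare_groups(shifted, base, paired=True)
            ps.append(p)
        assert ps[0] > ps[1] > ps[2] or ps[2] < 1e-10
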