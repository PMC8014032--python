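"""Appraisal indices: closed forms, oracles, bounds and monotonicity."""

from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vdpower import (
    GenotypeMatrix,
    PERFECT_MATCH,
    Partition,
    ThresholdRule,
    ValidityError,
    build_partition,
    c_vdp,
    c_vdp_chain,
    inject_missing,
    locus_dp,
    locus_frequencies,
    p_vdp,
    r_vdp,
    subset_loci,
    tdp,
)

from conftest import random_matrix


def brute_force_p_vdp(partition):
    """Oracle: enumerate all unordered sample pairs and count cross-group ones."""
    group_of = {s: g for g, grp in enumerate(partition.groups) for s in grp}
    samples = sorted(group_of)
    pairs = list(combinations(samples, 2))
    different = sum(1 for a, b in pairs if group_of[a] != group_of[b])
    return different / len(pairs)


class TestPVdp:
    def test_known_category_table(self):
        # 6 singletons + 20 groups of 10 over 206 samples
        part = Partition.from_category_table({1: 6, 10: 20})
        assert p_vdp(part).value == pytest.approx(1 - 900 / 21115)
        assert round(p_vdp(part).value, 3) == 0.957

    def test_boundary_values(self):
        assert p_vdp(Partition.from_category_table({1: 5})).value == 1.0
        assert p_vdp(Partition.from_category_table({5: 1})).value == 0.0

    def test_small_partition_matches_enumeration(self):
        part = Partition.from_category_table({2: 2, 1: 1})  # sizes [2,2,1], m=5
        assert p_vdp(part).value == pytest.approx(0.8)
        assert p_vdp(part).value == pytest.approx(brute_force_p_vdp(part))

    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_brute_force_enumeration(self, seed):
        matrix = random_matrix(seed, m=30, n_loci=3, n_alleles=2)
        part = build_partition(matrix, PERFECT_MATCH)
        assert p_vdp(part).value == pytest.approx(brute_force_p_vdp(part))

    def test_rejects_partial_match_partition(self):
        matrix = random_matrix(0, m=6, n_loci=4)
        part = build_partition(matrix, ThresholdRule("count", 2))
        with pytest.raises(ValidityError, match="perfect match"):
            p_vdp(part)

    def test_rejects_missing_data_partition(self):
        matrix = random_matrix(0, m=6, n_loci=4, missing_rate=0.2)
        part = build_partition(matrix, PERFECT_MATCH, undefined_pairs="same")
        with pytest.raises(ValidityError, match="missing"):
            p_vdp(part)


class TestCVdp:
    def test_direct_enumeration_of_ordered_pairs(self):
        # 4 samples, exactly one same-variety unordered pair -> 1 - 2/12
        matrix = GenotypeMatrix.from_calls(
            [["A/A"], ["A/A"], ["C/C"], ["G/G"]], sample_ids=list("wxyz")
        )
        assert c_vdp(matrix, PERFECT_MATCH).value == pytest.approx(1 - 2 / 12)

    def test_all_pairs_different_is_maximal(self):
        matrix = GenotypeMatrix.from_calls([["A/A"], ["C/C"], ["G/G"]])
        assert c_vdp(matrix, PERFECT_MATCH).value == 1.0

    def test_chain_form_on_known_tables(self):
        assert c_vdp_chain(Partition.from_category_table({2: 2, 1: 1})).value == pytest.approx(0.8)
        assert c_vdp_chain(Partition.from_category_table({4: 1})).value == 0.0
        # 6 singletons + 40 groups of 5: 1 - 800/42230
        part = Partition.from_category_table({1: 6, 5: 40})
        assert round(c_vdp_chain(part).value, 3) == 0.981

    @given(seed=st.integers(0, 2**31 - 1))
    def test_equals_p_vdp_under_perfect_match(self, seed):
        """Traversal and probability forms agree exactly on complete data."""
        matrix = random_matrix(seed, m=12, n_loci=3, n_alleles=2)
        part = build_partition(matrix, PERFECT_MATCH)
        assert c_vdp(matrix, PERFECT_MATCH).value == pytest.approx(
            p_vdp(part).value, abs=1e-12
        )
        assert c_vdp_chain(part).value == pytest.approx(p_vdp(part).value, abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_non_increasing_in_threshold(self, seed):
        matrix = random_matrix(seed, m=8, n_loci=6)
        values = [
            c_vdp(matrix, ThresholdRule("count", m_val)).value for m_val in (1, 2, 3, 4)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestRVdp:
    def test_known_category_table(self):
        part = Partition.from_category_table({1: 6, 5: 40})
        assert round(r_vdp(part).value, 3) == 0.223

    def test_bounds(self):
        assert r_vdp(Partition.from_category_table({1: 7})).value == 1.0
        # theoretical floor is 1/m, not 0
        assert r_vdp(Partition.from_category_table({9: 1})).value == pytest.approx(1 / 9)


class TestLocusDpAndTdp:
    def test_monomorphic_locus_has_zero_dp(self):
        matrix = GenotypeMatrix.from_calls([["A/A"], ["A/A"], ["A/A"]])
        assert locus_dp(locus_frequencies(matrix), "L1") == 0.0
        assert tdp(matrix).value == 0.0

    def test_two_equal_classes(self):
        matrix = GenotypeMatrix.from_calls([["A/A"], ["C/C"]])
        assert locus_dp(locus_frequencies(matrix), "L1") == pytest.approx(0.5)

    def test_skewed_class_spectrum(self):
        # classes at 205/206 and 1/206
        matrix = GenotypeMatrix.from_calls([["A/A"]] * 205 + [["C/C"]])
        dp = locus_dp(locus_frequencies(matrix), "L1")
        assert dp == pytest.approx(410 / 42436)

    def test_multiplication_law(self):
        # two independent loci each with DP = 0.5
        matrix = GenotypeMatrix.from_calls([["A/A", "C/C"], ["C/C", "A/A"]])
        assert tdp(matrix).value == pytest.approx(0.75)

    def test_frequencies_use_called_samples_only(self):
        matrix = GenotypeMatrix.from_calls([["A/A"], ["C/C"], [None]])
        freqs = locus_frequencies(matrix)
        assert freqs.n_called["L1"] == 2
        assert locus_dp(freqs, "L1") == pytest.approx(0.5)

    def test_all_missing_locus_is_undefined(self):
        matrix = GenotypeMatrix.from_calls([["A/A", None], ["C/C", None]])
        with pytest.raises(ValidityError, match="no called samples"):
            tdp(matrix)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_tdp_never_decreases_with_added_loci(self, seed):
        matrix = random_matrix(seed, m=10, n_loci=8)
        sub = subset_loci(matrix, matrix.locus_ids[:4])
        assert tdp(matrix).value >= tdp(sub).value - 1e-12


class TestMonotonicityProperties:
    @given(seed=st.integers(0, 2**31 - 1))
    def test_adding_loci_never_decreases_c_or_r(self, seed):
        matrix = random_matrix(seed, m=10, n_loci=8)
        sub = subset_loci(matrix, matrix.locus_ids[:4])
        assert c_vdp(matrix, PERFECT_MATCH).value >= c_vdp(sub, PERFECT_MATCH).value - 1e-12
        r_full = r_vdp(build_partition(matrix, PERFECT_MATCH)).value
        r_sub = r_vdp(build_partition(sub, PERFECT_MATCH)).value
        assert r_full >= r_sub - 1e-12

    @given(seed=st.integers(0, 2**31 - 1))
    def test_missing_injection_only_underestimates(self, seed):
        """Masking loci is a type-II error: scores never rise."""
        matrix = random_matrix(seed, m=10, n_loci=8)
        masked = inject_missing(matrix, 0.4, seed=seed)
        assert (
            c_vdp(masked, PERFECT_MATCH, undefined_pairs="same").value
            <= c_vdp(matrix, PERFECT_MATCH).value + 1e-12
        )
        r_full = r_vdp(build_partition(matrix, PERFECT_MATCH)).value
        r_masked = r_vdp(
            build_partition(masked, PERFECT_MATCH, undefined_pairs="same")
        ).value
        assert r_masked <= r_full + 1e-12

    @given(seed=st.integers(0, 2**31 - 1))
    def test_values_stay_in_bounds(self, seed):
        matrix = random_matrix(seed, m=9, n_loci=5, missing_rate=0.1)
        part = build_partition(matrix, PERFECT_MATCH, undefined_pairs="same")
        assert 1 / part.m <= r_vdp(part).value <= 1.0
        assert 0.0 <= c_vdp(matrix, PERFECT_MATCH, undefined_pairs="same").value <= 1.0
        assert 0.0 <= tdp(matrix).value < 1.0
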