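import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import karyostat as ks
from karyostat.stats import summarize_chromosomes, summarize_group

from conftest import make_matrix
from oracles import (
    oracle_aneuploidy,
    oracle_anca,
    oracle_classify,
    oracle_heterogeneity,
    oracle_instability,
)

REF = ks.EuploidReference()


# --- hand-computed micro-examples -----------------------------------------


def test_tally_counts_states_and_modal_fraction():
    t = ks.tally_chromosome(make_matrix([[2], [2], [2], [3]], ["1"]), "1")
    assert (t.modal_count, t.n_states) == (3, 2)
    assert t.nonmodal_fraction == pytest.approx(0.25)

    uniform = ks.tally_chromosome(make_matrix([[2]] * 4, ["1"]), "1")
    assert (uniform.nonmodal_fraction, uniform.n_states) == (0.0, 1)

    distinct = ks.tally_chromosome(make_matrix([[1], [2], [3], [4]], ["1"]), "1")
    assert (distinct.modal_count, distinct.n_states) == (1, 4)
    assert distinct.nonmodal_fraction == pytest.approx(0.75)
    # tie broken toward the euploid state
    assert distinct.modal_state == 2


def test_tally_errors_on_fully_missing_chromosome():
    mask = np.array([[False, True], [False, True]])
    m = make_matrix([[2, 2], [2, 2]], mask=mask)
    with pytest.raises(ValueError, match="missing"):
        ks.tally_chromosome(m, "2")


def test_instability_index_hand_examples():
    assert ks.instability_index(make_matrix([[2, 2]] * 3)) == 0.0
    m = make_matrix([[2, 2], [2, 2], [2, 2], [3, 2]])
    assert ks.instability_index(m) == pytest.approx(12.5)
    assert ks.instability_index(make_matrix([[2], [3]], ["1"])) == pytest.approx(50.0)


def test_anca_and_normalization_hand_examples(two_cell_matrix):
    assert ks.anca(make_matrix([[2, 2]] * 2)) == 0.0
    assert ks.anca(two_cell_matrix) == pytest.approx(0.5)
    assert ks.normalized_anca(two_cell_matrix) == pytest.approx(0.25)
    assert ks.anca(make_matrix([[4, 4]])) == 2.0
    # every chromosome of every cell altered -> AN hits its upper bound 1
    assert ks.normalized_anca(make_matrix([[3, 3], [1, 3]])) == 1.0


def test_aneuploidy_score_hand_examples(two_cell_matrix):
    assert ks.aneuploidy_score(make_matrix([[2, 2]] * 2)) == 0.0
    assert ks.aneuploidy_score(two_cell_matrix) == pytest.approx(0.25)
    assert ks.aneuploidy_score(make_matrix([[4, 4], [4, 4]])) == pytest.approx(2.0)


def test_heterogeneity_score_hand_examples():
    assert ks.heterogeneity_score(make_matrix([[2], [2], [2]], ["1"])) == 0.0
    assert ks.heterogeneity_score(make_matrix([[2], [2], [3], [3]], ["1"])) == pytest.approx(0.5)
    # maximized when every cell carries a distinct state: (0+1+2+3)/4
    assert ks.heterogeneity_score(make_matrix([[1], [2], [3], [4]], ["1"])) == pytest.approx(1.5)


@pytest.mark.parametrize(
    "counts, expected",
    [
        ([2, 2, 2, 2], "diploid"),
        ([4, 4], "polyploid"),
        ([6, 6], "polyploid"),
        ([2, 3], "aneuploid"),
        ([4, 4, 2], "aneuploid"),
        ([1, 1], "aneuploid"),  # uniform reduction below euploid is not polyploidy
        ([3, 3], "aneuploid"),  # non-integer multiple of 2
    ],
)
def test_classify_cell(counts, expected):
    ref = [2] * len(counts)
    assert ks.classify_cell(counts, ref) == expected


def test_classify_cell_sex_aware_reference():
    # male complement 46,XY is euploid under a sex-aware reference
    assert ks.classify_cell([2, 2, 1, 1], [2, 2, 1, 1]) == "diploid"
    assert ks.classify_cell([4, 4, 2, 2], [2, 2, 1, 1]) == "polyploid"


def test_ploidy_proportions_one_of_each():
    m = make_matrix([[2, 2], [4, 4], [2, 3]])
    p_a, p_d, p_p = ks.ploidy_proportions(m)
    assert (p_a, p_d, p_p) == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    assert p_a + p_d + p_p == 1.0
    assert ks.ploidy_proportions(make_matrix([[2, 2]] * 5)) == (0.0, 1.0, 0.0)


def test_summarize_group_composes_individual_statistics():
    m = make_matrix([[2, 3], [2, 2], [4, 4], [2, 2]])
    s = summarize_group(m, REF, group="G")
    assert s.instability_index == ks.instability_index(m)
    assert s.anca == ks.anca(m, REF)
    assert s.normalized_anca == pytest.approx(s.anca / m.n_chromosomes)
    assert s.aneuploidy_score == ks.aneuploidy_score(m, REF)
    assert s.heterogeneity_score == ks.heterogeneity_score(m)
    assert s.ploidy_proportions == ks.ploidy_proportions(m, REF)
    assert (s.n_cells, s.n_chromosomes) == (4, 2)


def test_single_cell_stratum_has_zero_instability_and_heterogeneity():
    m = make_matrix([[5, 1, 3]], chromosomes=["1", "2", "3"])
    s = summarize_group(m, REF)
    assert s.instability_index == 0.0
    assert s.heterogeneity_score == 0.0


def test_all_euploid_stratum_all_zero():
    s = summarize_group(make_matrix([[2, 2]] * 4), REF)
    assert (
        s.instability_index,
        s.anca,
        s.normalized_anca,
        s.aneuploidy_score,
        s.heterogeneity_score,
    ) == (0, 0, 0, 0, 0)
    assert s.ploidy_proportions == (0.0, 1.0, 0.0)


def test_per_chromosome_rows_and_aggregate_identity(two_cell_matrix):
    rows = summarize_chromosomes(two_cell_matrix, REF)
    by_chrom = {r.chromosome: r for r in rows}
    assert by_chrom["2"].aneuploidy_score == pytest.approx(0.5)
    assert by_chrom["1"].aneuploidy_score == by_chrom["1"].heterogeneity_score == 0.0
    m = make_matrix([[2, 3, 1], [2, 2, 4], [3, 2, 2], [2, 2, 2]],
                    chromosomes=["1", "2", "3"])
    per = summarize_chromosomes(m, REF)
    assert np.mean([r.aneuploidy_score for r in per]) == pytest.approx(
        ks.aneuploidy_score(m, REF)
    )
    assert np.mean([r.heterogeneity_score for r in per]) == pytest.approx(
        ks.heterogeneity_score(m)
    )
    single = make_matrix([[2], [3]], ["1"])
    row = summarize_chromosomes(single, REF)[0]
    assert row.aneuploidy_score == ks.aneuploidy_score(single, REF)


# --- missing-entry handling ------------------------------------------------


def test_statistics_ignore_masked_entries():
    mask = np.array([[False, True], [False, False], [False, False]])
    m = make_matrix([[2, 9], [2, 3], [2, 2]], mask=mask)
    # chromosome 2 observed counts are [3, 2]
    assert ks.aneuploidy_score(m) == pytest.approx(1 / 5)
    assert ks.anca(m) == pytest.approx(1 / 3)
    assert ks.instability_index(m) == pytest.approx(100 * 0.5 / 2)


# --- oracle equivalence and property tests ---------------------------------


def test_statistics_match_brute_force_on_small_enumeration():
    """Spot-check exhaustive agreement on all 2-cell x 2-chromosome matrices
    with counts in {0..3}; the wider sweep runs in the acceptance suite."""
    for values in itertools.product(range(4), repeat=4):
        rows = [list(values[:2]), list(values[2:])]
        m = make_matrix(rows)
        e = [2, 2]
        assert ks.instability_index(m) == pytest.approx(oracle_instability(rows))
        assert ks.anca(m) == pytest.approx(oracle_anca(rows, e))
        assert ks.aneuploidy_score(m) == pytest.approx(oracle_aneuploidy(rows, e))
        assert ks.heterogeneity_score(m) == pytest.approx(oracle_heterogeneity(rows))
        for row in rows:
            assert ks.classify_cell(row, e) == oracle_classify(row, e)


matrices = st.integers(1, 5).flatmap(
    lambda n: st.integers(1, 3).flatmap(
        lambda t: st.lists(
            st.lists(st.integers(0, 6), min_size=t, max_size=t),
            min_size=n,
            max_size=n,
        )
    )
)


@settings(max_examples=60, deadline=None)
@given(rows=matrices, data=st.data())
def test_invariance_properties(rows, data):
    m = make_matrix(rows)
    n, t = len(rows), len(rows[0])
    perm_cells = data.draw(st.permutations(range(n)))
    shuffled = make_matrix([rows[i] for i in perm_cells])
    # I, H, D, A invariant under cell permutation
    for fn in (ks.instability_index, ks.heterogeneity_score):
        assert fn(shuffled) == pytest.approx(fn(m))
    for fn in (ks.anca, ks.aneuploidy_score):
        assert fn(shuffled, REF) == pytest.approx(fn(m, REF))
    # D and A also invariant under chromosome permutation
    perm_chrom = data.draw(st.permutations(range(t)))
    reordered = make_matrix(
        [[row[j] for j in perm_chrom] for row in rows],
        chromosomes=[str(j + 1) for j in perm_chrom],
    )
    assert ks.aneuploidy_score(reordered, REF) == pytest.approx(ks.aneuploidy_score(m, REF))
    assert ks.anca(reordered, REF) == pytest.approx(ks.anca(m, REF))
    # duplicating every cell changes nothing
    doubled = make_matrix(rows + rows)
    s1, s2 = summarize_group(m, REF), summarize_group(doubled, REF)
    for attr in ("instability_index", "anca", "normalized_anca",
                 "aneuploidy_score", "heterogeneity_score", "ploidy_proportions"):
        assert getattr(s2, attr) == pytest.approx(getattr(s1, attr))


@settings(max_examples=60, deadline=None)
@given(rows=matrices)
def test_bounds_and_zero_iff_euploid(rows):
    m = make_matrix(rows)
    n, t = len(rows), len(rows[0])
    s = summarize_group(m, REF)
    assert 0 <= s.instability_index <= 100 * (1 - 1 / n) + 1e-12
    assert 0 <= s.anca <= t
    assert 0 <= s.normalized_anca <= 1
    assert s.aneuploidy_score >= 0
    assert 0 <= s.heterogeneity_score <= (n - 1) / 2 + 1e-12
    p_a, p_d, p_p = s.ploidy_proportions
    assert abs(p_a + p_d + p_p - 1) < 1e-9
    all_euploid = all(c == 2 for row in rows for c in row)
    measures_zero = (
        s.instability_index == s.anca == s.aneuploidy_score == s.heterogeneity_score == 0
    )
    assert measures_zero == all_euploid
    assert (p_d == 1.0) == all_euploid


@settings(max_examples=40, deadline=None)
@given(
    counts=st.lists(st.integers(0, 20), min_size=2, max_size=30),
    shift=st.integers(-3, 10),
)
def test_heterogeneity_depends_only_on_state_count_multiset(counts, shift):
    base = make_matrix([[c] for c in counts], ["1"])
    relabeled = make_matrix([[c + max(shift, 0)] for c in counts], ["1"])
    assert ks.heterogeneity_score(relabeled) == pytest.approx(ks.heterogeneity_score(base))
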