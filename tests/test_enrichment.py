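"""Insertion-site categorization, enrichment, and chi-square goodness-of-fit."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snapvelcro import (
    Category,
    CategoryTable,
    chi_square_gof,
    enrichment_table,
    filter_recognizable,
    load_insertions,
)
from snapvelcro.enrichment import InsertionRecord, categorize_insertions

ORDER = (  # (OL, OF, CL, CF) order used by the hand-worked examples
    Category.OPEN_LOOSE,
    Category.OPEN_FASTENED,
    Category.CLOSED_LOOSE,
    Category.CLOSED_FASTENED,
)


def table_from(counts):
    return CategoryTable.from_counts(dict(zip(ORDER, counts)))


# --- loading --------------------------------------------------------------


def test_load_coordinates_extracts_context(toy_seq, tmp_path):
    path = tmp_path / "ins.tsv"
    path.write_text("id\tcontig\tnick\tstrand\nx\ttoy\t16\t+\n")
    records = load_insertions(path, genome={"toy": toy_seq})
    assert len(records) == 1
    assert records[0].context10 == "TTTTTTTTTT"
    assert records[0].downstream_base == "A"


def test_load_bed6(toy_seq, tmp_path):
    path = tmp_path / "ins.bed"
    path.write_text("toy\t15\t16\t.\t0\t+\ntoy\t16\t17\t.\t0\t+\n")
    records = load_insertions(path, genome={"toy": toy_seq})
    assert [r.context10 for r in records] == ["TTTTTTTTTT", "TTTTTTTTTA"]


def test_load_junctions(tmp_path):
    path = tmp_path / "junc.tsv"
    path.write_text("id\tjunction\nj1\tTTTTTTTTTA\nj2\tCCTTTTTTTTTT\n")
    records = load_insertions(path)
    kept, dropped = filter_recognizable(records)
    assert [r.pattern for r in kept] == ["deg_pos1", "perfect"]
    assert not dropped


def test_load_malformed_row_reports_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("id\tcontig\tnick\tstrand\nok\ttoy\t16\t+\nbad\ttoy\tnope\t+\n")
    with pytest.raises(ValueError, match="line 3"):
        load_insertions(path, genome={"toy": "T" * 30})


def test_load_short_junction_rejected(tmp_path):
    path = tmp_path / "short.tsv"
    path.write_text("id\tjunction\nj\tTTTTT\n")
    with pytest.raises(ValueError, match="shorter"):
        load_insertions(path)


def test_load_unknown_contig_rejected(tmp_path):
    path = tmp_path / "ins.tsv"
    path.write_text("id\tcontig\tnick\tstrand\nx\tmissing\t16\t+\n")
    with pytest.raises(ValueError, match="contig"):
        load_insertions(path, genome={"toy": "T" * 30})


def test_dedup_flag(toy_seq, tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text(
        "id\tcontig\tnick\tstrand\n" + "a\ttoy\t16\t+\n" * 3 + "b\ttoy\t17\t+\n"
    )
    assert len(load_insertions(path, genome={"toy": toy_seq})) == 4
    assert len(load_insertions(path, genome={"toy": toy_seq}, dedup=True)) == 2


# --- filtering ------------------------------------------------------------


def test_filter_recognizable_examples():
    records = [
        InsertionRecord(id="keep", context10="TTTTTTTTTT"),
        InsertionRecord(id="drop", context10="TTTTTTGGTT"),  # two non-T in snap
    ]
    kept, dropped = filter_recognizable(records)
    assert [r.id for r in kept] == ["keep"]
    assert kept[0].pattern == "perfect"
    assert kept[0].status.category is Category.CLOSED_FASTENED
    assert [r.id for r in dropped] == ["drop"]


def test_filter_purine_condition_only_with_downstream_base():
    with_pyrimidine = InsertionRecord(
        id="p", context10="TTTTTTTTTT", downstream_base="C"
    )
    junction_only = InsertionRecord(id="j", context10="TTTTTTTTTT")
    kept, dropped = filter_recognizable([with_pyrimidine, junction_only])
    assert [r.id for r in kept] == ["j"]
    assert [r.id for r in dropped] == ["p"]


def test_filter_empty_input():
    assert filter_recognizable([]) == ([], [])


def test_filter_partitions_input():
    records = [
        InsertionRecord(id=str(i), context10=ctx)
        for i, ctx in enumerate(
            ["TTTTTTTTTT", "TTTTTTGGTT", "GGGGGGTTTC", "TTTTTTNTTT"]
        )
    ]
    kept, dropped = filter_recognizable(records)
    assert len(kept) + len(dropped) == len(records)
    assert {r.id for r in kept} | {r.id for r in dropped} == {r.id for r in records}


def test_categorize_insertions_requires_filter():
    with pytest.raises(ValueError, match="filter"):
        categorize_insertions([InsertionRecord(id="x", context10="TTTTTTTTTT")])


# --- chi-square -----------------------------------------------------------


def test_chi_square_null():
    chi2, df, p = chi_square_gof([40, 30, 20, 10], [0.4, 0.3, 0.2, 0.1])
    assert chi2 == pytest.approx(0.0)
    assert df == 3
    assert p == pytest.approx(1.0)


def test_chi_square_hand_computed():
    # E = (40,30,20,10): (10^2/40) + 0 + (5^2/20) + (5^2/10) = 6.25
    chi2, df, p = chi_square_gof([50, 30, 15, 5], [0.4, 0.3, 0.2, 0.1])
    assert chi2 == pytest.approx(6.25)
    assert df == 3
    assert 0 < p < 1


def test_chi_square_maximum_for_point_mass():
    n, k = 400, 4
    chi2, _, _ = chi_square_gof([n, 0, 0, 0], [1 / k] * k)
    assert chi2 == pytest.approx(n * (k - 1))


def test_chi_square_warns_on_small_expected_count():
    with pytest.warns(UserWarning, match="below 5"):
        chi_square_gof([10, 5, 4, 1], [0.5, 0.25, 0.15, 0.1])


def test_chi_square_errors():
    with pytest.raises(ValueError):
        chi_square_gof([0, 0, 0, 0], [0.25] * 4)
    with pytest.raises(ValueError):
        chi_square_gof([1, 2, 3, 4], [0.5, 0.5, 0.0, 0.0])
    with pytest.raises(ValueError):
        chi_square_gof([1, 2, 3, 4], [0.4, 0.3, 0.2, 0.2])  # sums to 1.1


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4),
    st.permutations(range(4)),
)
def test_chi_square_relabel_invariance(observed, perm):
    freqs = [0.4, 0.3, 0.2, 0.1]
    chi2, _, p = chi_square_gof(observed, freqs)
    chi2_p, _, p_p = chi_square_gof(
        [observed[i] for i in perm], [freqs[i] for i in perm]
    )
    assert chi2_p == pytest.approx(chi2)
    assert p_p == pytest.approx(p)


def test_p_decreases_with_chi2():
    freqs = [0.4, 0.3, 0.2, 0.1]
    shifts = [(40, 30, 20, 10), (45, 30, 18, 7), (50, 30, 15, 5), (60, 25, 10, 5)]
    ps = [chi_square_gof(list(o), freqs)[2] for o in shifts]
    assert ps == sorted(ps, reverse=True)


# --- enrichment -----------------------------------------------------------


def test_enrichment_identity_when_dataset_matches_reference():
    ref = table_from([400, 300, 200, 100])
    data = table_from([40, 30, 20, 10])
    result = enrichment_table(data, ref)
    for c in Category:
        assert result.enrichment[c] == pytest.approx(1.0)
        assert result.normalized_frequency[c] == pytest.approx(1.0)
    assert result.chi2 == pytest.approx(0.0)
    assert result.p == pytest.approx(1.0)
    assert result.df == 3


def test_enrichment_hand_example():
    ref = table_from([40, 30, 20, 10])  # frequencies .4/.3/.2/.1
    data = table_from([10, 30, 20, 40])  # frequencies .1/.3/.2/.4
    result = enrichment_table(data, ref)
    assert [result.enrichment[c] for c in ORDER] == pytest.approx([0.25, 1, 1, 4])
    assert [result.normalized_frequency[c] for c in ORDER] == pytest.approx(
        [1, 4, 4, 16]
    )
    assert result.normalized_frequency[Category.OPEN_LOOSE] == 1.0


def test_enrichment_alternate_baseline():
    ref = table_from([40, 30, 20, 10])
    data = table_from([10, 30, 20, 40])
    result = enrichment_table(data, ref, baseline=Category.OPEN_FASTENED)
    assert result.normalized_frequency[Category.OPEN_FASTENED] == 1.0
    assert result.normalized_frequency[Category.OPEN_LOOSE] == pytest.approx(0.25)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4),
    st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4),
)
def test_enrichment_swap_inverts(a, b):
    ta, tb = table_from(a), table_from(b)
    forward = enrichment_table(ta, tb)
    backward = enrichment_table(tb, ta)
    for c in Category:
        assert forward.enrichment[c] == pytest.approx(1.0 / backward.enrichment[c])


def test_enrichment_errors():
    ref_zero = table_from([10, 10, 10, 0])
    data = table_from([1, 1, 1, 1])
    with pytest.raises(ValueError):
        enrichment_table(data, ref_zero)
    with pytest.raises(ValueError):
        enrichment_table(CategoryTable(), table_from([1, 1, 1, 1]))
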