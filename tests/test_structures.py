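"""Loop/TAD validation statistics: matching, proportions, weighted scores."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicmamba.contact import ContactMap
from hicmamba.structures import (BoundarySet, LoopSet, StructureScoreInputs,
                                 intensity_comparison, match_boundaries,
                                 match_loops, proportion, read_bed,
                                 read_bedpe, sample_matched_nonloops,
                                 structure_weighted_score, support_partition,
                                 write_bed, write_bedpe)

BS = 10000


def _loops(pairs, chrom="chr1"):
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    return LoopSet(chrom=[chrom] * len(pairs),
                   a1_start=i * BS, a1_end=(i + 1) * BS,
                   a2_start=j * BS, a2_end=(j + 1) * BS)


# ---------------------------------------------------------------------------
# loop matching

def test_identical_sets_all_match():
    ls = _loops([(5, 20), (8, 40), (12, 30)])
    matched, unmatched = match_loops(ls, ls, tol_bins=1, bin_size=BS)
    assert matched == 3
    assert len(unmatched) == 0


def test_displacement_beyond_tolerance_fails():
    pred = _loops([(5, 20)])
    ref = _loops([(5 + 2, 20)])  # tol_bins + 1 away
    matched, _ = match_loops(pred, ref, tol_bins=1, bin_size=BS)
    assert matched == 0


def test_hand_counted_matches_with_planned_offsets():
    pred = _loops([(5, 20), (8, 40), (12, 30), (50, 70), (60, 90)])
    ref = _loops([(5, 21),    # 1-bin offset on one anchor: matches
                  (8, 43),    # 3-bin offset: no match
                  (60, 90)])  # exact: matches
    matched, unmatched = match_loops(pred, ref, tol_bins=1, bin_size=BS)
    assert matched == 2
    assert len(unmatched) == 3


def test_matching_is_per_chromosome():
    pred = _loops([(5, 20)], chrom="chr1")
    ref = _loops([(5, 20)], chrom="chr2")
    assert match_loops(pred, ref)[0] == 0


def test_anchor_order_normalized_on_construction():
    ls = LoopSet(chrom=["chr1"], a1_start=[200000], a1_end=[210000],
                 a2_start=[50000], a2_end=[60000])
    assert ls.a1_start[0] == 50000
    assert ls.a2_start[0] == 200000


# ---------------------------------------------------------------------------
# proportion (printed-arithmetic checks live in the acceptance suite)

def test_proportion_basic():
    assert proportion(485, 730) == 66.4
    assert proportion(7, 7) == 100.0


def test_proportion_contract_violations():
    with pytest.raises(ValueError):
        proportion(1, 0)
    with pytest.raises(ValueError):
        proportion(5, 4)


def test_proportion_invariant_to_record_order():
    pred = _loops([(5, 20), (8, 40), (12, 30)])
    ref = _loops([(12, 30), (5, 20)])
    base = match_loops(pred, ref)[0]
    perm = pred.subset([2, 0, 1])
    assert match_loops(perm, ref)[0] == base


# ---------------------------------------------------------------------------
# boundary support

def test_peak_inside_every_boundary_full_support():
    b = BoundarySet(chrom=["chr1"] * 2, start=[100000, 300000],
                    end=[110000, 310000])
    peaks = BoundarySet(chrom=["chr1"] * 2, start=[105000, 301000],
                        end=[106000, 302000])
    matched, prop = match_boundaries(b, peaks, tol_bp=0)
    assert matched == 2
    assert prop == 100.0


def test_no_peaks_no_support():
    b = BoundarySet(chrom=["chr1"], start=[0], end=[10000])
    peaks = BoundarySet(chrom=["chr2"], start=[0], end=[5000])
    assert match_boundaries(b, peaks)[0] == 0


def test_borderline_peak_at_exact_tolerance_counts():
    """Closed-interval rule: a peak touching boundary +- tol is support."""
    b = BoundarySet(chrom=["chr1"] * 4,
                    start=[100000, 300000, 500000, 700000],
                    end=[110000, 310000, 510000, 710000])
    peaks = BoundarySet(chrom=["chr1"] * 2,
                        start=[120000, 90000],  # first starts exactly at end+tol
                        end=[130000, 95000])
    matched, prop = match_boundaries(b, peaks, tol_bp=10000)
    assert matched == 1
    assert prop == 25.0


# ---------------------------------------------------------------------------
# structure weighted score

def test_weighted_score_hand_computation():
    inputs = StructureScoreInputs(
        A={"GM12878": {"se": 50}, "K562": {"se": 25}},
        N={"GM12878": 100, "K562": 100})
    table = structure_weighted_score(inputs)
    assert table.W["GM12878"]["se"] == Fraction(2, 3)
    assert table.W["K562"]["se"] == Fraction(1, 3)


def test_weighted_score_symmetry_and_saturation():
    eq = structure_weighted_score(StructureScoreInputs(
        A={"a": {"f": 30}, "b": {"f": 15}}, N={"a": 60, "b": 30}))
    assert eq.W["a"]["f"] == eq.W["b"]["f"] == Fraction(1, 2)
    sat = structure_weighted_score(StructureScoreInputs(
        A={"a": {"f": 60}, "b": {"f": 30}}, N={"a": 60, "b": 30}))
    assert sat.W["a"]["f"] == sat.W["b"]["f"] == Fraction(1, 2)


@given(st.integers(1, 500), st.integers(1, 500), st.data())
@settings(derandomize=True, max_examples=60, deadline=None)
def test_weighted_scores_sum_to_one_exactly(n1, n2, data):
    a1 = data.draw(st.integers(0, n1))
    a2 = data.draw(st.integers(0, n2))
    t = structure_weighted_score(StructureScoreInputs(
        A={"l1": {"f": a1}, "l2": {"f": a2}}, N={"l1": n1, "l2": n2}))
    if t.W["l1"]["f"] is None:
        assert a1 == a2 == 0
    else:
        assert t.W["l1"]["f"] + t.W["l2"]["f"] == 1


def test_zero_denominator_flagged_not_zero():
    t = structure_weighted_score(StructureScoreInputs(
        A={"a": {"f": 0}, "b": {"f": 0}}, N={"a": 10, "b": 10}))
    assert t.W["a"]["f"] is None


# ---------------------------------------------------------------------------
# support partition

def test_partition_pred_subset_of_set1():
    pred = _loops([(5, 20), (8, 40)])
    out = support_partition(pred, pred, _loops([(70, 90)]))
    assert out == {"only1": 1.0, "only2": 0.0, "both": 0.0, "neither": 0.0}


def test_partition_hand_classified_fractions():
    pred = _loops([(i, i + 30) for i in range(10, 110, 10)])  # 10 loops
    both = [(10, 40), (20, 50), (30, 60)]
    only1 = [(40, 70), (50, 80), (60, 90), (70, 100)]
    only2 = [(80, 110)]
    s1 = _loops(both + only1)
    s2 = _loops(both + only2)
    out = support_partition(pred, s1, s2, tol_bins=0)
    assert out == {"only1": 0.4, "only2": 0.1, "both": 0.3, "neither": 0.2}
    assert sum(out.values()) == pytest.approx(1.0)


def test_partition_fractions_always_sum_to_one():
    rng = np.random.default_rng(1)
    for _ in range(10):
        pred = _loops([(int(i), int(i + d)) for i, d in
                       zip(rng.integers(0, 80, 8), rng.integers(5, 15, 8))])
        s1 = _loops([(int(i), int(i + 7)) for i in rng.integers(0, 80, 4)])
        s2 = _loops([(int(i), int(i + 9)) for i in rng.integers(0, 80, 4)])
        assert sum(support_partition(pred, s1, s2).values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# matched non-loop sampling and intensity comparison

def _map_with_loops(small_pair):
    return small_pair["high"], small_pair["loops"]


def test_nonloop_controls_match_size_and_distances(small_pair):
    cmap, loops = _map_with_loops(small_pair)
    ctrl = sample_matched_nonloops(cmap, loops, seed=3)
    assert len(ctrl) == len(loops)
    d_in = sorted((loops.midpoints()[1] - loops.midpoints()[0]) // cmap.bin_size)
    d_out = sorted((ctrl.midpoints()[1] - ctrl.midpoints()[0]) // cmap.bin_size)
    assert d_in == d_out


def test_nonloop_controls_avoid_true_loops(small_pair):
    cmap, loops = _map_with_loops(small_pair)
    ctrl = sample_matched_nonloops(cmap, loops, seed=3, tol_bins=1)
    li = (loops.midpoints()[0]) // cmap.bin_size
    lj = (loops.midpoints()[1]) // cmap.bin_size
    ci = (ctrl.midpoints()[0]) // cmap.bin_size
    cj = (ctrl.midpoints()[1]) // cmap.bin_size
    for i, j in zip(ci, cj):
        assert not np.any((np.abs(li - i) <= 1) & (np.abs(lj - j) <= 1))


def test_nonloop_sampler_deterministic_per_seed(small_pair):
    cmap, loops = _map_with_loops(small_pair)
    a = sample_matched_nonloops(cmap, loops, seed=9)
    b = sample_matched_nonloops(cmap, loops, seed=9)
    c = sample_matched_nonloops(cmap, loops, seed=10)
    assert np.array_equal(a.a1_start, b.a1_start)
    assert np.array_equal(a.a2_start, b.a2_start)
    assert sorted(a.a2_start - a.a1_start) == sorted(c.a2_start - c.a1_start)


def test_planted_loops_brighter_than_matched_controls(small_pair):
    cmap, loops = _map_with_loops(small_pair)
    ctrl = sample_matched_nonloops(cmap, loops, seed=1)
    rep = intensity_comparison(cmap, loops, loops, ctrl)
    assert rep["validated"]["mean"] > rep["controls"]["mean"]
    assert rep["test"]["underpowered"] is False
    assert rep["test"]["pvalue"] < 0.05


def test_intensity_single_element_sets_flagged_underpowered(small_pair):
    cmap, loops = _map_with_loops(small_pair)
    one = loops.subset([0])
    rep = intensity_comparison(cmap, one, one, one)
    assert rep["test"]["underpowered"] is True
    assert "mean" in rep["validated"]


# ---------------------------------------------------------------------------
# BEDPE / BED I/O

def test_bedpe_roundtrip(tmp_path):
    ls = _loops([(5, 20), (8, 40)])
    p = tmp_path / "loops.bedpe"
    write_bedpe(ls, p)
    back = read_bedpe(p)
    assert np.array_equal(back.a1_start, ls.a1_start)
    assert np.array_equal(back.a2_end, ls.a2_end)


def test_bedpe_extra_columns_ignored(tmp_path):
    p = tmp_path / "x.bedpe"
    p.write_text("chr1\t0\t10000\tchr1\t50000\t60000\tloop1\t0.9\n")
    ls = read_bedpe(p)
    assert len(ls) == 1
    assert ls.a2_start[0] == 50000


def test_bed_sorted_on_load(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chr1\t50000\t60000\nchr1\t0\t10000\n")
    bs = read_bed(p)
    assert bs.start.tolist() == [0, 50000]
    q = tmp_path / "y.bed"
    write_bed(bs, q)
    assert read_bed(q).start.tolist() == [0, 50000]
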