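"""Gap enumeration, repeat detection, thermodynamics and pair design."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoerode.core_io import ScaffoldSet
from endoerode.gap_primer import (
    DesignFailure,
    GapInterval,
    PrimerPair,
    coverage_report,
    design_gap_primers,
    detect_repeats,
    find_gaps,
    iterative_mask,
    melting_temperature,
    reverse_complement,
    score_candidate,
)

# ---------------------------------------------------------------- gaps

@pytest.mark.parametrize(
    "seq,min_run,expected",
    [
        ("ACGTNNNNNACGT", 5, [(4, 9)]),
        ("ACGTACGT", 1, []),
        ("NNACGTNN", 2, [(0, 2), (6, 8)]),  # runs at sequence ends count
        ("ANNAANNNA", 2, [(1, 3), (5, 8)]),
        ("ANNAANNNA", 3, [(5, 8)]),
    ],
)
def test_find_gaps_maximal_runs(seq, min_run, expected):
    gaps = find_gaps(ScaffoldSet(records={"s": seq}), min_run=min_run)
    assert [(g.start, g.end) for g in gaps] == expected
    for g in gaps:
        assert set(seq[g.start : g.end]) == {"N"}
        assert g.estimated_size == g.end - g.start


@given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
@settings(max_examples=200, deadline=None)
def test_find_gaps_equals_scan_oracle(seq):
    """Every reported interval is a maximal N-run and none is missed."""
    gaps = find_gaps(ScaffoldSet(records={"s": seq}), min_run=1)
    covered = set()
    for g in gaps:
        covered.update(range(g.start, g.end))
        if g.start > 0:
            assert seq[g.start - 1] != "N"
        if g.end < len(seq):
            assert seq[g.end] != "N"
    assert covered == {i for i, c in enumerate(seq) if c == "N"}


# ---------------------------------------------------------------- repeats

def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_detect_repeats_recovers_planted_copies():
    rng = np.random.default_rng(5)
    bg = _rand_seq(rng, 100_000)
    core = _rand_seq(rng, 400)
    positions = [10_000, 45_000, 80_000]
    chars = list(bg)
    truth = set()
    for p in positions:
        chars[p : p + 400] = core
        truth.update(range(p, p + 400))
    s = ScaffoldSet(records={"c": "".join(chars)})
    reps = detect_repeats(s, k=24, min_copies=2)
    detected = set()
    for r in reps:
        detected.update(range(r.start, r.end))
    recall = len(detected & truth) / len(truth)
    fp = len(detected - truth) / (100_000 - len(truth))
    assert recall >= 0.95
    assert fp <= 0.01
    # all three copies share one family
    fams = {r.family_id for r in reps if truth & set(range(r.start, r.end))}
    assert len(fams) == 1


def test_detect_repeats_reverse_complement_copy():
    rng = np.random.default_rng(6)
    bg = _rand_seq(rng, 30_000)
    core = _rand_seq(rng, 300)
    chars = list(bg)
    chars[5_000 : 5_300] = core
    chars[20_000 : 20_300] = reverse_complement(core)
    reps = detect_repeats(ScaffoldSet(records={"c": "".join(chars)}), k=24)
    covered = set()
    for r in reps:
        covered.update(range(r.start, r.end))
    assert len(covered & set(range(5_000, 5_300))) >= 285
    assert len(covered & set(range(20_000, 20_300))) >= 285


def test_detect_repeats_unique_genome_is_empty():
    # every k-mer unique by construction: de Bruijn-free short random seq
    rng = np.random.default_rng(7)
    s = ScaffoldSet(records={"c": _rand_seq(rng, 5_000)})
    assert detect_repeats(s, k=24, min_copies=2) == []


def test_iterative_mask_reaches_fixed_point_and_sets_intervals():
    rng = np.random.default_rng(8)
    bg = _rand_seq(rng, 20_000)
    core = _rand_seq(rng, 200)
    chars = list(bg)
    chars[1_000:1_200] = core
    chars[10_000:10_200] = core
    s = ScaffoldSet(records={"c": "".join(chars)})
    reps = iterative_mask(s, k=24, min_copies=2)
    assert s.masked["c"] == [(r.start, r.end) for r in reps]


# ---------------------------------------------------------------- thermodynamics

_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _tm_oracle(seq, na_mM=50.0, primer_nM=500.0):
    """Independent hand-summed nearest-neighbor Tm from the unified table."""
    dh = ds = 0.0
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dh, ds = dh + 0.1, ds - 2.8
        else:
            dh, ds = dh + 2.3, ds + 4.1
    for i in range(len(seq) - 1):
        dinuc = seq[i : i + 2]
        h, s = _NN.get(dinuc) or _NN[_COMP[dinuc[1]] + _COMP[dinuc[0]]]
        dh, ds = dh + h, ds + s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh / (ds + 1.987 * math.log(primer_nM * 1e-9)) - 273.15


def test_tm_matches_hand_summed_table():
    seq = "AGCGTCGACCTAGGATCAAC"
    assert melting_temperature(seq, 50.0, 500.0) == pytest.approx(58.58, abs=0.1)
    assert melting_temperature(seq, 50.0, 500.0) == pytest.approx(
        _tm_oracle(seq), abs=0.1
    )


@pytest.mark.parametrize("seq", ["ACGTACGTACGT", "GGGCCCATATGCGC", "AAAATTTTCCCGG",
                                 "AGCTAGCTAGCTAGCTAGCTAGCTAGC"])
def test_tm_oracle_agreement_and_duplex_symmetry(seq):
    assert melting_temperature(seq) == pytest.approx(_tm_oracle(seq), abs=0.1)
    assert melting_temperature(seq) == pytest.approx(
        melting_temperature(reverse_complement(seq)), abs=1e-9
    )


def test_tm_gc_append_monotonicity():
    rng = np.random.default_rng(9)
    for _ in range(20):
        seq = _rand_seq(rng, 18)
        assert melting_temperature(seq + "GC") >= melting_temperature(seq)


@pytest.mark.parametrize("seq,err", [("ACGTNACGTAGC", "non-ACGT"), ("ACGT", "shorter")])
def test_tm_input_validation(seq, err):
    with pytest.raises(ValueError, match=err):
        melting_temperature(seq)


# ---------------------------------------------------------------- candidate gates

def test_score_candidate_rejects_homopolymer():
    assert score_candidate("GCATAAAAAGCATGCATGCA") is None


def test_score_candidate_rejects_extreme_gc():
    assert score_candidate("G" * 10 + "C" * 10) is None  # gc = 1.0
    assert score_candidate("ATATTATATAATATTATATA") is None  # gc = 0.0


def test_score_candidate_accepts_and_scores_clean_window():
    cand = score_candidate("AGCGTCGACCTAGGATCAAC", "s", 0, "+")
    assert cand is not None
    assert cand.penalty >= 0 and math.isfinite(cand.penalty)
    assert 0.20 <= cand.gc_fraction <= 0.80
    assert 57.0 <= cand.tm <= 63.0


# ---------------------------------------------------------------- pair design

def _gapped_scaffold(rng, flank=1_500, gap=300):
    left = _rand_seq(rng, flank)
    right = _rand_seq(rng, flank)
    seq = left + "N" * gap + right
    return ScaffoldSet(records={"s": seq}), GapInterval("s", flank, flank + gap)


def test_design_returns_spanning_pair_on_clean_flanks():
    rng = np.random.default_rng(10)
    scaff, gap = _gapped_scaffold(rng)
    result = design_gap_primers(gap, scaff, [])
    assert isinstance(result, PrimerPair)
    assert 100 <= result.product_size <= 1_000
    assert result.left.end <= gap.start and result.right.start >= gap.end
    assert result.left.strand == "+" and result.right.strand == "-"
    assert "N" not in result.left.sequence and "N" not in result.right.sequence


def test_design_fails_flanks_masked():
    rng = np.random.default_rng(11)
    scaff, gap = _gapped_scaffold(rng)
    from endoerode.gap_primer import RepeatInterval

    repeats = [RepeatInterval("s", 0, gap.start, 0)]  # whole left flank masked
    result = design_gap_primers(gap, scaff, repeats)
    assert isinstance(result, DesignFailure) and result.reason == "flanks_masked"


def test_design_fails_product_range_on_wide_gap():
    rng = np.random.default_rng(12)
    scaff, gap = _gapped_scaffold(rng, gap=2_000)
    result = design_gap_primers(gap, scaff, [], product_range=(100, 1_000))
    assert isinstance(result, DesignFailure)
    assert result.reason == "product_range_unsatisfiable"
    # the wider second-round window can succeed on the same gap
    retry = design_gap_primers(gap, scaff, [], product_range=(100, 3_000))
    assert isinstance(retry, PrimerPair) and retry.product_size <= 3_000


def test_design_rejects_unknown_scaffold():
    rng = np.random.default_rng(13)
    scaff, _ = _gapped_scaffold(rng)
    with pytest.raises(ValueError, match="unknown scaffold"):
        design_gap_primers(GapInterval("zz", 0, 5), scaff, [])


def test_designed_primers_avoid_masked_repeats():
    rng = np.random.default_rng(14)
    scaff, gap = _gapped_scaffold(rng)
    from endoerode.gap_primer import RepeatInterval

    # mask the 400 bp nearest the gap on the left
    repeats = [RepeatInterval("s", gap.start - 400, gap.start, 0)]
    result = design_gap_primers(gap, scaff, repeats, product_range=(100, 3_000))
    if isinstance(result, PrimerPair):
        assert result.left.end <= gap.start - 400


# ---------------------------------------------------------------- coverage

@pytest.mark.parametrize(
    "total,with_primers,percent",
    [(96, 68, 70.83), (10, 5, 50.00), (7, 0, 0.00), (0, 0, 0.00)],
)
def test_coverage_report(total, with_primers, percent):
    rep = coverage_report(total, with_primers)
    assert rep["percent"] == percent


def test_coverage_report_rejects_impossible_counts():
    with pytest.raises(ValueError):
        coverage_report(5, 6)
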