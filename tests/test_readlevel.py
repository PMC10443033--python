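"""Read-level diversity: distances, indel flagging, filters, spectra."""

import numpy as np
import pytest

from evolvrseq.align import align_read
from evolvrseq.io import AmpliconReference, Read
from evolvrseq.readlevel import (
    SUBSTITUTION_TYPES,
    UniqueReadTable,
    edit_distance,
    filter_occurrence,
    flag_indels,
    hamming_distance,
    normalize_and_spectrum,
    read_substitutions,
    remove_indel_reads,
    subtract_parental_reads,
    trim_to_window,
)

from _oracles import brute_force_read_filters, levenshtein
from conftest import random_seq


# the premature-stop-codon example: one substitution from wild type
def test_hamming_examples():
    assert hamming_distance("GAG", "TAG") == 1
    assert hamming_distance("ACGT", "ACGT") == 0
    assert hamming_distance("ACGT", "ACG") is None


def test_edit_distance_examples():
    assert edit_distance("ACGT", "ACGT") == 0
    assert edit_distance("ACGT", "ACT") == 1
    assert edit_distance("AACGT", "ACGTT") == 2
    assert hamming_distance("AACGT", "ACGTT") == 3  # edit < hamming => indels


def test_edit_distance_matches_dp_oracle(rng):
    for _ in range(100):
        a = random_seq(rng, int(rng.integers(0, 15)))
        b = random_seq(rng, int(rng.integers(0, 15)))
        assert edit_distance(a, b) == levenshtein(a, b)


def test_edit_leq_hamming_for_equal_lengths(rng):
    """Metric property: edit distance never exceeds Hamming distance."""
    for _ in range(2000):
        n = int(rng.integers(1, 20))
        a, b = random_seq(rng, n), random_seq(rng, n)
        assert edit_distance(a, b) <= hamming_distance(a, b)


WINDOW_REF = AmpliconReference("ref", "TTGACCAGTACGTACGGTTACGATCGATTGCCAGTGCAAT", (10, 30))


def _aln(seq):
    return align_read(Read("r", seq, np.full(len(seq), 38)), WINDOW_REF)


def test_trim_perfect_read_gives_window_substring():
    assert trim_to_window(_aln(WINDOW_REF.seq), WINDOW_REF) == WINDOW_REF.window_seq


def test_trim_substitution_survives_projection():
    seq = list(WINDOW_REF.seq)
    seq[15] = "A" if seq[15] != "A" else "C"
    projected = trim_to_window(_aln("".join(seq)), WINDOW_REF)
    assert projected != WINDOW_REF.window_seq
    assert hamming_distance(projected, WINDOW_REF.window_seq) == 1


def test_trim_deletion_shortens_projection():
    seq = WINDOW_REF.seq[:20] + WINDOW_REF.seq[22:]  # 2 bp deletion inside window
    projected = trim_to_window(_aln(seq), WINDOW_REF)
    assert len(projected) == 18


def test_trim_drops_partial_reads():
    assert trim_to_window(_aln(WINDOW_REF.seq[15:]), WINDOW_REF) is None


def test_flag_indels_rules():
    ref_w = "ACGTACGTAC"
    table = UniqueReadTable.from_counts(
        {
            "ACGTACGTAC": 10,  # reference
            "ACGAACGTAC": 6,  # 1 substitution: kept
            "ACTTAGGTAC": 6,  # 2 substitutions, edit == hamming: kept
            "ACGTACGTA": 6,  # 1 bp shorter: removed
            "AACGTACGTA": 6,  # compensating ins+del, edit < hamming: removed
        },
        ref_w,
    )
    flagged = flag_indels(table)
    by_seq = dict(zip(flagged.frame["seq"], flagged.frame["has_indel"]))
    assert not by_seq["ACGTACGTAC"]
    assert not by_seq["ACGAACGTAC"]
    assert not by_seq["ACTTAGGTAC"]
    assert by_seq["ACGTACGTA"]
    assert by_seq["AACGTACGTA"]
    kept, removed = remove_indel_reads(flagged)
    assert removed == 12
    assert len(kept) == 3


def test_occurrence_filter_boundary():
    table = UniqueReadTable.from_counts({"AAAA": 4, "CCCC": 5, "GGGG": 50}, "TTTT")
    filtered = filter_occurrence(table, min_count=5)
    assert set(filtered.frame["seq"]) == {"CCCC", "GGGG"}
    empty = filter_occurrence(UniqueReadTable.from_counts({}, "TTTT"))
    assert len(empty) == 0


def test_parental_subtraction_boundary():
    treated = UniqueReadTable.from_counts({"AAAA": 50, "CCCC": 10, "GGGG": 8}, "AAAA")
    parental = UniqueReadTable.from_counts({"AAAA": 1000, "CCCC": 4, "GGGG": 5}, "AAAA")
    out = subtract_parental_reads(treated, parental)
    # reference read (abundant in parental) and GGGG (parental count 5) removed;
    # CCCC stays: parental count 4 is below the threshold
    assert set(out.frame["seq"]) == {"CCCC"}


def test_normalized_hamming_spectrum_example():
    ref_w = "AAAA"
    table = flag_indels(UniqueReadTable.from_counts({"AATA": 50}, ref_w))
    summary = normalize_and_spectrum(table, mean_depth=1000)
    assert summary.hamming_spectrum == {1: pytest.approx(0.05)}


def test_all_reference_reads_give_empty_spectra():
    table = flag_indels(UniqueReadTable.from_counts({"AAAA": 100}, "AAAA"))
    summary = normalize_and_spectrum(table, mean_depth=100)
    assert summary.substitution_spectrum.total == 0
    assert summary.fraction_mutated == 0.0


def test_substitution_classification():
    ref_w = "ACGT"
    assert read_substitutions("TCGT", ref_w) == [(0, "A", "T")]
    table = flag_indels(UniqueReadTable.from_counts({"TCGT": 7, "ACGA": 3}, ref_w))
    summary = normalize_and_spectrum(table, mean_depth=100)
    spec = summary.substitution_spectrum
    assert spec.counts["A>T"] == 7
    assert spec.counts["T>A"] == 3
    assert spec.total == 10
    assert len(SUBSTITUTION_TYPES) == 12


def test_fraction_mutated_permutation_invariant():
    import random

    ref_w = "ACGTACGT"
    reads = ["ACGTACGT"] * 20 + ["ACGTACGA"] * 10 + ["TCGTACGT"] * 5
    t1 = UniqueReadTable.tally(reads, ref_w)
    random.Random(0).shuffle(reads)
    t2 = UniqueReadTable.tally(reads, ref_w)
    s1 = normalize_and_spectrum(flag_indels(t1), 100)
    s2 = normalize_and_spectrum(flag_indels(t2), 100)
    assert s1.fraction_mutated == s2.fraction_mutated == pytest.approx(15 / 35)


def test_filter_chain_matches_brute_force(rng):
    """Constructed 12-read-type fixture: survivors of occurrence, parental
    and indel filters equal direct enumeration."""
    ref_w = "ACGTACGTACGTACGT"
    reads = (
        [ref_w] * 40
        + ["CCGTACGTACGTACGT"] * 7   # novel substitution, survives
        + ["ACGTACGTACGTACGA"] * 4   # below occurrence threshold
        + ["ACGTTCGTACGTACGT"] * 9   # present >=5 in parental too: removed
        + ["ACGACGTACGTACGT"] * 8    # deletion: removed
        + ["AACGTACGTACGTACGT"] * 6  # insertion: removed
        + ["ACGTACGTACGAACGT"] * 5   # novel substitution at threshold: survives
    )
    parental = [ref_w] * 60 + ["ACGTTCGTACGTACGT"] * 6 + ["CCGTACGTACGTACGT"] * 2
    expected = brute_force_read_filters(reads, parental, ref_w, min_count=5)

    table = remove_indel_reads(flag_indels(UniqueReadTable.tally(reads, ref_w)))[0]
    table = filter_occurrence(table, 5)
    table = subtract_parental_reads(table, UniqueReadTable.tally(parental, ref_w), 5)
    observed = dict(zip(table.frame["seq"], table.frame["count"]))
    assert observed == expected


def test_mean_hamming_increases_with_mutation_load():
    ref_w = "ACGTACGTAC"
    low = flag_indels(UniqueReadTable.from_counts({ref_w: 90, "ACGTACGTAT": 10}, ref_w))
    high = flag_indels(UniqueReadTable.from_counts({ref_w: 50, "ACGTACGTAT": 30,
                                                    "TCGTACGAAT": 20}, ref_w))
    s_low = normalize_and_spectrum(low, 100)
    s_high = normalize_and_spectrum(high, 100)
    assert s_high.mean_hamming > s_low.mean_hamming
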