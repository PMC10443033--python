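"""Paired-end merging: lossless reconstruction, rejection rules, statistics."""

import numpy as np
import pytest

from evolvrseq.io import Read, revcomp, write_fastq
from evolvrseq.merge import (
    REJECT_AMBIGUOUS,
    REJECT_NO_OVERLAP,
    MergeStats,
    merge_files,
    merge_pair,
    merge_pairs,
)
from evolvrseq.simulate import sequence_reads, simulate_molecules, uniform_subst_matrix

from conftest import random_seq


def _pair_from_molecule(mol, read_len=None, q1=30, q2=30):
    read_len = read_len or (len(mol) // 2 + 10)
    r1 = Read("p/1", mol[:read_len], np.full(read_len, q1))
    r2 = Read("p/2", revcomp(mol[-read_len:]), np.full(read_len, q2))
    return r1, r2


def test_error_free_simulated_pairs_merge_losslessly(amplicon):
    """Oracle equivalence: 500 error-free pairs reconstruct their molecules."""
    ref, _ = amplicon
    mols, _ = simulate_molecules(
        ref, np.full(len(ref), 0.003), uniform_subst_matrix(), 500, 21
    )
    r1b, r2b = sequence_reads(mols, error_rate=0.0, rng=22)
    for i in range(500):
        res = merge_pair(r1b.read(i), r2b.read(i))
        assert res.status == "merged"
        assert res.merged.seq == mols[i].tobytes().decode()
        assert res.overlap_len == 2 * 150 - len(ref)


def test_single_overlap_mismatch_rejects_under_zero_tolerance(rng):
    mol = random_seq(rng, 100)
    r1, r2 = _pair_from_molecule(mol, read_len=60)
    # corrupt one R1 base inside the overlap region [40, 60)
    seq = list(r1.seq)
    seq[50] = "ACGT"[("ACGT".index(seq[50]) + 1) % 4]
    r1 = Read(r1.id, "".join(seq), r1.qual)
    res = merge_pair(r1, r2)
    assert res.status == "rejected"
    assert res.reject_reason == REJECT_NO_OVERLAP


def test_overlap_quality_is_capped_max(rng):
    mol = random_seq(rng, 100)
    r1, r2 = _pair_from_molecule(mol, read_len=60, q1=30, q2=38)
    res = merge_pair(r1, r2)
    assert res.status == "merged"
    # overlap covers molecule positions [40, 60): quality = max(30, 38)
    assert np.all(res.merged.qual[40:60] == 38)
    assert np.all(res.merged.qual[:40] == 30)
    assert np.all(res.merged.qual[60:] == 38)


def test_merge_is_symmetric(rng):
    mol = random_seq(rng, 90)
    r1, r2 = _pair_from_molecule(mol, read_len=55)
    fwd = merge_pair(r1, r2)
    # swapping roles sequences the reverse-complement fragment: R1' = R2,
    # R2' = R1 (merge_pair reverse-complements its second argument itself)
    swapped = merge_pair(Read("p/1", r2.seq, r2.qual), Read("p/2", r1.seq, r1.qual))
    assert fwd.status == swapped.status == "merged"
    assert swapped.merged.seq == revcomp(fwd.merged.seq)


def test_merged_length_identity(rng):
    for _ in range(20):
        mol = random_seq(rng, int(rng.integers(60, 120)))
        r1, r2 = _pair_from_molecule(mol, read_len=50)
        res = merge_pair(r1, r2)
        if res.status == "merged":
            assert len(res.merged.seq) == len(r1) + len(r2) - res.overlap_len


def test_ambiguous_equal_overlap_rejected():
    # perfect tandem repeat: offsets 0 and 10 both give a valid maximal
    # 20 bp overlap, which cannot be resolved without guessing
    unit = "ACGTACGTGG"
    mol = unit * 6
    r1 = Read("p/1", mol[:30], np.full(30, 30))
    r2 = Read("p/2", revcomp(mol[20:40]), np.full(20, 30))
    res = merge_pair(r1, r2, min_overlap=5)
    assert res.status == "rejected"
    assert res.reject_reason == REJECT_AMBIGUOUS


def test_n_in_overlap_rejects(rng):
    mol = random_seq(rng, 100)
    r1, r2 = _pair_from_molecule(mol, read_len=60)
    seq = list(r1.seq)
    seq[50] = "N"
    res = merge_pair(Read(r1.id, "".join(seq), r1.qual), r2)
    assert res.status == "rejected"


def test_merge_pairs_detects_desync(rng):
    mol = random_seq(rng, 100)
    r1, r2 = _pair_from_molecule(mol)
    r2 = Read("other/2", r2.seq, r2.qual)
    with pytest.raises(ValueError, match="desynchronized"):
        list(merge_pairs([(r1, r2)]))


def test_merge_files_empty(tmp_path):
    f1, f2, out = tmp_path / "a.fastq", tmp_path / "b.fastq", tmp_path / "m.fastq"
    write_fastq([], f1)
    write_fastq([], f2)
    stats = merge_files(f1, f2, out)
    assert stats.total == 0 and stats.merged == 0
    assert out.read_text() == ""


def test_error_rate_rejection_fraction(amplicon):
    """With per-base error e, a pair survives only if both overlap copies
    agree; the rejection fraction matches 1 - (1-e)^(2*overlap) within 3 SE."""
    ref, _ = amplicon
    n = 1500
    e = 0.02
    mols, _ = simulate_molecules(ref, np.zeros(len(ref)), uniform_subst_matrix(), n, 5)
    r1b, r2b = sequence_reads(mols, error_rate=e, rng=6)
    stats = MergeStats()
    list(merge_pairs(zip(iter(r1b), iter(r2b)), stats=stats))
    overlap = 2 * 150 - len(ref)
    expected = 1 - (1 - e) ** (2 * overlap)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(stats.rejected / n - expected) < 3 * se
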