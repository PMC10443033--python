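"""Simulator: nick geometry, footprint construction, molecule sampling."""

import numpy as np
import pytest

from evolvrseq.io import AmpliconReference, revcomp
from evolvrseq.merge import merge_pair
from evolvrseq.simulate import (
    GuideSpec,
    GuideValidationError,
    MutagenesisProfile,
    NickSpec,
    RepairModel,
    biased_subst_matrix,
    build_position_profile,
    find_nick,
    make_default_amplicon,
    sequence_reads,
    simulate_molecules,
    truth_frequencies,
    uniform_subst_matrix,
)


def _toy_reference():
    """Hand-built 60 bp reference with a + strand guide.

    Protospacer at [10, 30), PAM 'TGG' at [30, 33). The blunt cut falls
    between protospacer bases 17 and 18, i.e. between reference positions
    26 and 27, so nick_pos = 27 = pam_start - 3.
    """
    left = "AACCGGTTAA"
    protospacer = "GATTACAGATTACAGATTAC"
    pam = "TGG"
    right = "ACGTACGTACGTACGTACGTACGTACG"
    seq = left + protospacer + pam + right
    assert len(seq) == 60
    ref = AmpliconReference("toy", seq)
    guide = GuideSpec("gt", protospacer, "+", 30)
    return ref, guide


def test_find_nick_h840a_plus_guide():
    ref, guide = _toy_reference()
    nick = find_nick(ref, guide, "H840A")
    assert nick == NickSpec(nick_pos=27, nicked_strand="+", direction=1)
    # 3 nt 5' of the PAM: bases 27, 28, 29 sit between the nick and the PAM
    assert guide.pam_start - nick.nick_pos == 3


def test_find_nick_d10a_flips_strand_and_direction():
    ref, guide = _toy_reference()
    nick = find_nick(ref, guide, "D10A")
    assert nick.nicked_strand == "-"
    assert nick.direction == -1
    assert nick.nick_pos == 27  # blunt cut: same between-base position


def test_find_nick_minus_strand_guide(amplicon):
    ref, guides = amplicon
    nick = find_nick(ref, guides["g2"], "H840A")
    assert nick.nicked_strand == "-"
    assert nick.direction == -1
    # first base in the direction of activity is immediately 5' of the nick
    assert nick.first_base() == nick.nick_pos - 1


def test_find_nick_rejects_bad_pam():
    ref, guide = _toy_reference()
    # shift the PAM off its NGG: reference has 'GG' only at [31, 33)
    bad = GuideSpec("bad", guide.spacer, "+", 29)
    with pytest.raises(GuideValidationError):
        find_nick(ref, bad, "H840A")


def test_guide_requires_spacer_match():
    ref, guide = _toy_reference()
    bad = GuideSpec("bad", "A" * 20, "+", 30)
    with pytest.raises(GuideValidationError, match="spacer"):
        bad.validate(ref)


def test_profile_zero_nicks_is_flat_background():
    ref, _ = _toy_reference()
    repair = RepairModel(escape_prob=0.7, background_rate=1e-3)
    p = build_position_profile(ref, [], MutagenesisProfile(), repair)
    assert np.allclose(p, 1e-3)


def test_profile_decay_zero_is_step():
    ref, _ = _toy_reference()
    model = MutagenesisProfile(peak_rate=0.1, decay=0.0, fwd_window=5,
                               rev_window=3, rev_fraction=0.5)
    repair = RepairModel(escape_prob=1.0, background_rate=0.0)
    nick = NickSpec(30, "+", 1)
    p = build_position_profile(ref, [nick], model, repair)
    assert np.allclose(p[30:35], 0.1)
    assert np.allclose(p[27:30], 0.05)
    assert np.all(p[:27] == 0.0) and np.all(p[35:] == 0.0)


def test_profile_colocated_nicks_combine_independently():
    ref, _ = _toy_reference()
    model = MutagenesisProfile(peak_rate=0.1, decay=0.0, fwd_window=1, rev_window=0)
    repair = RepairModel(escape_prob=1.0, background_rate=0.0)
    nick = NickSpec(30, "+", 1)
    p = build_position_profile(ref, [nick, nick], model, repair)
    assert p[30] == pytest.approx(1 - 0.9**2)  # = 0.19


def test_profile_union_bounds(amplicon):
    ref, guides = amplicon
    model = MutagenesisProfile()
    repair = RepairModel(escape_prob=1.0, background_rate=0.0)
    nicks = [find_nick(ref, g, "H840A") for g in guides.values()]
    combined = build_position_profile(ref, nicks, model, repair)
    singles = [build_position_profile(ref, [n], model, repair) for n in nicks]
    for s in singles:
        assert np.all(combined >= s - 1e-12)
    assert np.all(combined <= np.sum(singles, axis=0) + 1e-12)


def test_msh6_multiplier_scales_profile(amplicon):
    ref, guides = amplicon
    repair = RepairModel(escape_prob=0.4, msh6_multiplier=1.5, background_rate=1e-4)
    nicks = [find_nick(ref, guides["g2"], "H840A")]
    wt = build_position_profile(ref, nicks, MutagenesisProfile(), repair, genotype="WT")
    mut = build_position_profile(ref, nicks, MutagenesisProfile(), repair, genotype="msh6d")
    assert np.allclose(mut, wt * 1.5)


def test_simulate_zero_profile_yields_reference(amplicon):
    ref, _ = amplicon
    mols, truth = simulate_molecules(ref, np.zeros(len(ref)), uniform_subst_matrix(), 50, 7)
    assert truth.empty
    assert all(m.tobytes().decode() == ref.seq for m in mols)


def test_simulate_deterministic_substitution(amplicon):
    ref, _ = amplicon
    p = np.zeros(len(ref))
    p[100] = 1.0
    matrix = biased_subst_matrix(ref.seq[100], "T" if ref.seq[100] != "T" else "A", 1.0)
    alt = "T" if ref.seq[100] != "T" else "A"
    mols, truth = simulate_molecules(ref, p, matrix, 30, 7)
    assert len(truth) == 30
    assert set(truth["alt"]) == {alt}
    assert all(chr(m[100]) == alt for m in mols)


def test_simulate_binomial_frequency(amplicon):
    """Observed alt fraction at a p=0.05 site within 3 binomial SE."""
    ref, _ = amplicon
    n = 100_000
    p = np.zeros(len(ref))
    p[150] = 0.05
    _, truth = simulate_molecules(ref, p, uniform_subst_matrix(), n, 42)
    freq = truth_frequencies(truth, n, len(ref))
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(freq[150] - 0.05) < 3 * se


def test_sequence_reads_lossless_and_mergeable(amplicon):
    ref, _ = amplicon
    mols, _ = simulate_molecules(
        ref, np.full(len(ref), 0.002), uniform_subst_matrix(), 40, 3
    )
    r1, r2 = sequence_reads(mols, error_rate=0.0, rng=4)
    for i in range(40):
        res = merge_pair(r1.read(i), r2.read(i))
        assert res.status == "merged"
        assert res.merged.seq == mols[i].tobytes().decode()


@pytest.mark.parametrize("length", [250, 280, 299, 300])
def test_read_pair_geometry(length, rng):
    mols = np.tile(
        np.frombuffer("".join("ACGT"[i] for i in rng.integers(0, 4, length)).encode(),
                      dtype=np.uint8),
        (2, 1),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error")
        if 2 * 150 - length < 20:
            with pytest.warns(UserWarning, match="overlap"):
                sequence_reads(mols, rng=1)
        else:
            sequence_reads(mols, rng=1)


def test_amplicon_longer_than_pair_span_errors(rng):
    mols = np.full((2, 310), ord("A"), dtype=np.uint8)
    with pytest.raises(ValueError, match="exceeds"):
        sequence_reads(mols, rng=1)


def test_sequencing_error_rate_calibrated(amplicon):
    ref, _ = amplicon
    mols = np.tile(np.frombuffer(ref.seq.encode(), dtype=np.uint8), (10_000, 1))
    r1, _ = sequence_reads(mols, error_rate=0.01, rng=9)
    truth = mols[:, :150]
    observed = np.mean(r1.seqs != truth)
    se = np.sqrt(0.01 * 0.99 / r1.seqs.size)
    assert abs(observed - 0.01) < 3 * se


def test_default_amplicon_reproducible():
    a1, g1 = make_default_amplicon()
    a2, g2 = make_default_amplicon()
    assert a1.seq == a2.seq
    assert g1.keys() == g2.keys()
    for k in g1:
        assert g1[k] == g2[k]
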